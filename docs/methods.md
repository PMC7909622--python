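# Methods

## Spectrum processing

A spectrum is a list of fragment peaks (m/z in Da, unitless intensity) plus
precursor m/z, neutral parent mass, InChIKey and ionization mode.  Two
filtering tracks are maintained, because the embedding score and the
cosine-type scores want different peak sets:

* **common front end** — peaks restricted to m/z ∈ [0, 1000] (closed
  interval); spectra with fewer than 10 remaining peaks are rejected.
* **cosine track** — peaks below 1% of the base-peak intensity are removed
  (peaks at exactly 1% are kept; only strictly smaller values count as
  noise).
* **embedding track** — the peak count is capped at ⌊0.5 · parent mass⌋,
  keeping the most intense peaks, so document length scales with molecule
  size; larger molecules are expected to produce more informative fragments.
  The floor is used because a fractional peak count is meaningless and
  flooring is conservative.

Both tracks end by normalizing intensities to base peak = 1.  When the
parent mass is absent it is estimated as precursor m/z − 1.007276 Da,
assuming a singly protonated positive-mode ion; this is an explicit
assumption (logged), adequate for the positive-mode libraries this package
targets and for the synthetic benchmark, and no further adduct inference is
attempted.  Spectra without InChIKey annotations are retained for training
but excluded from structural evaluation.

## From spectrum to document

Each peak becomes the token `peak@xxx.xx` at a configurable decimal
precision (default 2).  Neutral losses, precursor m/z − peak m/z, between
5.0 and 200.0 Da (boundaries inclusive) are added as `loss@xxx.xx` tokens
carrying their generating peak's normalized intensity.  Binning rounds
half away from zero on the decimal representation (200.445 → 200.45);
binary-float banker's rounding would bin boundary values inconsistently
across platforms.  Peak words are ordered by ascending m/z, loss words by
ascending loss value; duplicate tokens from distinct peaks are kept,
because deduplication would silently drop intensity mass.  Ordering is
irrelevant to training since the context window spans the whole document.

## Embedding model

Word vectors are trained with the continuous-bag-of-words objective and
negative sampling.  The gradient loop is a compact numba kernel written for
this package: it is single-threaded and fully seeded, so a fixed seed gives
bit-identical vectors run to run (the documented reproducibility contract;
multi-worker training is deliberately not implemented).  Negative samples
are drawn from the unigram distribution raised to 0.75; the learning rate
decays linearly from 0.025 to 0.0001 over all training steps; input vectors
are initialized uniformly in ±0.5/d and output weights at zero.

Parameters that matter (defaults in parentheses):

* **window (500)** — fragment peaks have no meaningful order, so the window
  exceeds any document length and the whole spectrum is context for every
  word; a warning is emitted if a document is longer than the window.
* **mode (cbow)** — CBOW is the default; skip-gram is available.
* **negative (5)**, **epochs (15)** — negative sampling with five noise
  words; 15 epochs suits larger corpora, 50 is appropriate for small ones.
* **vector_size (300)** — embedding dimension; a config key, not a
  constant.  The synthetic benchmark runs at 100, which this corpus size
  supports equally well.
* **min_count (1)** — every observed word gets a vector, so missing words
  arise only from train/apply vocabulary mismatch.

The spectrum vector is v_S = Σ wᵢ·vᵢ over in-vocabulary words (an optional
intensity exponent on wᵢ defaults to 1.0, reproducing the plain weighted
sum).  Similarity is the cosine of two spectrum vectors.  The missing
fraction — the intensity-weighted share of words unknown to the model — is
always computed; scores where either spectrum exceeds the allowed missing
fraction (default 0.05) are flagged unreliable rather than withheld, a
policy choice callers can tighten.

Two properties of the training objective are worth knowing.  First,
embedding similarity between words is *second-order*: words sharing many
contexts converge, which is exactly the regime of fragment peaks (related
peaks co-occur in some spectra and share the rest of the document as
context).  A degenerate pair of words that only ever occur together in
tiny documents is actually pushed apart, because a word never co-occurs
with itself; the test suite pins the realistic partial-co-occurrence
behavior against an independent positive-PMI SVD factorization oracle.
Second, under-trained embeddings on small corpora are anisotropic: absolute
cosine values compress toward 1 while the score *ordering* is already
highly informative.  The benchmark metrics below are therefore rank-based
(matching argmax, top-k, top-percentile curves, network neighborhoods).

## Classical scores

The cosine score aligns peak pairs within an m/z tolerance (0.005 Da,
inclusive) and computes Σ I_a·I_b over the alignment, normalized by the
product of the all-peak intensity norms — the standard dot-product cosine;
matched-only normalization would not be a cosine and can exceed 1.  The
modified cosine additionally admits pairs whose m/z difference equals the
precursor m/z difference; each peak is matched at most once, as is or in
its shifted form, and with a zero shift duplicate candidates collapse.

The assignment uses the linear-time greedy heuristic: candidates sorted by
descending intensity product (ties: smaller |Δm/z|, then lower peak
indices — a deterministic order the underlying problem does not dictate)
are accepted while both endpoints are free.  Tests compare it against an
exact maximum-weight assignment oracle: it never exceeds the optimum and
attains it in ~90% of random small instances.  Scores with fewer than
`min_match` aligned pairs are forced to 0.0 (defaults: 6 for cosine, 10
for modified cosine), with the match count still reported.  Both scores
are cross-checked against an independent reference implementation
(matchms) to 1e−9 in the test suite.

## Structural ground truth

Structural similarity is the Tanimoto (Jaccard) coefficient over
fixed-length fingerprint bit vectors, default 2048-bit daylight-like rdkit
path fingerprints.  Fingerprint generation sits behind an optional rdkit
adapter; every workflow equally accepts precomputed hex-encoded bit-vector
tables, so no chemistry dependency is required for evaluation.

## Workflows

* **Top-percentile analysis** — for each fraction f, the mean structural
  similarity over the ⌈f · n_pairs⌉ unique spectrum pairs with the highest
  spectral scores, alongside the theoretical maximum curve (the f highest
  structural similarities).
* **Library matching** — candidates within 1 ppm of the query precursor
  m/z; the argmax-scoring candidate is accepted iff its score is strictly
  above the threshold (ties: smaller precursor difference, then id).  A
  match is a true positive when it shares the query's planar InChIKey
  (first 14 characters).  Retrieval is the fraction of queries yielding any
  match; accuracy is TP/(TP+FP).  The threshold sweep (0.95 down to 0 in
  0.05 steps) scores each query–candidate set once and re-derives decisions
  per threshold, so retrieval is monotone by construction.
* **Top-k analog search** — the k highest embedding-similarity library
  entries per query, no precursor prefiltering; embedding vectors are
  computed once, so ranking a whole library is a matrix product.
* **Molecular networking** — each spectrum contributes edges to its up to
  10 highest-scoring neighbors with score strictly above the threshold; the
  graph is the undirected union, so degrees can exceed 10 via incoming
  edges.  Connected components larger than 30 nodes are split by Louvain
  modularity communities (seeded, delegated to networkx); smaller
  components are kept whole.  A cluster is well-clustered when the mean
  structural similarity over its internal edges is ≥ 0.5, poorly-clustered
  below; nodes without edges are unclustered.  The three node fractions are
  computed with exact rational arithmetic and sum to 1.

## Synthetic benchmark

The generator decouples spectral and structural relatedness with a
substructure-block model: 40 blocks, each owning disjoint fingerprint bits
(2048/40 per block) and 8 characteristic fragments (m/z uniform in
[50, 440] Da, base intensity uniform in [0.05, 1]).  A molecule is the
union of 4 blocks, so the Tanimoto between two molecules is *exactly*
shared blocks / union blocks — analytically exact ground truth without any
chemistry.  Half of the molecules are one-block mutations of an earlier
molecule, creating structural-analog families (one-block relatives of
4-block molecules sit at Tanimoto 3/5 = 0.6; the analog-search hit rate is
therefore reported at the 0.5 homogeneity cutoff).  Parent masses are drawn
uniformly in [460, 640] Da so that a usable share of fragments produces
neutral losses in [5, 200] Da, and the precursor m/z is parent mass +
1.007276 exactly, emulating a well-calibrated instrument for the 1 ppm
preselection window.

Spectra are noisy renderings of a molecule's fragment profile: 10% peak
dropout (never below 10 peaks), multiplicative log-normal intensity jitter
(σ = 0.1), additive Gaussian m/z jitter (σ = 0.002 Da, comparable to the
0.005 Da matching tolerance and the 0.01 word bin), and 3 spurious uniform
peaks.  Default study design: 200 molecules × 4 spectra; 100 held-out query
spectra whose molecules keep at least one library spectrum (library-split
mode), or full removal of query molecules from both library and training
corpus (unknown mode).  All randomness flows from one seeded generator;
identical config + seed yields byte-identical output files.

What the generator does **not** emulate: real fragmentation chemistry
(fragment m/z are arbitrary, not mass-balanced), adducts and multiple
charge states, retention behavior, instrument-dependent intensity response,
and the long-tailed library sizes of public repositories.  Passing
benchmarks therefore demonstrate that the pipeline recovers planted
co-occurrence structure under realistic noise magnitudes — not
field performance on real libraries, whose scale is roughly 100× larger
than this corpus (the benchmark sizes were chosen so the full study runs in
seconds on one CPU).

## Numerical choices and degenerate inputs

Tolerance comparisons are inclusive; threshold acceptance ("larger than")
is strict.  All-zero-intensity spectra, empty spectra, zero-norm spectrum
vectors, documents with no in-vocabulary words, mismatched fingerprint
lengths, and two empty fingerprints raise errors rather than returning
sentinel scores.  Rejection by the minimum-peak filter is a value
(`None`), not an error, so pipelines can count rejects.  Unparseable
records in library files are skipped with a logged warning instead of
aborting the read.

## Known limitations

The embedding trainer is a minimal CBOW/skip-gram implementation: no
sub-sampling of frequent words, no hierarchical softmax, no vocabulary
pruning by corpus position, single-threaded only.  The parent-mass fallback
assumes [M+H]+; negative-mode spectra are stored but not chemically
interpreted.  The MSP reader covers the common Name:/PrecursorMZ:/Num
Peaks: dialect, not every vendor variant.  Fingerprint semantics are
whatever the supplied bit vectors encode; the package takes no position on
the best structural similarity measure.
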