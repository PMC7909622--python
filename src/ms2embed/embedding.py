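"""Word embeddings over spectrum documents and the embedding similarity score.

The model treats every binned peak or neutral loss as a word and each
spectrum as one document.  Unlike natural-language text, fragment peaks
have no meaningful order, so the context window (default 500) is chosen
to exceed any document length: every word in a spectrum is context for
every other.  Training uses the continuous-bag-of-words objective with
negative sampling; the gradient loop is a compact numba kernel that is
bit-reproducible for a fixed seed (single-threaded by construction).

A spectrum is represented by the weighted sum of its word vectors,

    v_S = sum_i w_i * v_i,

with w_i the intensity normalized to base peak = 1 and v_i the word
vector of peak (or loss) i.  The similarity of two spectra is the
cosine of their spectrum vectors.  Words absent from the model's
vocabulary contribute nothing to v_S; their weighted share is tracked
as the *missing fraction*

    missing = 1 - (sum of known w_i) / (sum of all w_i),

and scores where either spectrum exceeds an allowed missing fraction
(default 0.05) are flagged unreliable.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .documents import SpectrumDocument

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingMeta:
    """Training hyperparameters recorded as model provenance.

    ``window`` should be at least the longest document length so the
    whole spectrum counts as context; ``mode`` is ``"cbow"`` (default,
    observed to work better for spectra) or ``"skip-gram"``.
    """

    vector_size: int = 300
    window: int = 500
    epochs: int = 15
    negative: int = 5
    mode: str = "cbow"
    seed: int = 0
    min_count: int = 1
    alpha: float = 0.025
    min_alpha: float = 0.0001
    workers: int = 1

    def __post_init__(self):
        if self.mode not in ("cbow", "skip-gram"):
            raise ValueError(f"unknown training mode {self.mode!r}")


@dataclass(frozen=True)
class SpectrumVector:
    """An embedded spectrum: d-dimensional vector + missing fraction."""

    values: np.ndarray
    missing_fraction: float


@dataclass(frozen=True)
class EmbeddingScore:
    """Similarity value plus the coverage diagnostics behind it."""

    score: float
    missing_fraction_a: float
    missing_fraction_b: float
    reliable: bool


class EmbeddingModel:
    """Vocabulary of peak/loss words mapped to d-dimensional vectors."""

    def __init__(self, vocabulary: dict[str, int], vectors: np.ndarray,
                 training_meta: TrainingMeta, counts: Optional[dict[str, int]] = None):
        if len(vocabulary) != vectors.shape[0]:
            raise ValueError("one vector per vocabulary word required")
        self.vocabulary = vocabulary
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self.training_meta = training_meta
        self.counts = counts or {}

    @property
    def vector_size(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self.vocabulary

    def word_vector(self, word: str) -> np.ndarray:
        return self.vectors[self.vocabulary[word]]

    def save(self, path) -> None:
        """Persist vocabulary, vectors and provenance to one .npz file."""
        words = np.array(sorted(self.vocabulary, key=self.vocabulary.get), dtype=object)
        np.savez(
            path,
            words=words.astype(str),
            vectors=self.vectors,
            counts=np.array([self.counts.get(w, 0) for w in words], dtype=np.int64),
            meta=json.dumps(asdict(self.training_meta)),
        )

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        data = np.load(path, allow_pickle=False)
        words = [str(w) for w in data["words"]]
        meta = TrainingMeta(**json.loads(str(data["meta"])))
        counts = dict(zip(words, (int(c) for c in data["counts"])))
        return cls({w: i for i, w in enumerate(words)}, data["vectors"], meta, counts)


@njit(cache=True)
def _sigmoid(x):
    if x > 6.0:
        return 1.0
    if x < -6.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _sample_negative(cumulative, n_words):
    r = np.random.random()
    lo, hi = 0, n_words - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cumulative[mid] < r:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _train_kernel(corpus, offsets, syn0, syn1, cumulative, window, epochs,
                  negative, alpha0, min_alpha, seed, use_cbow):
    """Negative-sampling SGD over the flattened corpus.

    corpus: word indices of all documents back to back; offsets marks
    document boundaries.  syn0 are the input (word) vectors that become
    the model; syn1 the output weights.  Single-threaded, seeded.
    """
    np.random.seed(seed)
    n_words_vocab = syn1.shape[0]
    d = syn0.shape[1]
    n_docs = offsets.shape[0] - 1
    total_steps = epochs * corpus.shape[0]
    step = 0
    neu1 = np.zeros(d)
    neu1e = np.zeros(d)
    for _epoch in range(epochs):
        for doc in range(n_docs):
            start, stop = offsets[doc], offsets[doc + 1]
            for t in range(start, stop):
                lr = alpha0 + (min_alpha - alpha0) * (step / total_steps)
                step += 1
                center = corpus[t]
                lo = max(start, t - window)
                hi = min(stop, t + window + 1)
                n_context = hi - lo - 1
                if n_context <= 0:
                    continue
                if use_cbow:
                    # h = mean of context vectors predicts the center word
                    for j in range(d):
                        neu1[j] = 0.0
                        neu1e[j] = 0.0
                    for c in range(lo, hi):
                        if c == t:
                            continue
                        w = corpus[c]
                        for j in range(d):
                            neu1[j] += syn0[w, j]
                    for j in range(d):
                        neu1[j] /= n_context
                    for k in range(negative + 1):
                        if k == 0:
                            target = center
                            label = 1.0
                        else:
                            target = _sample_negative(cumulative, n_words_vocab)
                            if target == center:
                                continue
                            label = 0.0
                        f = 0.0
                        for j in range(d):
                            f += neu1[j] * syn1[target, j]
                        g = (label - _sigmoid(f)) * lr
                        for j in range(d):
                            neu1e[j] += g * syn1[target, j]
                            syn1[target, j] += g * neu1[j]
                    for j in range(d):
                        neu1e[j] /= n_context
                    for c in range(lo, hi):
                        if c == t:
                            continue
                        w = corpus[c]
                        for j in range(d):
                            syn0[w, j] += neu1e[j]
                else:
                    # skip-gram: each context vector predicts the center word
                    for c in range(lo, hi):
                        if c == t:
                            continue
                        w = corpus[c]
                        for j in range(d):
                            neu1e[j] = 0.0
                        for k in range(negative + 1):
                            if k == 0:
                                target = center
                                label = 1.0
                            else:
                                target = _sample_negative(cumulative, n_words_vocab)
                                if target == center:
                                    continue
                                label = 0.0
                            f = 0.0
                            for j in range(d):
                                f += syn0[w, j] * syn1[target, j]
                            g = (label - _sigmoid(f)) * lr
                            for j in range(d):
                                neu1e[j] += g * syn1[target, j]
                                syn1[target, j] += g * syn0[w, j]
                        for j in range(d):
                            syn0[w, j] += neu1e[j]


def train_embedding(corpus: Sequence[SpectrumDocument],
                    params: TrainingMeta = TrainingMeta()) -> EmbeddingModel:
    """Train word vectors on a document corpus.

    Words occurring fewer than ``min_count`` times are dropped from the
    vocabulary.  With a fixed seed (and the single-threaded kernel) the
    resulting vector matrix is identical run to run.  Negative samples
    are drawn from the unigram distribution raised to the power 0.75.
    """
    if len(corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    longest = max(len(doc) for doc in corpus)
    if params.window < longest:
        warnings.warn(
            f"window ({params.window}) is shorter than the longest document "
            f"({longest} words); context will be truncated", stacklevel=2)
    if params.workers != 1:
        warnings.warn("multi-worker training is not deterministic; "
                      "the kernel runs single-threaded regardless", stacklevel=2)

    word_counts = Counter(w for doc in corpus for w in doc.words)
    kept = [(w, c) for w, c in word_counts.items() if c >= params.min_count]
    kept.sort(key=lambda item: (-item[1], item[0]))  # frequency, then lexicographic
    if not kept:
        raise ValueError("no word reaches min_count; vocabulary is empty")
    vocabulary = {w: i for i, (w, _) in enumerate(kept)}
    counts = np.array([c for _, c in kept], dtype=np.float64)

    encoded = []
    offsets = [0]
    for doc in corpus:
        idx = [vocabulary[w] for w in doc.words if w in vocabulary]
        encoded.extend(idx)
        offsets.append(len(encoded))
    corpus_arr = np.array(encoded, dtype=np.int64)
    offsets_arr = np.array(offsets, dtype=np.int64)

    noise = counts ** 0.75
    cumulative = np.cumsum(noise / noise.sum())
    cumulative[-1] = 1.0

    rng = np.random.RandomState(params.seed)
    d = params.vector_size
    syn0 = (rng.rand(len(vocabulary), d) - 0.5) / d
    syn1 = np.zeros((len(vocabulary), d))

    _train_kernel(corpus_arr, offsets_arr, syn0, syn1, cumulative,
                  params.window, params.epochs, params.negative,
                  params.alpha, params.min_alpha, params.seed,
                  params.mode == "cbow")
    logger.info("trained %s model: %d words, d=%d, %d epochs",
                params.mode, len(vocabulary), d, params.epochs)
    return EmbeddingModel(vocabulary, syn0, params, dict(kept))


def missing_fraction(model: EmbeddingModel, doc: SpectrumDocument) -> float:
    """Intensity-weighted share of the document's words unknown to the model."""
    total = float(sum(doc.weights))
    if total <= 0:
        raise ValueError("document weights must sum to a positive value")
    known = sum(w for word, w in zip(doc.words, doc.weights) if word in model)
    return 1.0 - known / total


def spectrum_vector(model: EmbeddingModel, doc: SpectrumDocument,
                    intensity_power: float = 1.0) -> SpectrumVector:
    """Weighted sum of word vectors, v_S = sum_i w_i * v_i.

    ``intensity_power`` optionally raises the weights to a power before
    summing; the default 1.0 is the plain intensity-weighted sum.
    """
    values = np.zeros(model.vector_size)
    any_known = False
    for word, weight in zip(doc.words, doc.weights):
        if word in model:
            any_known = True
            values += (weight ** intensity_power) * model.word_vector(word)
    if not any_known:
        raise ValueError(
            f"document {doc.source_id!r} has no words in the model vocabulary")
    return SpectrumVector(values=values, missing_fraction=missing_fraction(model, doc))


def vector_similarity(a: SpectrumVector, b: SpectrumVector,
                      allowed_missing: float = 0.05) -> EmbeddingScore:
    """Cosine of two spectrum vectors with missing-fraction policy.

    The score is always reported; when either spectrum's missing
    fraction exceeds ``allowed_missing`` the result is flagged
    unreliable instead of being withheld.
    """
    na = np.linalg.norm(a.values)
    nb = np.linalg.norm(b.values)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero-norm spectrum vector")
    score = float(np.dot(a.values, b.values) / (na * nb))
    reliable = (a.missing_fraction <= allowed_missing
                and b.missing_fraction <= allowed_missing)
    return EmbeddingScore(score=score,
                          missing_fraction_a=a.missing_fraction,
                          missing_fraction_b=b.missing_fraction,
                          reliable=reliable)


def embedding_similarity(model: EmbeddingModel, doc_a: SpectrumDocument,
                         doc_b: SpectrumDocument,
                         allowed_missing: float = 0.05,
                         intensity_power: float = 1.0) -> EmbeddingScore:
    """Document-level convenience wrapper around :func:`vector_similarity`."""
    return vector_similarity(
        spectrum_vector(model, doc_a, intensity_power),
        spectrum_vector(model, doc_b, intensity_power),
        allowed_missing,
    )


def embed_documents(model: EmbeddingModel, docs: Sequence[SpectrumDocument],
                    intensity_power: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Stack spectrum vectors for a document list.

    Returns (matrix of shape (n_docs, d), missing fractions).
    """
    vectors = np.zeros((len(docs), model.vector_size))
    missing = np.zeros(len(docs))
    for i, doc in enumerate(docs):
        sv = spectrum_vector(model, doc, intensity_power)
        vectors[i] = sv.values
        missing[i] = sv.missing_fraction
    return vectors, missing


def embedding_similarity_matrix(queries: Sequence[SpectrumDocument],
                                refs: Sequence[SpectrumDocument],
                                model: EmbeddingModel,
                                intensity_power: float = 1.0) -> np.ndarray:
    """All-vs-all cosine of spectrum vectors; vectors computed once.

    With ``queries is refs`` the result is symmetric with unit
    diagonal.  This brute-force matrix form is what makes embedding
    similarity cheap enough for all-vs-all comparisons: after one pass
    to embed, each entry is a dot product of fixed-length vectors.
    """
    if len(queries) == 0 or len(refs) == 0:
        return np.zeros((len(queries), len(refs)))
    q_vecs, _ = embed_documents(model, queries, intensity_power)
    if queries is refs:
        r_vecs = q_vecs
    else:
        r_vecs, _ = embed_documents(model, refs, intensity_power)
    q_norm = q_vecs / np.linalg.norm(q_vecs, axis=1, keepdims=True)
    r_norm = r_vecs / np.linalg.norm(r_vecs, axis=1, keepdims=True)
    return q_norm @ r_norm.T
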