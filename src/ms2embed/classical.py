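"""Greedy cosine and modified cosine spectral similarity.

Both scores align fragment peaks between two spectra and compute a
normalized sum of intensity products over the aligned pairs:

    score = sum_matched(I_a * I_b) / (sqrt(sum I_a^2) * sqrt(sum I_b^2))

with the norms taken over ALL peaks of each spectrum.  The cosine score
matches peaks whose m/z agree within a tolerance; the modified cosine
additionally allows pairs whose m/z difference equals the precursor
m/z difference (within the same tolerance), so that fragments carrying
an intact modified substructure still align.  Each peak may be matched
at most once — as is, or in its shifted form, never both.

The assignment problem (a maximum-weight matching) is solved greedily:
candidate pairs sorted by descending intensity product are accepted
whenever both endpoints are still free.  Ties break on smaller m/z
difference, then lower peak index, making results platform-stable.
Scores with fewer than ``min_match`` aligned pairs are forced to 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .spectrum import Spectrum

DEFAULT_TOLERANCE = 0.005
DEFAULT_MIN_MATCH_COSINE = 6
DEFAULT_MIN_MATCH_MODIFIED = 10


@dataclass(frozen=True)
class CandidatePair:
    """A potential peak alignment between two spectra."""

    index_a: int
    index_b: int
    product: float  # intensity_a * intensity_b
    delta_mz: float  # |mz_a - mz_b - applied shift|
    shifted: bool


@dataclass(frozen=True)
class ScoreResult:
    """Similarity in [0, 1] plus the number of aligned peak pairs."""

    score: float
    n_matches: int


def collect_candidate_pairs(a: Spectrum, b: Spectrum, tolerance: float = DEFAULT_TOLERANCE,
                            shift: Optional[float] = None) -> list[CandidatePair]:
    """Enumerate peak pairs within tolerance, optionally also shifted ones.

    ``shift`` is the precursor m/z difference (a minus b); shifted
    candidates satisfy ``|mz_a - mz_b - shift| <= tolerance`` and are
    flagged.  With shift = 0, shifted candidates that duplicate an
    unshifted pair are dropped.
    """
    pairs: list[CandidatePair] = []
    shifts: list[tuple[float, bool]] = [(0.0, False)]
    if shift is not None:
        shifts.append((float(shift), True))
    seen: set[tuple[int, int]] = set()
    for offset, flagged in shifts:
        diff = a.mz[:, None] - b.mz[None, :] - offset
        ia, ib = np.nonzero(np.abs(diff) <= tolerance)
        for i, j in zip(ia, ib):
            if (i, j) in seen:
                continue  # shift == 0 duplicates collapse onto unshifted pairs
            seen.add((int(i), int(j)))
            product = float(a.intensities[i] * b.intensities[j])
            if product > 0:
                pairs.append(CandidatePair(int(i), int(j), product,
                                           float(abs(diff[i, j])), flagged))
    return pairs


def greedy_assignment(candidates: Sequence[CandidatePair]) -> list[CandidatePair]:
    """Accept candidates by descending intensity product, each peak once.

    Linear-time matching heuristic for the maximum-weight assignment:
    after sorting (product desc, |delta m/z| asc, index_a asc, index_b
    asc), a candidate is kept iff neither of its peaks is already used
    — across both the shifted and unshifted pools.
    """
    order = sorted(candidates,
                   key=lambda c: (-c.product, c.delta_mz, c.index_a, c.index_b))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matching = []
    for cand in order:
        if cand.index_a in used_a or cand.index_b in used_b:
            continue
        used_a.add(cand.index_a)
        used_b.add(cand.index_b)
        matching.append(cand)
    return matching


def _norms(a: Spectrum, b: Spectrum) -> float:
    return float(np.sqrt(np.sum(a.intensities ** 2)) * np.sqrt(np.sum(b.intensities ** 2)))


def _score_from_matching(a: Spectrum, b: Spectrum, matching: Sequence[CandidatePair],
                         min_match: int) -> ScoreResult:
    norm = _norms(a, b)
    if norm == 0:
        raise ValueError("cannot score a spectrum with all-zero intensities")
    n_matches = len(matching)
    if n_matches < min_match:
        return ScoreResult(score=0.0, n_matches=n_matches)
    raw = sum(c.product for c in matching) / norm
    return ScoreResult(score=min(float(raw), 1.0), n_matches=n_matches)


def cosine_score(a: Spectrum, b: Spectrum, tolerance: float = DEFAULT_TOLERANCE,
                 min_match: int = DEFAULT_MIN_MATCH_COSINE) -> ScoreResult:
    """Greedy cosine similarity of two spectra.

    Pairs with fewer than ``min_match`` aligned peaks score 0.0 (the
    match count is still reported).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot score an empty spectrum")
    matching = greedy_assignment(collect_candidate_pairs(a, b, tolerance))
    return _score_from_matching(a, b, matching, min_match)


def modified_cosine_score(a: Spectrum, b: Spectrum, tolerance: float = DEFAULT_TOLERANCE,
                          min_match: int = DEFAULT_MIN_MATCH_MODIFIED) -> ScoreResult:
    """Cosine variant that also aligns precursor-difference-shifted peaks."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot score an empty spectrum")
    if a.precursor_mz is None or b.precursor_mz is None:
        raise ValueError("modified cosine requires precursor m/z on both spectra")
    shift = a.precursor_mz - b.precursor_mz
    matching = greedy_assignment(collect_candidate_pairs(a, b, tolerance, shift=shift))
    return _score_from_matching(a, b, matching, min_match)


def classical_similarity_matrix(queries: Sequence[Spectrum], refs: Sequence[Spectrum],
                                kind: str = "cosine",
                                tolerance: float = DEFAULT_TOLERANCE,
                                min_match: Optional[int] = None) -> np.ndarray:
    """All-vs-all matrix of cosine or modified-cosine scores.

    When ``queries is refs`` only the upper triangle is computed and
    mirrored.
    """
    if kind == "cosine":
        score_fn, default_min = cosine_score, DEFAULT_MIN_MATCH_COSINE
    elif kind in ("modified-cosine", "modified_cosine"):
        score_fn, default_min = modified_cosine_score, DEFAULT_MIN_MATCH_MODIFIED
    else:
        raise ValueError(f"unknown classical score kind {kind!r}")
    mm = default_min if min_match is None else min_match
    matrix = np.zeros((len(queries), len(refs)))
    symmetric = queries is refs
    for i, q in enumerate(queries):
        start = i if symmetric else 0
        for j in range(start, len(refs)):
            matrix[i, j] = score_fn(q, refs[j], tolerance, mm).score
            if symmetric:
                matrix[j, i] = matrix[i, j]
    return matrix
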