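"""Structural similarity ground truth: Tanimoto over fingerprint bits.

Spectral similarity scores are only proxies; the quantity of interest
is how structurally alike the underlying molecules are.  Following
common practice this package measures structural similarity as the
Tanimoto coefficient (Jaccard index) between fixed-length molecular
fingerprint bit vectors, by default 2048-bit daylight-like path
fingerprints.

Fingerprint generation is delegated to an optional rdkit adapter; all
evaluation workflows equally accept precomputed bit vectors, so nothing
here requires a chemistry dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class FingerprintBitvector:
    """A molecular fingerprint: fixed-length binary vector plus an id."""

    molecule_id: str
    bits: np.ndarray

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=bool)
        if bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        object.__setattr__(self, "bits", bits)

    @property
    def n_bits(self) -> int:
        return len(self.bits)

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, molecule_id: str, hex_string: str, n_bits: Optional[int] = None) -> "FingerprintBitvector":
        raw = np.frombuffer(bytes.fromhex(hex_string), dtype=np.uint8)
        bits = np.unpackbits(raw)
        if n_bits is not None:
            bits = bits[:n_bits]
        return cls(molecule_id=molecule_id, bits=bits.astype(bool))


def tanimoto(p: FingerprintBitvector, q: FingerprintBitvector) -> float:
    """Jaccard index |p AND q| / |p OR q| of two bit vectors."""
    if p.n_bits != q.n_bits:
        raise ValueError(f"fingerprint length mismatch: {p.n_bits} vs {q.n_bits}")
    union = np.count_nonzero(p.bits | q.bits)
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return np.count_nonzero(p.bits & q.bits) / union


def structural_similarity_matrix(fingerprints: Sequence[FingerprintBitvector]) -> np.ndarray:
    """All-vs-all Tanimoto matrix; symmetric, unit diagonal.

    Computed via one integer matrix product: with the bit matrix B,
    intersections are B @ B.T and unions follow from the row popcounts.
    """
    n = len(fingerprints)
    if n == 0:
        return np.zeros((0, 0))
    lengths = {fp.n_bits for fp in fingerprints}
    if len(lengths) > 1:
        raise ValueError("all fingerprints must have the same length")
    bit_matrix = np.stack([fp.bits for fp in fingerprints]).astype(np.int32)
    intersection = bit_matrix @ bit_matrix.T
    popcount = bit_matrix.sum(axis=1)
    union = popcount[:, None] + popcount[None, :] - intersection
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(union > 0, intersection / np.maximum(union, 1), 0.0)
    return matrix


def fraction_above(matrix: np.ndarray, threshold: float) -> float:
    """Fraction of unique off-diagonal pairs with similarity > threshold.

    Self-pairs are excluded; each unordered pair counts once.  This is
    the probability of drawing, uniformly at random, a molecule pair
    whose structural similarity exceeds the threshold.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square similarity matrix")
    iu = np.triu_indices(matrix.shape[0], k=1)
    values = matrix[iu]
    if values.size == 0:
        raise ValueError("matrix has no off-diagonal pairs")
    return float(np.count_nonzero(values > threshold) / values.size)


def fingerprint_from_structure(
    structure: str, molecule_id: Optional[str] = None, n_bits: int = DEFAULT_N_BITS
) -> FingerprintBitvector:
    """Daylight-like path fingerprint from an InChI or SMILES string.

    Pure passthrough to the rdkit adapter — no bespoke chemistry.  When
    rdkit is not installed, precomputed bit vectors (see
    :func:`ms2embed.io.read_fingerprints`) are the supported route.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "rdkit is not installed; supply precomputed fingerprint bit vectors instead"
        ) from exc
    structure = structure.strip()
    if structure.startswith("InChI="):
        mol = Chem.MolFromInchi(structure)
    else:
        mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return FingerprintBitvector(molecule_id=molecule_id or structure, bits=bits)
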