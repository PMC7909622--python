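"""Turn processed spectra into weighted word documents.

Every fragment peak becomes a text token encoding its binned position,
e.g. ``peak@200.45`` at two-decimal precision.  Neutral losses
(precursor m/z minus fragment m/z) between 5.0 and 200.0 Da are added
as ``loss@xxx.xx`` tokens.  The ordered bag of peak and loss words,
with parallel normalized-intensity weights, is the document the
embedding model trains on.

Binning uses round-half-away-from-zero on the decimal representation
(so 200.445 -> 200.45), not binary-float banker's rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .spectrum import Spectrum, normalize_intensities

LOSS_LOW = 5.0
LOSS_HIGH = 200.0


@dataclass(frozen=True)
class SpectrumDocument:
    """Peak/loss words with parallel intensity weights.

    ``words[i]`` was generated by a peak carrying normalized intensity
    ``weights[i]``; loss words inherit the weight of their generating
    peak.  Duplicate words from distinct peaks stay separate tokens —
    dropping them would silently discard intensity mass.
    """

    words: tuple[str, ...]
    weights: tuple[float, ...]
    n_decimals: int = 2
    source_id: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.words) != len(self.weights):
            raise ValueError("words and weights must be parallel sequences")

    def __len__(self) -> int:
        return len(self.words)


def mz_to_word(value: float, n_decimals: int = 2, prefix: str = "peak") -> str:
    """Format an m/z (or loss) value as a ``prefix@...`` token.

    Rounds half away from zero on the printed decimal value, with
    exactly ``n_decimals`` digits (zero-padded).
    """
    if value <= 0:
        raise ValueError("word values must be positive")
    if prefix not in ("peak", "loss"):
        raise ValueError(f"unknown word prefix {prefix!r}")
    quantum = Decimal(1).scaleb(-n_decimals)
    binned = Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{prefix}@{binned:.{n_decimals}f}"


def compute_losses(
    spectrum: Spectrum, low: float = LOSS_LOW, high: float = LOSS_HIGH
) -> list[tuple[float, float]]:
    """Neutral losses ``precursor_mz - peak_mz`` within [low, high].

    Each retained loss carries its generating peak's intensity.  Losses
    are returned sorted ascending by loss value.  Without a precursor
    m/z no losses can be computed and the list is empty.
    """
    if spectrum.precursor_mz is None:
        return []
    losses = spectrum.precursor_mz - spectrum.mz
    keep = (losses >= low) & (losses <= high)
    pairs = list(zip(losses[keep], spectrum.intensities[keep]))
    pairs.sort(key=lambda p: p[0])
    return pairs


def spectrum_to_document(spectrum: Spectrum, n_decimals: int = 2) -> SpectrumDocument:
    """Convert a processed spectrum into its word document.

    Peak words come first (ascending m/z), then loss words (ascending
    loss value); weights are the max-normalized intensities of the
    generating peaks.
    """
    if len(spectrum) == 0:
        raise ValueError("cannot build a document from an empty spectrum")
    spectrum = normalize_intensities(spectrum)
    words = [mz_to_word(mz, n_decimals, "peak") for mz in spectrum.mz]
    weights = list(spectrum.intensities)
    for loss, intensity in compute_losses(spectrum):
        words.append(mz_to_word(loss, n_decimals, "loss"))
        weights.append(intensity)
    return SpectrumDocument(
        words=tuple(words),
        weights=tuple(float(w) for w in weights),
        n_decimals=n_decimals,
        source_id=spectrum.spectrum_id,
    )


def documents_from_spectra(spectra: Sequence[Spectrum], n_decimals: int = 2) -> list[SpectrumDocument]:
    return [spectrum_to_document(s, n_decimals) for s in spectra]


def write_corpus(documents: Sequence[SpectrumDocument], words_path, weights_path) -> None:
    """Serialize a corpus: one document per line, whitespace-separated
    words, with a parallel weights table (same layout) as sidecar."""
    with open(words_path, "w") as wh, open(weights_path, "w") as gh:
        for doc in documents:
            wh.write(" ".join(doc.words) + "\n")
            gh.write(" ".join(f"{w:.8g}" for w in doc.weights) + "\n")


def read_corpus(words_path, weights_path, n_decimals: int = 2) -> list[SpectrumDocument]:
    """Load a corpus written by :func:`write_corpus`."""
    docs = []
    with open(words_path) as wh, open(weights_path) as gh:
        for i, (wline, gline) in enumerate(zip(wh, gh)):
            words = tuple(wline.split())
            weights = tuple(float(v) for v in gline.split())
            docs.append(SpectrumDocument(words=words, weights=weights,
                                         n_decimals=n_decimals, source_id=str(i)))
    return docs
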