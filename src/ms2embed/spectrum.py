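"""Spectrum data model and peak-filtering pipeline.

An MS/MS spectrum is a list of fragment peaks (m/z in Da, unitless
intensity) plus the metadata needed downstream: precursor m/z, neutral
parent mass, InChIKey and ionization mode.  Two distinct processing
tracks are maintained because embedding-based and cosine-type scores
want different peak filtering:

* ``cosine`` track  — drop peaks below 1% relative intensity;
* ``embedding`` track — cap the number of peaks at half the parent mass
  so document length scales with molecule size.

Both tracks share the common front end: restrict m/z to [0, 1000] and
discard spectra with fewer than 10 peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Mass of a proton in Da, used for the parent-mass fallback
#: (assumes a singly protonated, positive-mode ion).
PROTON_MASS = 1.007276


class Peak(NamedTuple):
    """A single fragment peak: m/z in Da, non-negative intensity."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS spectrum: peaks sorted ascending by m/z plus metadata.

    Parameters
    ----------
    mz, intensities
        Parallel arrays of peak positions (Da) and abundances.  They are
        copied and sorted ascending by m/z on construction.
    precursor_mz
        m/z of the ion selected for fragmentation, if known.
    parent_mass
        Neutral monoisotopic mass of the molecule, if known.
    inchikey
        Full InChIKey annotation, or ``None`` for unannotated spectra.
    ionmode
        ``"positive"``, ``"negative"`` or ``"unknown"``.
    spectrum_id
        Opaque identifier, preserved through I/O round trips.
    """

    mz: np.ndarray
    intensities: np.ndarray
    precursor_mz: Optional[float] = None
    parent_mass: Optional[float] = None
    inchikey: Optional[str] = None
    ionmode: str = "unknown"
    spectrum_id: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensities, dtype=np.float64)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensities must be 1-D arrays of equal length")
        if np.any(mz <= 0):
            raise ValueError("all peak m/z values must be positive")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensities", inten[order])
        if self.precursor_mz is not None and self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive when present")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensities)]

    def planar_inchikey(self) -> Optional[str]:
        """First 14 characters of the InChIKey (the 2D-skeleton hash)."""
        if self.inchikey is None:
            return None
        return planar_inchikey(self.inchikey)


def planar_inchikey(inchikey: str) -> str:
    """Return the 14-character planar InChIKey prefix.

    The first block of an InChIKey hashes the molecular skeleton, so
    spectra sharing it are treated as the same 2D structure.
    """
    value = inchikey.strip()[:14].upper()
    if len(value) != 14 or not value.isalpha():
        raise ValueError(f"not a valid planar InChIKey prefix: {value!r}")
    return value


def normalize_intensities(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the base peak has intensity exactly 1."""
    if len(spectrum) == 0:
        raise ValueError("cannot normalize an empty spectrum")
    peak_max = spectrum.intensities.max()
    if peak_max <= 0:
        raise ValueError("cannot normalize a spectrum with all-zero intensities")
    return replace(spectrum, intensities=spectrum.intensities / peak_max)


def filter_mz_range(spectrum: Spectrum, low: float = 0.0, high: float = 1000.0) -> Spectrum:
    """Keep peaks with ``low <= mz <= high`` (closed interval)."""
    if low >= high:
        raise ValueError("low must be smaller than high")
    keep = (spectrum.mz >= low) & (spectrum.mz <= high)
    return replace(spectrum, mz=spectrum.mz[keep], intensities=spectrum.intensities[keep])


def require_minimum_peaks(spectrum: Spectrum, n: int = 10) -> Optional[Spectrum]:
    """Return the spectrum iff it has at least ``n`` peaks, else ``None``.

    Rejection is a value, not an error: pipelines drop the ``None``s and
    log the count.
    """
    return spectrum if len(spectrum) >= n else None


def select_by_relative_intensity(spectrum: Spectrum, threshold: float = 0.01) -> Spectrum:
    """Keep peaks whose intensity is >= ``threshold`` of the base peak.

    Peaks at exactly the threshold are kept (only strictly smaller
    relative intensities count as noise).
    """
    if len(spectrum) == 0:
        raise ValueError("relative-intensity filter needs at least one peak")
    peak_max = spectrum.intensities.max()
    keep = spectrum.intensities >= threshold * peak_max
    return replace(spectrum, mz=spectrum.mz[keep], intensities=spectrum.intensities[keep])


def estimate_parent_mass(spectrum: Spectrum) -> float:
    """Parent mass from metadata, falling back to precursor_mz − m(H+).

    The fallback assumes a singly protonated positive-mode ion; it is an
    assumption, logged at debug level, for spectra whose metadata lacks
    an explicit parent mass.
    """
    if spectrum.parent_mass is not None:
        return float(spectrum.parent_mass)
    if spectrum.precursor_mz is not None:
        logger.debug(
            "spectrum %s: parent mass estimated as precursor_mz - %.6f (assumed [M+H]+)",
            spectrum.spectrum_id, PROTON_MASS,
        )
        return float(spectrum.precursor_mz) - PROTON_MASS
    raise ValueError("neither parent_mass nor precursor_mz available")


def reduce_to_top_peaks(spectrum: Spectrum) -> Spectrum:
    """Cap the peak count at floor(0.5 * parent_mass).

    Larger molecules are expected to yield more informative fragments,
    so the cap scales linearly with parent mass.  When the spectrum has
    no more peaks than the cap it is returned unchanged.  Kept peaks are
    the most intense ones, re-sorted ascending by m/z.
    """
    parent_mass = estimate_parent_mass(spectrum)
    cap = int(np.floor(0.5 * parent_mass))
    if len(spectrum) <= cap:
        return spectrum
    # stable sort on -intensity keeps lower-m/z peaks on intensity ties
    order = np.argsort(-spectrum.intensities, kind="stable")[:cap]
    order.sort()
    return replace(spectrum, mz=spectrum.mz[order], intensities=spectrum.intensities[order])


@dataclass(frozen=True)
class ProcessingConfig:
    """Selects and parameterizes one of the two filtering tracks."""

    track: str = "embedding"  # "embedding" or "cosine"
    mz_low: float = 0.0
    mz_high: float = 1000.0
    min_peaks: int = 10
    relative_intensity_threshold: float = 0.01
    normalize: bool = True

    def __post_init__(self):
        if self.track not in ("embedding", "cosine"):
            raise ValueError(f"unknown processing track: {self.track!r}")


def process_spectrum(spectrum: Spectrum, config: ProcessingConfig = ProcessingConfig()) -> Optional[Spectrum]:
    """Run one spectrum through the configured filtering track.

    Returns ``None`` when the spectrum is rejected (fewer than
    ``min_peaks`` peaks after the m/z-range filter, or no positive
    intensity left).
    """
    s = filter_mz_range(spectrum, config.mz_low, config.mz_high)
    s = require_minimum_peaks(s, config.min_peaks)
    if s is None or s.intensities.max() <= 0:
        return None
    if config.track == "cosine":
        s = select_by_relative_intensity(s, config.relative_intensity_threshold)
    else:
        try:
            s = reduce_to_top_peaks(s)
        except ValueError:
            # no parent mass and no precursor: leave the peak list uncapped
            logger.debug("spectrum %s: no parent mass, peak cap skipped", s.spectrum_id)
    if config.normalize:
        s = normalize_intensities(s)
    return s


def process_spectra(
    spectra: Iterable[Spectrum], config: ProcessingConfig = ProcessingConfig()
) -> list[Spectrum]:
    """Filter a collection, dropping rejected spectra and logging counts."""
    kept: list[Spectrum] = []
    n_in = 0
    for s in spectra:
        n_in += 1
        out = process_spectrum(s, config)
        if out is not None:
            kept.append(out)
    logger.info("processing (%s track): kept %d of %d spectra", config.track, len(kept), n_in)
    return kept
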