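"""Readers and writers for spectral library formats.

Supported formats: MGF (BEGIN IONS/END IONS blocks, via pyteomics), the
NIST-style MSP text dialect, and GNPS-style JSON (a list of records with
``peaks_json`` strings).  Metadata keys are matched case-insensitively.
Unparseable records are skipped with a logged warning rather than
aborting the whole read.

Fingerprint bit vectors travel as two-column hex tables
(``molecule_id<TAB>hex``), one row per molecule.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .spectrum import Spectrum
from .structural import FingerprintBitvector

logger = logging.getLogger(__name__)

_FORMATS = ("mgf", "msp", "json")


def _lower_keys(d: dict) -> dict:
    return {str(k).lower(): v for k, v in d.items()}


def _get(meta: dict, *keys: str):
    for key in keys:
        if key in meta and meta[key] not in ("", None, "N/A", "n/a"):
            return meta[key]
    return None


def _first_scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def read_spectra(path, format: Optional[str] = None) -> list[Spectrum]:
    """Read a spectral library file into a list of :class:`Spectrum`.

    Parameters
    ----------
    path
        File to read.
    format
        ``"mgf"``, ``"msp"`` or ``"json"``; inferred from the file
        suffix when omitted.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown spectral format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt == "msp":
        return _read_msp(path)
    return _read_gnps_json(path)


def _build_spectrum(mz, intensities, meta: dict, default_id: str) -> Spectrum:
    precursor_mz = _get(meta, "precursor_mz", "pepmass", "precursormz")
    precursor_mz = _first_scalar(precursor_mz)
    parent_mass = _first_scalar(_get(meta, "parent_mass", "parentmass", "exactmass"))
    inchikey = _get(meta, "inchikey", "inchiaux", "inchi_key")
    ionmode = str(_get(meta, "ionmode", "ion_mode") or "unknown").lower()
    if ionmode not in ("positive", "negative"):
        ionmode = "unknown"
    spectrum_id = _get(meta, "spectrum_id", "spectrumid", "title", "name") or default_id
    return Spectrum(
        mz=np.asarray(mz, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
        precursor_mz=float(precursor_mz) if precursor_mz is not None else None,
        parent_mass=float(parent_mass) if parent_mass is not None else None,
        inchikey=str(inchikey) if inchikey else None,
        ionmode=ionmode,
        spectrum_id=str(spectrum_id),
        metadata=meta,
    )


def _read_mgf(path: Path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, record in enumerate(reader):
            try:
                meta = _lower_keys(record.get("params", {}))
                spectra.append(
                    _build_spectrum(record["m/z array"], record["intensity array"], meta, f"mgf:{i}")
                )
            except Exception as exc:  # noqa: BLE001 - per-record skip policy
                logger.warning("skipping unparseable MGF record %d in %s: %s", i, path, exc)
    return spectra


def _read_msp(path: Path) -> list[Spectrum]:
    """Parse the ``Name:`` / ``Num Peaks:`` MSP dialect."""
    spectra = []
    meta: dict = {}
    peaks: list[tuple[float, float]] = []
    index = 0

    def flush():
        nonlocal meta, peaks, index
        if meta or peaks:
            try:
                mz, inten = zip(*peaks) if peaks else ((), ())
                spectra.append(_build_spectrum(mz, inten, meta, f"msp:{index}"))
            except Exception as exc:  # noqa: BLE001
                logger.warning("skipping unparseable MSP record %d in %s: %s", index, path, exc)
            index += 1
        meta, peaks = {}, []

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().lower().replace(" ", "_")
                if key == "name" and meta:
                    flush()
                if key != "num_peaks":
                    meta[key] = value.strip()
                continue
            fields = line.replace(";", " ").split()
            for k in range(0, len(fields) - 1, 2):
                peaks.append((float(fields[k]), float(fields[k + 1])))
    flush()
    return spectra


def _read_gnps_json(path: Path) -> list[Spectrum]:
    with open(path) as handle:
        records = json.load(handle)
    spectra = []
    for i, record in enumerate(records):
        try:
            meta = _lower_keys(record)
            peaks = meta.pop("peaks_json", "[]")
            if isinstance(peaks, str):
                peaks = json.loads(peaks)
            peaks = np.asarray(peaks, dtype=float).reshape(-1, 2)
            spectra.append(_build_spectrum(peaks[:, 0], peaks[:, 1], meta, f"json:{i}"))
        except Exception as exc:  # noqa: BLE001
            logger.warning("skipping unparseable JSON record %d in %s: %s", i, path, exc)
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF (PEPMASS/TITLE + optional metadata keys)."""
    records = []
    for s in spectra:
        params = {"title": s.spectrum_id or ""}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.parent_mass is not None:
            params["parent_mass"] = s.parent_mass
        if s.inchikey:
            params["inchikey"] = s.inchikey
        if s.ionmode != "unknown":
            params["ionmode"] = s.ionmode
        records.append(
            {"m/z array": s.mz, "intensity array": s.intensities, "params": params}
        )
    _mgf.write(records, str(path), file_mode="w")


def write_gnps_json(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra in the GNPS-style JSON dialect this module reads."""
    records = []
    for s in spectra:
        record = {
            "spectrum_id": s.spectrum_id,
            "peaks_json": json.dumps([[float(m), float(i)] for m, i in zip(s.mz, s.intensities)]),
            "Ion_Mode": s.ionmode,
        }
        if s.precursor_mz is not None:
            record["Precursor_MZ"] = str(s.precursor_mz)
        if s.parent_mass is not None:
            record["Parent_Mass"] = str(s.parent_mass)
        if s.inchikey:
            record["InChIKey"] = s.inchikey
        records.append(record)
    with open(path, "w") as handle:
        json.dump(records, handle)


def write_fingerprints(fingerprints: Iterable[FingerprintBitvector], path) -> None:
    """Write bit vectors as an ``id<TAB>hex`` table, one row per molecule."""
    with open(path, "w") as handle:
        for fp in fingerprints:
            handle.write(f"{fp.molecule_id}\t{fp.to_hex()}\n")


def read_fingerprints(path, n_bits: Optional[int] = None) -> list[FingerprintBitvector]:
    """Read an ``id<TAB>hex`` fingerprint table."""
    out = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            molecule_id, hex_string = line.split("\t")
            out.append(FingerprintBitvector.from_hex(molecule_id, hex_string, n_bits=n_bits))
    return out


def write_similarity_matrix(matrix: np.ndarray, labels: Sequence[str], path) -> None:
    """Write a labeled similarity matrix as TSV (row/column headers)."""
    matrix = np.asarray(matrix)
    with open(path, "w") as handle:
        handle.write("\t" + "\t".join(labels) + "\n")
        for label, row in zip(labels, matrix):
            handle.write(label + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_similarity_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a TSV similarity matrix written by :func:`write_similarity_matrix`."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in handle:
            rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
    return np.asarray(rows, dtype=float), header
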