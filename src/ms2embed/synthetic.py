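"""Synthetic spectra/fingerprint benchmarks with exact structural ground truth.

Real spectral libraries couple two unknowns: how spectra relate to each
other and how molecules relate to each other.  The generator decouples
them with a *substructure block* model: a fixed pool of blocks, each
owning a disjoint set of fingerprint bits and a disjoint set of
characteristic fragments.  A synthetic molecule is a union of blocks,
so molecules sharing blocks share both fingerprint bits and fragment
peaks, and the Tanimoto similarity between two molecules is exactly

    shared blocks / union of blocks

by construction.  Spectra are noisy renderings of a molecule's fragment
profile (dropout, intensity and m/z jitter, spurious peaks), several
per molecule, which makes spectral-vs-structural correlation testable
offline: an informative spectral score must rank same-molecule and
shared-block pairs above unrelated ones.

Molecular *families* are created by mutating an existing molecule's
block set one block at a time, so the benchmark contains close analogs
(Tanimoto 0.5-0.7), not just random overlap.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .spectrum import PROTON_MASS, Spectrum
from .structural import FingerprintBitvector
from . import io as msio


@dataclass(frozen=True)
class SyntheticMolecule:
    """A block-model molecule: fingerprint + fragment profile + parent mass."""

    molecule_id: str
    blocks: tuple[int, ...]
    fingerprint: FingerprintBitvector
    fragment_mz: np.ndarray
    fragment_intensity: np.ndarray
    parent_mass: float

    @property
    def inchikey(self) -> str:
        """Synthetic InChIKey-like identifier (planar part = molecule_id)."""
        return f"{self.molecule_id}-SYNTHETICFPAA-N"


@dataclass(frozen=True)
class NoiseParams:
    """Spectrum-level noise: dropout, jitter, spurious peaks."""

    dropout: float = 0.1            # per-fragment omission probability
    intensity_jitter: float = 0.1   # sd of multiplicative log-normal jitter
    mz_jitter: float = 0.002        # sd (Da) of additive m/z jitter
    n_spurious: int = 3             # uniform-random noise peaks added

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be a probability < 1")
        if self.intensity_jitter < 0 or self.mz_jitter < 0 or self.n_spurious < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Experimental design knobs for :func:`generate_benchmark`."""

    n_molecules: int = 200
    n_blocks: int = 40
    blocks_per_molecule: int = 4
    fragments_per_block: int = 8
    spectra_per_molecule: int = 4
    n_queries: int = 100
    mode: str = "library-split"  # or "unknown"
    family_prob: float = 0.5     # chance a molecule mutates an earlier one
    n_bits: int = 2048
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self):
        if self.mode not in ("library-split", "unknown"):
            raise ValueError(f"unknown benchmark mode {self.mode!r}")
        if self.blocks_per_molecule > self.n_blocks:
            raise ValueError("blocks_per_molecule cannot exceed n_blocks")
        if self.n_blocks * 1 > self.n_bits:
            raise ValueError("need at least one fingerprint bit per block")


def _molecule_ids(n: int, rng: np.random.Generator) -> list[str]:
    letters = np.array(list(string.ascii_uppercase))
    ids: set[str] = set()
    while len(ids) < n:
        ids.add("".join(rng.choice(letters, size=14)))
    return sorted(ids)


def generate_molecule_set(n_molecules: int, n_blocks: int = 40,
                          blocks_per_molecule: int = 4, seed: int = 0,
                          fragments_per_block: int = 8, n_bits: int = 2048,
                          family_prob: float = 0.5,
                          mz_range: tuple[float, float] = (50.0, 440.0),
                          parent_mass_range: tuple[float, float] = (460.0, 640.0),
                          ) -> list[SyntheticMolecule]:
    """Draw a molecule set from the block model; deterministic per seed.

    Each of the ``n_blocks`` blocks owns ``n_bits // n_blocks`` disjoint
    fingerprint bits and ``fragments_per_block`` fragments (m/z uniform
    in ``mz_range``, base intensity uniform in [0.05, 1]).  With
    probability ``family_prob`` a new molecule is a one-block mutation
    of a random earlier molecule, producing structural analogs; the
    Tanimoto of any two molecules equals their block-overlap ratio
    exactly.
    """
    if blocks_per_molecule > n_blocks:
        raise ValueError("blocks_per_molecule cannot exceed n_blocks")
    bits_per_block = n_bits // n_blocks
    if bits_per_block < 1:
        raise ValueError("n_bits too small for the requested number of blocks")
    rng = np.random.default_rng(seed)

    block_mz = [np.sort(rng.uniform(*mz_range, size=fragments_per_block))
                for _ in range(n_blocks)]
    block_intensity = [rng.uniform(0.05, 1.0, size=fragments_per_block)
                       for _ in range(n_blocks)]

    ids = _molecule_ids(n_molecules, rng)
    block_sets: list[tuple[int, ...]] = []
    for i in range(n_molecules):
        if i > 0 and rng.random() < family_prob:
            parent = list(block_sets[rng.integers(0, i)])
            free = [b for b in range(n_blocks) if b not in parent]
            parent[rng.integers(0, len(parent))] = int(rng.choice(free))
            blocks = tuple(sorted(set(parent)))
        else:
            blocks = tuple(sorted(rng.choice(n_blocks, size=blocks_per_molecule,
                                             replace=False).tolist()))
        block_sets.append(blocks)

    molecules = []
    for mol_id, blocks in zip(ids, block_sets):
        bits = np.zeros(n_bits, dtype=bool)
        for b in blocks:
            bits[b * bits_per_block:(b + 1) * bits_per_block] = True
        mz = np.concatenate([block_mz[b] for b in blocks])
        intensity = np.concatenate([block_intensity[b] for b in blocks])
        order = np.argsort(mz)
        molecules.append(SyntheticMolecule(
            molecule_id=mol_id,
            blocks=blocks,
            fingerprint=FingerprintBitvector(molecule_id=mol_id, bits=bits),
            fragment_mz=mz[order],
            fragment_intensity=intensity[order],
            parent_mass=float(rng.uniform(*parent_mass_range)),
        ))
    return molecules


def block_overlap_tanimoto(a: SyntheticMolecule, b: SyntheticMolecule) -> float:
    """Closed-form Tanimoto from block overlap (the generator's ground truth)."""
    sa, sb = set(a.blocks), set(b.blocks)
    return len(sa & sb) / len(sa | sb)


def generate_spectrum(molecule: SyntheticMolecule,
                      noise: NoiseParams = NoiseParams(),
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None,
                      spectrum_id: Optional[str] = None) -> Spectrum:
    """One noisy spectrum of a molecule; deterministic per seed.

    Fragments are dropped out independently (at least 10 always
    retained), intensities get multiplicative log-normal jitter, m/z
    get additive Gaussian jitter, and ``n_spurious`` uniform noise
    peaks are appended.  The precursor m/z is parent mass + m(H+),
    exact, so precursor-window preselection behaves as with calibrated
    instruments.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_frag = len(molecule.fragment_mz)
    if n_frag < 10:
        raise ValueError("molecule has fewer than 10 fragments; cannot guarantee "
                         "a 10-peak spectrum")
    keep = rng.random(n_frag) >= noise.dropout
    if keep.sum() < 10:
        dropped = np.nonzero(~keep)[0]
        revive = rng.choice(dropped, size=10 - int(keep.sum()), replace=False)
        keep[revive] = True
    mz = molecule.fragment_mz[keep] + rng.normal(0.0, noise.mz_jitter, size=int(keep.sum()))
    intensity = molecule.fragment_intensity[keep] * np.exp(
        rng.normal(0.0, noise.intensity_jitter, size=int(keep.sum())))
    if noise.n_spurious:
        mz = np.concatenate([mz, rng.uniform(50.0, molecule.parent_mass,
                                             size=noise.n_spurious)])
        intensity = np.concatenate([intensity,
                                    rng.uniform(0.01, 0.3, size=noise.n_spurious)])
    mz = np.clip(mz, 1.0, None)
    return Spectrum(
        mz=mz,
        intensities=intensity,
        precursor_mz=molecule.parent_mass + PROTON_MASS,
        parent_mass=molecule.parent_mass,
        inchikey=molecule.inchikey,
        ionmode="positive",
        spectrum_id=spectrum_id or f"{molecule.molecule_id}_s{seed}",
    )


@dataclass(frozen=True)
class Benchmark:
    """A generated study: corpus, library, queries and ground truth."""

    training_spectra: list[Spectrum]
    library_spectra: list[Spectrum]
    query_spectra: list[Spectrum]
    truth: dict  # query spectrum_id -> planar molecule id
    fingerprints: list[FingerprintBitvector]
    molecules: list[SyntheticMolecule]
    config: BenchmarkConfig
    seed: int

    def library_annotations(self) -> dict:
        return {s.spectrum_id: s.planar_inchikey() for s in self.library_spectra}


def generate_benchmark(config: BenchmarkConfig = BenchmarkConfig(),
                       seed: int = 0) -> Benchmark:
    """Generate a full benchmark in one of two experimental designs.

    ``library-split``: every query spectrum's molecule keeps at least
    one other spectrum in the library (and training corpus), emulating
    matching against a library that contains the right answer.

    ``unknown``: all spectra of the query molecules are removed from
    both library and training corpus, emulating analog search for
    compounds the model has never seen.
    """
    rng = np.random.default_rng(seed)
    molecules = generate_molecule_set(
        config.n_molecules, config.n_blocks, config.blocks_per_molecule,
        seed=int(rng.integers(0, 2**31 - 1)),
        fragments_per_block=config.fragments_per_block,
        n_bits=config.n_bits, family_prob=config.family_prob)

    spectra_by_molecule: dict[str, list[Spectrum]] = {}
    for molecule in molecules:
        spectra_by_molecule[molecule.molecule_id] = [
            generate_spectrum(molecule, config.noise, rng=rng,
                              spectrum_id=f"{molecule.molecule_id}_s{k}")
            for k in range(config.spectra_per_molecule)
        ]

    truth: dict = {}
    queries: list[Spectrum] = []
    library: list[Spectrum] = []

    if config.mode == "library-split":
        eligible = [m.molecule_id for m in molecules
                    if len(spectra_by_molecule[m.molecule_id]) >= 2]
        n_queries = min(config.n_queries, len(eligible))
        chosen = rng.choice(eligible, size=n_queries, replace=False)
        chosen_set = set(str(c) for c in chosen)
        for molecule in molecules:
            spectra = spectra_by_molecule[molecule.molecule_id]
            if molecule.molecule_id in chosen_set:
                query = spectra[int(rng.integers(0, len(spectra)))]
                queries.append(query)
                truth[query.spectrum_id] = molecule.molecule_id
                library.extend(s for s in spectra if s.spectrum_id != query.spectrum_id)
            else:
                library.extend(spectra)
        training = library
    else:  # unknown-compound mode: query molecules fully held out
        n_query_molecules = min(config.n_queries, config.n_molecules - 1)
        chosen = rng.choice([m.molecule_id for m in molecules],
                            size=n_query_molecules, replace=False)
        chosen_set = set(str(c) for c in chosen)
        for molecule in molecules:
            spectra = spectra_by_molecule[molecule.molecule_id]
            if molecule.molecule_id in chosen_set:
                for query in spectra:
                    queries.append(query)
                    truth[query.spectrum_id] = molecule.molecule_id
            else:
                library.extend(spectra)
        training = library

    return Benchmark(
        training_spectra=list(training),
        library_spectra=library,
        query_spectra=queries,
        truth=truth,
        fingerprints=[m.fingerprint for m in molecules],
        molecules=molecules,
        config=config,
        seed=seed,
    )


def write_benchmark(benchmark: Benchmark, directory) -> None:
    """Emit the benchmark as MGF + fingerprint hex table + truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    msio.write_mgf(benchmark.library_spectra, directory / "library.mgf")
    msio.write_mgf(benchmark.query_spectra, directory / "queries.mgf")
    msio.write_fingerprints(benchmark.fingerprints, directory / "fingerprints.tsv")
    with open(directory / "truth.tsv", "w") as handle:
        handle.write(f"# seed={benchmark.seed} mode={benchmark.config.mode}\n")
        for query_id, molecule_id in sorted(benchmark.truth.items()):
            handle.write(f"{query_id}\t{molecule_id}\n")
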