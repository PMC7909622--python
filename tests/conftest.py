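import numpy as np
import pytest

import ms2embed as m


@pytest.fixture(scope="session")
def small_benchmark():
    """A modest library-split benchmark shared across test modules."""
    config = m.BenchmarkConfig(n_molecules=60, n_queries=30)
    return m.generate_benchmark(config, seed=0)


@pytest.fixture(scope="session")
def small_model(small_benchmark):
    """Embedding model trained on the small benchmark's library corpus."""
    lib = m.process_spectra(small_benchmark.training_spectra,
                            m.ProcessingConfig(track="embedding"))
    corpus = m.documents_from_spectra(lib)
    meta = m.TrainingMeta(vector_size=50, epochs=15, seed=0)
    return m.train_embedding(corpus, meta), corpus, lib


@pytest.fixture
def simple_spectrum():
    return m.Spectrum(
        mz=[100.0, 150.0, 300.0],
        intensities=[0.5, 1.0, 0.25],
        precursor_mz=400.0,
        parent_mass=398.992724,
        inchikey="ABCDEFGHIJKLMN-UHFFFAOYSA-N",
        ionmode="positive",
        spectrum_id="simple",
    )


def random_spectrum(rng, n_peaks=30, precursor=None, mz_range=(50.0, 500.0)):
    mz = np.sort(rng.uniform(*mz_range, size=n_peaks))
    intensities = rng.uniform(0.01, 1.0, size=n_peaks)
    return m.Spectrum(mz=mz, intensities=intensities, precursor_mz=precursor,
                      spectrum_id=f"rand{rng.integers(1 << 30)}")
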