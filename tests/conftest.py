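import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

import leafspec as ls
from leafspec.spectra import Spectrum, SpectralRecord


@pytest.fixture(scope="session")
def small_dataset():
    """12 genotypes x 3 reps from the default generator world (fast)."""
    cfg = ls.GeneratorConfig(n_genotypes=12, repetitions=3, seed=42)
    return ls.generate_dataset(cfg)


@pytest.fixture(scope="session")
def full_grid():
    return np.arange(350, 2501, dtype=np.int64)


@pytest.fixture()
def smooth_spectrum(full_grid):
    """Gently curving full-range spectrum (near-linear at the junctions)."""
    w = full_grid.astype(float)
    r = 0.40 + 2e-5 * (w - 350.0) + 0.01 * np.sin(w / 800.0)
    return Spectrum(full_grid, r)


def make_record(reflectance, grid, genotype="G0", experiment="exp", repetition=1, leaf_replicate=1):
    return SpectralRecord(
        spectrum=Spectrum(grid, reflectance),
        genotype=genotype,
        experiment=experiment,
        repetition=repetition,
        leaf_replicate=leaf_replicate,
    )


@pytest.fixture()
def flat_record_factory(full_grid):
    def factory(level, **kw):
        return make_record(np.full(full_grid.size, level), full_grid, **kw)

    return factory
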