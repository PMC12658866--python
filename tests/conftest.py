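import numpy as np
import pytest

from mapperms import (
    BinRange,
    RawSpectrum,
    SampleRun,
    SeparationParams,
    SynthConfig,
    generate_dataset,
    vectorize_run,
)


@pytest.fixture(scope="session")
def params():
    return SeparationParams()  # ε = 0.08, r = 0.3


@pytest.fixture
def tiny_run():
    """Three spectra at distinct retention coordinates."""
    return SampleRun(
        sample_id="T1",
        spectra=[
            RawSpectrum(600.0, 1.0, np.array([29.3, 29.6, 30.9]),
                        np.array([5.0, 7.0, 2.0])),
            RawSpectrum(3000.0, 1.0, np.array([30.1, 30.4]),
                        np.array([4.0, 9.0])),
            RawSpectrum(5400.0, 1.0, np.array([29.0]), np.array([3.0])),
        ],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """K=4 synthetic dataset small enough for per-test pipelines."""
    cfg = SynthConfig(
        K=4,
        n_spectra=120,
        bins=BinRange(29, 128),
        n_shared=5,
        n_unique_per_sample=1,
        planted_groups=((0, 1), (2, 3)),
        n_group_templates_per_member=2,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    runs, truth = small_dataset
    bins = truth.config.bins
    return {r.sample_id: vectorize_run(r, bins) for r in runs}


def on_sphere(tangent: dict[int, float], dim: int = 8) -> np.ndarray:
    """Unit vector near e_0 with the given tangent components (axis→value).

    Chordal distances between such points equal tangent-plane distances to
    second order, letting tests plant distances to ~1e-5 accuracy.
    """
    v = np.zeros(dim)
    for ax, val in tangent.items():
        v[ax] = val
    rest = 1.0 - np.sum(v**2)
    assert rest > 0
    v[0] = np.sqrt(rest)
    return v
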