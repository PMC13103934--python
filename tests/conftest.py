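import numpy as np
import pytest

import spectrakit as sk
from spectrakit.synth import Peak, SyntheticSpec


@pytest.fixture
def small_set() -> sk.SpectrumSet:
    """Tiny 2-spectrum set on a 3-point axis."""
    return sk.SpectrumSet(
        axis=np.array([400.0, 401.0, 402.0]),
        intensities=np.array([[10.0, 12.0, 11.0], [9.0, 13.0, 10.0]]),
        labels=("a", "b"),
    )


@pytest.fixture
def bsa_set():
    """Default BSA-like replicate set with its ground truth."""
    return sk.generate_spectra(sk.bsa_like_spec(seed=11))


@pytest.fixture
def two_class_set() -> sk.SpectrumSet:
    """Default two-analyte (BPE-like / R6G-like) class-structured set."""
    return sk.generate_two_class(sk.bpe_like_spec(seed=7), sk.r6g_like_spec(seed=7))


@pytest.fixture
def linear_baseline_set():
    """Noise-free linear baseline (slope 0.5, intercept 100) + 3 Lorentzians."""
    spec = SyntheticSpec(
        axis_start=600.0,
        axis_stop=1600.0,
        axis_step=1.0,
        peaks=(Peak(800.0, 500.0, 10.0), Peak(1100.0, 700.0, 9.0), Peak(1400.0, 400.0, 11.0)),
        baseline_poly=(100.0, 0.5),
        n_replicates=1,
        seed=0,
    )
    return sk.generate_spectra(spec)


def fig4_chain_steps():
    """The canonical preprocessing chain with its standard parameters."""
    return [
        {"op": "interpolate_to_grid"},
        {"op": "crop", "lo": 600, "hi": 1600},
        {"op": "despike", "regions": [(600, 750), (1050, 1150)],
         "threshold": 300, "window": 11},
        {"op": "smooth_savgol", "window": 15, "polyorder": 2},
        {"op": "baseline_airpls", "lam": 100, "order": 1,
         "max_iter": 15, "tol": 0.001},
        {"op": "normalize", "mode": "area"},
    ]


def random_set(rng: np.random.Generator, n: int | None = None,
               m: int | None = None) -> sk.SpectrumSet:
    """Random non-degenerate SpectrumSet for property tests."""
    n = n if n is not None else int(rng.integers(2, 6))
    m = m if m is not None else int(rng.integers(5, 40))
    axis = np.sort(rng.uniform(400, 1800, size=m))
    while np.any(np.diff(axis) <= 0):  # pragma: no cover - vanishing chance
        axis = np.sort(rng.uniform(400, 1800, size=m))
    intensities = rng.normal(100, 30, size=(n, m))
    return sk.SpectrumSet(axis, intensities, tuple(f"s{i}" for i in range(n)))
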