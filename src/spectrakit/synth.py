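"""Seeded generator of realistic Raman/SERS fixtures with known ground truth.

Each replicate is built as

    baseline + peaks + Gaussian noise + cosmic-ray spikes

where the baseline is a polynomial plus optional broad fluorescence humps,
peaks are Gaussian or Lorentzian vibrational bands, and spikes are
single-sample positive excursions.  Replicate-to-replicate variation comes
from a global peak-amplitude jitter and an independent baseline scale per
replicate.  Every random draw derives from one stream per replicate, seeded
by (seed, replicate index), so growing N never reshuffles earlier
replicates and an identical seed reproduces the set bit-identically.

Profile conventions (amplitude = apex height, c = center, w = width):

* Lorentzian: ``A * w^2 / ((x - c)^2 + w^2)``  (w is the HWHM)
* Gaussian:   ``A * exp(-(x - c)^2 / (2 w^2))``  (w is the SD)

The module also ships ready-made specs emulating the demonstration
analytes: a BSA-like protein replicate set (broad fluorescence background,
five bands between 600 and 1600 cm^-1, cosmic spikes near 700 and 1100)
and a BPE-like / R6G-like two-analyte pair with disjoint band positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import SpectrumSet, merge_sets

__all__ = [
    "Peak",
    "Hump",
    "Spike",
    "SyntheticSpec",
    "TruthRecord",
    "generate_spectra",
    "generate_two_class",
    "bsa_like_spec",
    "bpe_like_spec",
    "r6g_like_spec",
]


@dataclass(frozen=True)
class Peak:
    center: float  # cm^-1
    amplitude: float  # apex height, intensity units
    width: float  # HWHM (lorentzian) or SD (gaussian), cm^-1
    shape: str = "lorentzian"  # or "gaussian"


@dataclass(frozen=True)
class Hump:
    """Broad background component (always Gaussian, width >= 200 cm^-1)."""

    center: float
    amplitude: float
    width: float


@dataclass(frozen=True)
class Spike:
    position: float  # cm^-1, snapped to the nearest grid point
    amplitude: float  # must exceed the noise SD


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a synthetic replicate set."""

    axis_start: float = 400.0
    axis_stop: float = 1800.0
    axis_step: float = 1.0
    peaks: tuple[Peak, ...] = ()
    baseline_poly: tuple[float, ...] = (0.0,)  # ascending coefficients in x
    humps: tuple[Hump, ...] = ()
    noise_sd: float = 0.0
    spikes: tuple[Spike, ...] = ()  # applied to every replicate
    spike_count: int = 0  # alternative: random positions per replicate
    spike_amp_range: tuple[float, float] = (0.0, 0.0)
    n_replicates: int = 5
    amplitude_jitter: float = 0.0  # fractional SD of the global peak scale
    baseline_jitter: float = 0.0  # fractional SD of the baseline scale
    seed: int = 0
    label_prefix: str = "rep"
    group: str | None = None

    def __post_init__(self) -> None:
        if self.axis_step <= 0 or self.axis_stop <= self.axis_start:
            raise ValueError("axis must have positive step and extent")
        for p in self.peaks:
            if p.width <= 0:
                raise ValueError(f"peak width must be > 0: {p}")
            if p.amplitude < 0:
                raise ValueError(f"peak amplitude must be >= 0: {p}")
            if p.shape not in ("gaussian", "lorentzian"):
                raise ValueError(f"unknown peak shape {p.shape!r}")
        for h in self.humps:
            if h.width < 200:
                raise ValueError(
                    f"broad-hump width must be >= 200 cm^-1, got {h.width}"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for s in self.spikes:
            if self.noise_sd > 0 and s.amplitude <= self.noise_sd:
                raise ValueError(
                    f"spike amplitude {s.amplitude} must exceed noise SD "
                    f"{self.noise_sd}"
                )
        if self.spike_count > 0 and self.spikes:
            raise ValueError("give either a spike table or spike_count, not both")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def axis(self) -> np.ndarray:
        n = int(np.floor((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)


@dataclass(frozen=True)
class TruthRecord:
    """Noise-free components of every replicate, for truth-based testing.

    ``baseline + peaks + noise + spikes`` reconstructs the generated
    intensities exactly (identical floating-point expression).
    """

    baseline: np.ndarray  # N x M noise-free baseline per replicate
    peaks: np.ndarray  # N x M noise-free peaks-only signal
    noise: np.ndarray  # N x M additive noise realization
    spikes: np.ndarray  # N x M spike contribution (single samples)
    spike_positions: tuple[np.ndarray, ...]  # per replicate, cm^-1
    peak_centers: np.ndarray  # spec peak centers, cm^-1


def _profile(x: np.ndarray, peak: Peak) -> np.ndarray:
    if peak.shape == "lorentzian":
        return peak.amplitude * peak.width**2 / ((x - peak.center) ** 2 + peak.width**2)
    return peak.amplitude * np.exp(-((x - peak.center) ** 2) / (2.0 * peak.width**2))


def generate_spectra(spec: SyntheticSpec) -> tuple[SpectrumSet, TruthRecord]:
    """Generate a replicate set plus its ground-truth decomposition."""
    x = spec.axis
    m = x.size
    n = spec.n_replicates

    clean_peaks = np.zeros(m)
    for p in spec.peaks:
        clean_peaks += _profile(x, p)
    clean_base = np.polynomial.polynomial.polyval(x, spec.baseline_poly)
    clean_base = np.broadcast_to(clean_base, (m,)).astype(np.float64).copy()
    for h in spec.humps:
        clean_base += h.amplitude * np.exp(-((x - h.center) ** 2) / (2.0 * h.width**2))

    baseline = np.empty((n, m))
    peaks = np.empty((n, m))
    noise = np.empty((n, m))
    spikes = np.zeros((n, m))
    spike_pos: list[np.ndarray] = []
    intensities = np.empty((n, m))

    for i in range(n):
        rng = np.random.default_rng([spec.seed, i])
        amp_scale = 1.0 + spec.amplitude_jitter * rng.standard_normal()
        base_scale = 1.0 + spec.baseline_jitter * rng.standard_normal()
        baseline[i] = base_scale * clean_base
        peaks[i] = amp_scale * clean_peaks
        noise[i] = spec.noise_sd * rng.standard_normal(m)
        if spec.spikes:
            kidx = np.array(
                [int(np.argmin(np.abs(x - s.position))) for s in spec.spikes]
            )
            spikes[i, kidx] += np.array([s.amplitude for s in spec.spikes])
        elif spec.spike_count > 0:
            kidx = np.sort(rng.choice(m, size=spec.spike_count, replace=False))
            amps = rng.uniform(*spec.spike_amp_range, size=spec.spike_count)
            spikes[i, kidx] += amps
        else:
            kidx = np.array([], dtype=int)
        spike_pos.append(x[kidx])
        intensities[i] = baseline[i] + peaks[i] + noise[i] + spikes[i]

    width = len(str(n))
    labels = tuple(f"{spec.label_prefix}{i + 1:0{width}d}" for i in range(n))
    groups = (spec.group,) * n if spec.group is not None else None
    sset = SpectrumSet(x, intensities, labels, groups)
    truth = TruthRecord(
        baseline=baseline,
        peaks=peaks,
        noise=noise,
        spikes=spikes,
        spike_positions=tuple(spike_pos),
        peak_centers=np.array([p.center for p in spec.peaks]),
    )
    return sset, truth


def generate_two_class(
    spec_a: SyntheticSpec, spec_b: SyntheticSpec
) -> SpectrumSet:
    """Generate and merge two class-labeled replicate sets on a common axis.

    The class peak tables must be disjoint: any cross-class pair of centers
    closer than the wider peak's width is an error; closer than three
    widths draws a warning.
    """
    if not np.array_equal(spec_a.axis, spec_b.axis):
        raise ValueError("the two specs must share an identical axis")
    max_w = max((p.width for p in spec_a.peaks + spec_b.peaks), default=0.0)
    for pa in spec_a.peaks:
        for pb in spec_b.peaks:
            sep = abs(pa.center - pb.center)
            if sep < max_w:
                raise ValueError(
                    f"peak centers {pa.center} and {pb.center} overlap "
                    f"(separation {sep} < width {max_w})"
                )
            if sep <= 3 * max_w:
                warnings.warn(
                    f"peak centers {pa.center} and {pb.center} are closer "
                    f"than 3x the maximum width ({3 * max_w} cm^-1)",
                    stacklevel=2,
                )
    a, _ = generate_spectra(spec_a)
    b, _ = generate_spectra(spec_b)
    if a.groups is None:
        a = SpectrumSet(a.axis, a.intensities, a.labels, ("A",) * a.n_spectra)
    if b.groups is None:
        b = SpectrumSet(b.axis, b.intensities, b.labels, ("B",) * b.n_spectra)
    return merge_sets(a, b)


# ---------------------------------------------------------------------------
# ready-made demonstration specs


def bsa_like_spec(seed: int = 0, n_replicates: int = 5) -> SyntheticSpec:
    """Protein-like replicate set: five bands, fluorescence background,
    cosmic spikes near 700 and 1100 cm^-1, on a non-integer grid."""
    return SyntheticSpec(
        axis_start=400.0,
        axis_stop=1800.0,
        axis_step=0.9,
        peaks=(
            Peak(702.0, 600.0, 9.0),
            Peak(877.0, 450.0, 10.0),
            Peak(1087.0, 800.0, 9.0),
            Peak(1308.0, 500.0, 11.0),
            Peak(1443.0, 420.0, 10.0),
        ),
        baseline_poly=(300.0, 0.4),
        humps=(Hump(1150.0, 900.0, 420.0),),
        noise_sd=20.0,
        spikes=(Spike(700.0, 1500.0), Spike(1100.0, 1100.0)),
        n_replicates=n_replicates,
        amplitude_jitter=0.05,
        baseline_jitter=0.08,
        seed=seed,
        label_prefix="bsa",
    )


def bpe_like_spec(seed: int = 0, n_replicates: int = 5) -> SyntheticSpec:
    """First analyte of the two-class demonstration pair."""
    return SyntheticSpec(
        axis_start=600.0,
        axis_stop=1600.0,
        axis_step=1.0,
        peaks=(
            Peak(970.0, 300.0, 8.0),
            Peak(1200.0, 420.0, 9.0),
            Peak(1320.0, 260.0, 8.0),
            Peak(1600.0, 350.0, 9.0),
        ),
        baseline_poly=(60.0, 0.02),
        noise_sd=6.0,
        n_replicates=n_replicates,
        amplitude_jitter=0.06,
        baseline_jitter=0.05,
        seed=seed,
        label_prefix="bpe",
        group="BPE",
    )


def r6g_like_spec(seed: int = 0, n_replicates: int = 5) -> SyntheticSpec:
    """Second analyte of the two-class demonstration pair; band positions
    disjoint from :func:`bpe_like_spec`."""
    return SyntheticSpec(
        axis_start=600.0,
        axis_stop=1600.0,
        axis_step=1.0,
        peaks=(
            Peak(612.0, 380.0, 8.0),
            Peak(774.0, 300.0, 9.0),
            Peak(1090.0, 240.0, 8.0),
            Peak(1363.0, 450.0, 9.0),
            Peak(1509.0, 330.0, 9.0),
        ),
        baseline_poly=(60.0, 0.02),
        noise_sd=6.0,
        n_replicates=n_replicates,
        amplitude_jitter=0.06,
        baseline_jitter=0.05,
        seed=seed + 1,
        label_prefix="r6g",
        group="R6G",
    )
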