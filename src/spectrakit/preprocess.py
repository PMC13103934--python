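"""Preprocessing chain for Raman/SERS spectra.

The canonical workflow mirrors common SERS practice: interpolate the axis
to an integer grid, crop to the feature-rich window, remove cosmic-ray
spikes, smooth, subtract the fluorescence baseline, and normalize.  Every
operation applies to all spectra of a :class:`~spectrakit.dataset.SpectrumSet`
at once, is pure with respect to its input, and preserves labels and groups.

Baseline correction offers three estimators:

* :func:`baseline_airpls` — adaptive iteratively reweighted penalized least
  squares: a Whittaker smoother alternated with residual-driven reweighting
  that progressively ignores points above the baseline.
* :func:`baseline_polynomial` — the iterative minimum-polynomial method.
* :func:`baseline_glfit` — a broad pseudo-Voigt (Gaussian–Lorentzian)
  background fit by bounded nonlinear least squares.

All three satisfy the conservation identity ``corrected + baseline = input``
to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.optimize
import scipy.signal
import scipy.sparse
import scipy.sparse.linalg

from .dataset import SpectrumSet

__all__ = [
    "BaselineResult",
    "OutlierReport",
    "interpolate_to_grid",
    "crop",
    "despike",
    "smooth_savgol",
    "smooth_fourier",
    "baseline_airpls",
    "baseline_polynomial",
    "baseline_glfit",
    "normalize",
    "detect_outliers",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class BaselineResult:
    """Per-spectrum baseline estimate and baseline-corrected intensities."""

    set: SpectrumSet  # corrected spectra (input - baseline)
    baselines: np.ndarray  # N x M estimated baselines
    iterations_used: np.ndarray  # per-spectrum iteration count
    converged: np.ndarray  # per-spectrum boolean flag

    @property
    def corrected(self) -> np.ndarray:
        return self.set.intensities

    def to_frame(self) -> pd.DataFrame:
        """Per-spectrum convergence summary as a table."""
        return pd.DataFrame(
            {
                "label": list(self.set.labels),
                "iterations_used": self.iterations_used,
                "converged": self.converged,
            }
        )


@dataclass(frozen=True)
class OutlierReport:
    """Scores and flags from the three-criterion outlier screen."""

    labels: tuple[str, ...]
    correlation: np.ndarray  # Pearson r to leave-one-out consensus
    deviation: np.ndarray  # mean |I_i - consensus| / mean per-wavenumber SD
    distance: np.ndarray  # Euclidean distance ratio to median
    flag_correlation: np.ndarray
    flag_deviation: np.ndarray
    flag_distance: np.ndarray
    combined: np.ndarray
    warnings: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "correlation": self.correlation,
                "deviation": self.deviation,
                "distance": self.distance,
                "flag_correlation": self.flag_correlation,
                "flag_deviation": self.flag_deviation,
                "flag_distance": self.flag_distance,
                "outlier": self.combined,
            }
        )


# ---------------------------------------------------------------------------
# axis operations


def interpolate_to_grid(sset: SpectrumSet) -> SpectrumSet:
    """Resample every spectrum onto the integer-wavenumber grid.

    The new axis runs over consecutive integers from ``ceil(min(axis))`` to
    ``floor(max(axis))``; intensities are linearly interpolated between the
    bracketing original samples.  No extrapolation occurs.
    """
    lo = int(np.ceil(sset.axis[0]))
    hi = int(np.floor(sset.axis[-1]))
    if hi - lo < 1:
        raise ValueError(
            f"axis range [{sset.axis[0]}, {sset.axis[-1]}] spans fewer than "
            "2 integer wavenumbers"
        )
    new_axis = np.arange(lo, hi + 1, dtype=np.float64)
    if new_axis.size == sset.axis.size and np.array_equal(new_axis, sset.axis):
        return sset
    new_int = np.empty((sset.n_spectra, new_axis.size))
    for i in range(sset.n_spectra):
        new_int[i] = np.interp(new_axis, sset.axis, sset.intensities[i])
    return sset.with_axis(new_axis, new_int)


def crop(sset: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Restrict the axis to the closed window [lo, hi]."""
    if not lo < hi:
        raise ValueError(f"crop window is empty: lo={lo} must be < hi={hi}")
    mask = (sset.axis >= lo) & (sset.axis <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"fewer than 2 axis points fall inside [{lo}, {hi}]"
        )
    if mask.all():
        return sset
    return sset.with_axis(sset.axis[mask], sset.intensities[:, mask])


# ---------------------------------------------------------------------------
# despiking


def _region_mask(axis: np.ndarray, regions) -> np.ndarray:
    if regions == "all" or regions is None:
        return np.ones(axis.size, dtype=bool)
    mask = np.zeros(axis.size, dtype=bool)
    for lo, hi in regions:
        sub = (axis >= lo) & (axis <= hi)
        if not sub.any():
            raise ValueError(
                f"despike region [{lo}, {hi}] contains no axis points"
            )
        mask |= sub
    return mask


def despike(
    sset: SpectrumSet,
    regions="all",
    threshold: float = 300.0,
    window: int = 11,
) -> SpectrumSet:
    """Remove single-sample cosmic-ray spikes.

    Within the given wavenumber ``regions`` (list of ``(lo, hi)`` windows,
    or ``"all"``), a point is flagged as a spike when it exceeds the running
    median (window length ``window``, robust to the spike itself) by more
    than ``threshold`` intensity units.  Flagged points are replaced by
    linear interpolation between the nearest unflagged neighbors; points
    outside the regions are left bit-identical.
    """
    if window % 2 == 0 or window < 3 or window > sset.n_points:
        raise ValueError(
            f"despike window must be odd, >=3 and <= M={sset.n_points}; "
            f"got {window}"
        )
    if threshold <= 0:
        raise ValueError(f"despike threshold must be > 0, got {threshold}")
    region = _region_mask(sset.axis, regions)

    out = sset.intensities.copy()
    idx = np.arange(sset.n_points)
    for i in range(sset.n_spectra):
        y = sset.intensities[i]
        med = scipy.ndimage.median_filter(y, size=window, mode="nearest")
        flagged = region & (y - med > threshold)
        if not flagged.any():
            continue
        keep = ~flagged
        # np.interp extends by the nearest kept value at the boundaries
        out[i, flagged] = np.interp(idx[flagged], idx[keep], y[keep])
    return sset.with_intensities(out)


# ---------------------------------------------------------------------------
# smoothing


def smooth_savgol(sset: SpectrumSet, window: int = 15, polyorder: int = 2) -> SpectrumSet:
    """Savitzky–Golay least-squares polynomial smoothing.

    Edges are handled by fitting the polynomial to the available one-sided
    window, so the output length equals the input length and polynomials of
    degree <= ``polyorder`` pass through unchanged.
    """
    if window % 2 == 0:
        raise ValueError(f"Savitzky-Golay window must be odd, got {window}")
    if not polyorder < window <= sset.n_points:
        raise ValueError(
            f"need polyorder < window <= M; got polyorder={polyorder}, "
            f"window={window}, M={sset.n_points}"
        )
    out = scipy.signal.savgol_filter(
        sset.intensities, window, polyorder, axis=1, mode="interp"
    )
    return sset.with_intensities(out)


def smooth_fourier(sset: SpectrumSet, cutoff: float) -> SpectrumSet:
    """Low-pass Fourier filtering with a hard frequency cutoff.

    Each spectrum is mirror-padded to length 2M (bounding edge ringing),
    transformed, components above ``cutoff`` times the Nyquist frequency
    zeroed, inverse-transformed, and truncated back to M samples.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    m = sset.n_points
    padded = np.concatenate([sset.intensities, sset.intensities[:, ::-1]], axis=1)
    spec = np.fft.rfft(padded, axis=1)
    # rfft of a length-2M signal has M+1 bins; bin M is Nyquist
    keep = np.arange(spec.shape[1]) <= cutoff * m
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=2 * m, axis=1)[:, :m]
    return sset.with_intensities(out)


# ---------------------------------------------------------------------------
# baseline correction


def _difference_penalty(m: int, order: int, lam: float) -> scipy.sparse.csc_matrix:
    d = scipy.sparse.eye(m, format="csc")
    for _ in range(order):
        d = d[1:] - d[:-1]
    return (lam * (d.T @ d)).tocsc()


def baseline_airpls(
    sset: SpectrumSet,
    lam: float = 100.0,
    order: int = 1,
    max_iter: int = 15,
    tol: float = 0.001,
) -> BaselineResult:
    """Adaptive iteratively reweighted penalized least-squares baseline.

    Each spectrum ``y`` is fit by the weighted Whittaker smoother

        z = argmin  sum_k w_k (y_k - z_k)^2 + lam * sum (d^order z)^2,

    starting from unit weights.  After each solve, with residual
    ``d = y - z`` and negative-residual mass ``D = sum_{d_k<0} |d_k|``, the
    weights become 0 where ``d_k >= 0`` and ``exp(t |d_k| / D)`` where
    ``d_k < 0`` (iteration index ``t``); both endpoints receive the largest
    negative-residual weight so the baseline stays anchored.  Iteration
    stops when ``D < tol * sum |y|`` or at ``max_iter``.

    Parameters
    ----------
    lam
        Roughness penalty weight; larger values give stiffer baselines.
    order
        Difference order of the penalty (1 or 2).  Order 1 leaves straight
        lines unpenalized.
    """
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    if order not in (1, 2):
        raise ValueError(f"difference order must be 1 or 2, got {order}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    if not 0 < tol < 1:
        raise ValueError(f"tol must lie in (0, 1), got {tol}")

    m = sset.n_points
    penalty = _difference_penalty(m, order, lam)
    baselines = np.empty_like(sset.intensities)
    iters = np.zeros(sset.n_spectra, dtype=int)
    converged = np.zeros(sset.n_spectra, dtype=bool)

    for i in range(sset.n_spectra):
        y = sset.intensities[i]
        total_mass = np.abs(y).sum()
        w = np.ones(m)
        z = y.copy()
        for t in range(1, max_iter + 1):
            system = scipy.sparse.diags(w, format="csc") + penalty
            try:
                z = scipy.sparse.linalg.spsolve(system, w * y)
            except RuntimeError as exc:  # umfpack/superlu singularity
                raise np.linalg.LinAlgError(
                    f"singular Whittaker system for spectrum "
                    f"{sset.labels[i]!r}: {exc}"
                ) from exc
            if not np.all(np.isfinite(z)):
                raise np.linalg.LinAlgError(
                    f"singular Whittaker system for spectrum {sset.labels[i]!r}"
                )
            d = y - z
            neg = d < 0
            neg_mass = np.abs(d[neg]).sum()
            iters[i] = t
            if neg_mass < tol * total_mass or not neg.any():
                converged[i] = True
                break
            w = np.zeros(m)
            w[neg] = np.exp(t * np.abs(d[neg]) / neg_mass)
            w[0] = w[-1] = np.exp(t * np.abs(d[neg]).max() / neg_mass)
        baselines[i] = z

    corrected = sset.with_intensities(sset.intensities - baselines)
    return BaselineResult(corrected, baselines, iters, converged)


def baseline_polynomial(
    sset: SpectrumSet,
    order: int = 3,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> BaselineResult:
    """Iterative minimum-polynomial baseline (modified polyfit).

    Repeatedly least-squares fits a degree-``order`` polynomial to the
    working signal and replaces the working signal with the pointwise
    minimum of itself and the fit; peaks are thereby clipped out of the fit.
    Stops when successive fits differ by less than ``tol`` in relative L2
    norm, or after ``max_iter`` fits.  The final fit is the baseline.
    """
    if order < 0:
        raise ValueError(f"polynomial order must be >= 0, got {order}")
    if order >= sset.n_points:
        raise ValueError(
            f"polynomial order {order} >= number of points {sset.n_points}"
        )
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")

    baselines = np.empty_like(sset.intensities)
    iters = np.zeros(sset.n_spectra, dtype=int)
    converged = np.zeros(sset.n_spectra, dtype=bool)
    for i in range(sset.n_spectra):
        working = sset.intensities[i].copy()
        prev_fit: np.ndarray | None = None
        fit = working
        for t in range(1, max_iter + 1):
            poly = np.polynomial.Polynomial.fit(sset.axis, working, order)
            fit = poly(sset.axis)
            iters[i] = t
            if prev_fit is not None:
                denom = np.linalg.norm(prev_fit)
                change = np.linalg.norm(fit - prev_fit) / max(denom, 1e-300)
                if change < tol:
                    converged[i] = True
                    break
            prev_fit = fit
            working = np.minimum(working, fit)
        baselines[i] = fit

    corrected = sset.with_intensities(sset.intensities - baselines)
    return BaselineResult(corrected, baselines, iters, converged)


def _pseudo_voigt(x: np.ndarray, amp: float, center: float, width: float, eta: float) -> np.ndarray:
    lor = width**2 / ((x - center) ** 2 + width**2)
    gau = np.exp(-((x - center) ** 2) / (2.0 * width**2))
    return amp * (eta * lor + (1.0 - eta) * gau)


def baseline_glfit(
    sset: SpectrumSet, n_components: int = 1, min_width: float = 200.0
) -> BaselineResult:
    """Broad Gaussian–Lorentzian (pseudo-Voigt) background fit.

    Fits ``n_components`` pseudo-Voigt profiles, each constrained to width
    >= ``min_width`` cm^-1 (much wider than vibrational peaks), plus a
    constant offset, by bounded nonlinear least squares.  The fitted broad
    background is the baseline; narrow peaks survive subtraction because
    the width bound prevents the background from following them.

    Non-convergence is reported per spectrum via ``converged``; the last
    iterate is still returned.
    """
    if n_components < 1:
        raise ValueError(f"n_components must be >= 1, got {n_components}")
    if min_width <= 0:
        raise ValueError(f"min_width must be > 0, got {min_width}")

    x = sset.axis
    span = x[-1] - x[0]

    def model(params: np.ndarray) -> np.ndarray:
        out = np.full_like(x, params[-1])
        for j in range(n_components):
            amp, center, width, eta = params[4 * j : 4 * j + 4]
            out = out + _pseudo_voigt(x, amp, center, width, eta)
        return out

    baselines = np.empty_like(sset.intensities)
    iters = np.zeros(sset.n_spectra, dtype=int)
    converged = np.zeros(sset.n_spectra, dtype=bool)
    for i in range(sset.n_spectra):
        y = sset.intensities[i]
        amp0 = max(float(y.max() - y.min()), 0.0)
        p0, lo, hi = [], [], []
        for j in range(n_components):
            center0 = x[0] + span * (j + 0.5) / n_components
            p0 += [amp0 / n_components, center0, max(min_width, span / 3), 0.5]
            lo += [0.0, x[0] - span, min_width, 0.0]
            hi += [np.inf, x[-1] + span, np.inf, 1.0]
        p0.append(float(y.min()))
        lo.append(-np.inf)
        hi.append(np.inf)

        res = scipy.optimize.least_squares(
            lambda p: model(p) - y,
            np.asarray(p0),
            bounds=(np.asarray(lo), np.asarray(hi)),
            max_nfev=2000 * (4 * n_components + 1),
        )
        baselines[i] = model(res.x)
        iters[i] = int(res.nfev)
        converged[i] = bool(res.success)

    corrected = sset.with_intensities(sset.intensities - baselines)
    return BaselineResult(corrected, baselines, iters, converged)


# ---------------------------------------------------------------------------
# normalization


def normalize(
    sset: SpectrumSet, mode: str = "area", peak_position: float | None = None
) -> SpectrumSet:
    """Scale each spectrum for shape comparison across samples.

    Modes
    -----
    ``area``
        Divide by the trapezoidal area over the axis (area becomes 1).
    ``peak``
        Divide by the maximum intensity, or by the intensity at the sample
        nearest ``peak_position`` when given (that value becomes 1).
    ``minmax``
        Affine map so the minimum becomes 0 and the maximum 1.
    """
    if mode not in ("area", "peak", "minmax"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    inten = sset.intensities
    if mode == "area":
        areas = np.trapezoid(inten, sset.axis, axis=1)
        bad = np.nonzero(areas == 0)[0]
        if bad.size:
            raise ValueError(
                f"zero trapezoidal area for spectrum {sset.labels[bad[0]]!r}"
            )
        out = inten / areas[:, None]
    elif mode == "peak":
        if peak_position is None:
            ref = inten.max(axis=1)
        else:
            k = int(np.argmin(np.abs(sset.axis - peak_position)))
            ref = inten[:, k]
        bad = np.nonzero(ref == 0)[0]
        if bad.size:
            raise ValueError(
                f"zero peak reference for spectrum {sset.labels[bad[0]]!r}"
            )
        out = inten / ref[:, None]
    else:
        mins = inten.min(axis=1)
        maxs = inten.max(axis=1)
        bad = np.nonzero(maxs == mins)[0]
        if bad.size:
            raise ValueError(
                f"constant spectrum {sset.labels[bad[0]]!r} cannot be "
                "min/max scaled"
            )
        out = (inten - mins[:, None]) / (maxs - mins)[:, None]
    return sset.with_intensities(out)


# ---------------------------------------------------------------------------
# outlier screening


def detect_outliers(
    sset: SpectrumSet,
    corr_thresh: float = 0.9,
    sd_thresh: float = 3.0,
    dist_thresh: float = 3.0,
    combine: str = "any",
) -> OutlierReport:
    """Screen spectra against correlation, deviation and distance criteria.

    Each spectrum is compared with the leave-one-out consensus mean of the
    remaining spectra:

    a. correlation criterion — Pearson r(spectrum, consensus) below
       ``corr_thresh``;
    b. standard-deviation criterion — mean absolute deviation from the
       consensus above ``sd_thresh`` times the mean per-wavenumber sample
       standard deviation of the full set;
    c. distance criterion — Euclidean distance to the consensus above
       ``dist_thresh`` times the median such distance across spectra.

    Criteria combine with OR (``combine="any"``, the default) or AND.  A
    constant consensus makes criterion (a) undefined; it is then skipped for
    that spectrum with a warning recorded in the report.
    """
    if sset.n_spectra < 3:
        raise ValueError(
            f"outlier detection needs at least 3 spectra, got {sset.n_spectra}"
        )
    if combine not in ("any", "all"):
        raise ValueError(f"combine must be 'any' or 'all', got {combine!r}")

    n = sset.n_spectra
    inten = sset.intensities
    total = inten.sum(axis=0)
    pooled_sd = float(np.mean(np.std(inten, axis=0, ddof=1)))

    corr = np.empty(n)
    dev = np.empty(n)
    dist = np.empty(n)
    flag_a = np.zeros(n, dtype=bool)
    warnings: list[str] = []
    skip_a = np.zeros(n, dtype=bool)
    for i in range(n):
        consensus = (total - inten[i]) / (n - 1)
        if np.ptp(consensus) == 0:
            skip_a[i] = True
            corr[i] = np.nan
            warnings.append(
                f"constant leave-one-out consensus for {sset.labels[i]!r}; "
                "correlation criterion skipped"
            )
        else:
            if np.ptp(inten[i]) == 0:
                corr[i] = np.nan
                skip_a[i] = True
                warnings.append(
                    f"constant spectrum {sset.labels[i]!r}; correlation "
                    "criterion skipped"
                )
            else:
                corr[i] = float(np.corrcoef(inten[i], consensus)[0, 1])
                flag_a[i] = corr[i] < corr_thresh
        dev[i] = float(np.mean(np.abs(inten[i] - consensus)))
        dist[i] = float(np.linalg.norm(inten[i] - consensus))

    if pooled_sd == 0:
        flag_b = np.zeros(n, dtype=bool)
        dev_score = np.zeros(n)
    else:
        dev_score = dev / pooled_sd
        flag_b = dev_score > sd_thresh
    med = float(np.median(dist))
    if med == 0:
        dist_score = np.where(dist > 0, np.inf, 0.0)
    else:
        dist_score = dist / med
    flag_c = dist_score > dist_thresh

    if combine == "any":
        combined = flag_a | flag_b | flag_c
    else:
        # a skipped correlation criterion does not veto an AND combination
        combined = (flag_a | skip_a) & flag_b & flag_c
    return OutlierReport(
        labels=sset.labels,
        correlation=corr,
        deviation=dev_score,
        distance=dist_score,
        flag_correlation=flag_a,
        flag_deviation=flag_b,
        flag_distance=flag_c,
        combined=combined,
        warnings=tuple(warnings),
    )
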