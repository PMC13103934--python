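"""Reproducibility statistics, peak identification and multivariate analysis.

The central reproducibility statistic is the average spectral variation

    sigma_avg = (1/M) * sum_k sqrt( (1/(N-1)) * sum_i (I_i(k) - Ibar(k))^2 ),

the mean over wavenumbers of the across-replicate sample standard
deviation.  Its dimensionless companion, the relative variation, divides by
the trapezoidal area under the mean spectrum, so after area normalization
the two coincide.

Multivariate exploration follows standard chemometrics practice: Ward
hierarchical clustering on Euclidean distances, PCA on the column-centered
intensity matrix, and t-SNE for nonlinear embedding of small sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.signal

from .dataset import SpectrumSet

__all__ = [
    "PeakList",
    "SummaryStats",
    "ClusterResult",
    "PCAResult",
    "Embedding2D",
    "sigma_avg",
    "relative_variation",
    "summarize",
    "correlation_matrix",
    "find_peaks",
    "hca_ward",
    "pca",
    "tsne_embed",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class PeakList:
    """Detected peaks, positions in ascending wavenumber order."""

    positions: np.ndarray  # apex wavenumbers (cm^-1), axis members
    heights: np.ndarray  # apex intensities
    prominences: np.ndarray  # vertical distance to the higher base level

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "height": self.heights,
                "prominence": self.prominences,
            }
        )


@dataclass(frozen=True)
class SummaryStats:
    """Mean spectrum with a +/- k*SD confidence band."""

    axis: np.ndarray
    mean: np.ndarray
    sd: np.ndarray  # per-wavenumber sample SD (N-1 denominator)
    lower: np.ndarray
    upper: np.ndarray
    k: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavenumber": self.axis,
                "mean": self.mean,
                "sd": self.sd,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass(frozen=True)
class ClusterResult:
    """Ward agglomeration: scipy-style merge table plus display leaf order."""

    merges: np.ndarray  # (N-1) x 4: child a, child b, height, new size
    leaf_order: np.ndarray  # permutation of spectrum indices
    labels: tuple[str, ...]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster assignment with exactly ``n_clusters`` clusters."""
        return scipy.cluster.hierarchy.fcluster(
            self.merges, n_clusters, criterion="maxclust"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["child_a", "child_b", "height", "size"]
        )


@dataclass(frozen=True)
class PCAResult:
    """Principal-component scores, orthonormal loadings, variance ratios."""

    scores: np.ndarray  # N x n_components
    loadings: np.ndarray  # n_components x M, orthonormal rows
    explained_variance_ratio: np.ndarray

    def to_frames(self) -> dict[str, pd.DataFrame]:
        comps = [f"PC{j + 1}" for j in range(self.scores.shape[1])]
        return {
            "scores": pd.DataFrame(self.scores, columns=comps),
            "loadings": pd.DataFrame(self.loadings, index=comps),
            "ratios": pd.DataFrame(
                {"component": comps, "ratio": self.explained_variance_ratio}
            ),
        }


@dataclass(frozen=True)
class Embedding2D:
    """2-D t-SNE coordinates plus the settings that produced them."""

    coordinates: np.ndarray  # N x 2
    seed: int
    perplexity: float
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coordinates, columns=["tsne1", "tsne2"])


# ---------------------------------------------------------------------------
# reproducibility statistics


def sigma_avg(sset: SpectrumSet) -> float:
    """Average spectral variation: mean across-replicate sample SD.

    Requires N >= 2.  Zero for identical replicates; scales linearly with
    the intensities and is invariant to adding a common constant.
    """
    if sset.n_spectra < 2:
        raise ValueError("sigma_avg needs at least 2 spectra")
    sd = np.std(sset.intensities, axis=0, ddof=1)
    return float(np.mean(sd))


def relative_variation(sset: SpectrumSet) -> float:
    """sigma_avg divided by the trapezoidal area under the mean spectrum.

    Dimensionless and invariant to a common positive intensity rescaling.
    After area normalization the mean area is 1, so this equals
    :func:`sigma_avg`.
    """
    area = float(np.trapezoid(sset.intensities.mean(axis=0), sset.axis))
    if area == 0:
        raise ValueError("mean-spectrum area is zero; relative variation undefined")
    return sigma_avg(sset) / area


def summarize(sset: SpectrumSet, k: float = 1.0) -> SummaryStats:
    """Per-wavenumber mean, sample SD and a mean +/- k*SD band."""
    if sset.n_spectra < 2:
        raise ValueError("summarize needs at least 2 spectra")
    mean = sset.intensities.mean(axis=0)
    sd = np.std(sset.intensities, axis=0, ddof=1)
    return SummaryStats(
        axis=sset.axis.copy(),
        mean=mean,
        sd=sd,
        lower=mean - k * sd,
        upper=mean + k * sd,
        k=float(k),
    )


def correlation_matrix(
    sset: SpectrumSet, include_mean: bool = True
) -> pd.DataFrame:
    """Pairwise Pearson correlations between spectra.

    When ``include_mean`` is true the grand mean spectrum is appended as a
    final ``mean`` row/column, serving as the reference trace.
    """
    if sset.n_spectra < 2:
        raise ValueError("correlation matrix needs at least 2 spectra")
    rows = sset.intensities
    labels = list(sset.labels)
    const = np.nonzero(np.ptp(rows, axis=1) == 0)[0]
    if const.size:
        raise ValueError(
            f"constant spectrum {sset.labels[const[0]]!r}: correlation undefined"
        )
    if include_mean:
        rows = np.vstack([rows, rows.mean(axis=0)])
        labels = labels + ["mean"]
    mat = np.corrcoef(rows)
    return pd.DataFrame(mat, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# peak identification


def find_peaks(
    axis: np.ndarray,
    intensity: np.ndarray,
    top_n: int = 5,
    min_prominence: float | None = None,
) -> PeakList:
    """Identify the most prominent peaks of a single spectrum.

    A peak is a local maximum (interior plateaus report their midpoint);
    its prominence is the apex height minus the higher of the two base
    levels, each base level being the signal minimum between the apex and
    the nearest higher point on that side (or the axis boundary).  The
    ``top_n`` peaks by prominence are returned, optionally filtered by
    ``min_prominence``, sorted by ascending wavenumber.
    """
    axis = np.asarray(axis, dtype=np.float64)
    y = np.asarray(intensity, dtype=np.float64)
    if y.ndim != 1 or y.size != axis.size:
        raise ValueError("intensity must be a single spectrum matching the axis")
    if y.size < 3:
        raise ValueError("need at least 3 points to find peaks")
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    idx, props = scipy.signal.find_peaks(y, prominence=min_prominence or 0.0)
    if idx.size == 0:
        raise ValueError("no local maxima found (monotone or flat signal)")
    prom = props["prominences"]
    order = np.argsort(prom)[::-1][:top_n]
    chosen = np.sort(idx[order])
    sel = np.searchsorted(idx, chosen)
    return PeakList(
        positions=axis[chosen],
        heights=y[chosen],
        prominences=prom[sel],
    )


def find_peaks_set(
    sset: SpectrumSet,
    label: str,
    top_n: int = 5,
    min_prominence: float | None = None,
) -> PeakList:
    """Convenience wrapper: peak identification on one spectrum of a set."""
    return find_peaks(sset.axis, sset.row(label), top_n, min_prominence)


# ---------------------------------------------------------------------------
# multivariate exploration


def hca_ward(sset: SpectrumSet) -> ClusterResult:
    """Agglomerative clustering of spectra with Ward linkage.

    Euclidean distances between spectra; merge heights on the standard Ward
    scale, where the merge of two singletons a, b occurs at ||a - b||.
    Heights are non-decreasing down the merge table, and the agglomeration
    is deterministic.
    """
    if sset.n_spectra < 2:
        raise ValueError("clustering needs at least 2 spectra")
    merges = scipy.cluster.hierarchy.linkage(sset.intensities, method="ward")
    leaf_order = scipy.cluster.hierarchy.leaves_list(merges)
    return ClusterResult(merges=merges, leaf_order=leaf_order, labels=sset.labels)


def pca(sset: SpectrumSet, n_components: int) -> PCAResult:
    """Principal-component analysis of the column-centered intensity matrix.

    Centering only (no per-wavenumber scaling).  Computed by singular value
    decomposition; the explained-variance ratio of component j is
    sigma_j^2 / sum sigma^2 over all min(N-1, M) components.  Sign
    convention: each loading's largest-magnitude element is positive.
    """
    n, m = sset.n_spectra, sset.n_points
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    max_comp = min(n - 1, m)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must lie in [1, {max_comp}] for N={n}, M={m}; "
            f"got {n_components}"
        )
    centered = sset.intensities - sset.intensities.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    s = s[:max_comp]
    vt = vt[:max_comp]
    u = u[:, :max_comp]
    # sign convention: largest-|.| element of each loading positive
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    vt = vt * signs[:, None]
    u = u * signs[None, :]
    total = float(np.sum(s**2))
    ratios = (s**2 / total) if total > 0 else np.zeros_like(s)
    return PCAResult(
        scores=(u * s)[:, :n_components],
        loadings=vt[:n_components],
        explained_variance_ratio=ratios[:n_components],
    )


def tsne_embed(
    sset: SpectrumSet,
    perplexity: float = 3.0,
    n_iter: int = 500,
    seed: int = 0,
) -> Embedding2D:
    """2-D t-SNE embedding of the spectra (deterministic for a fixed seed).

    Perplexity must satisfy the standard feasibility bound
    3 * perplexity <= N - 1 (each point needs 3 * perplexity neighbors).
    Delegates the KL-divergence optimization to scikit-learn with a PCA
    initialization.
    """
    from sklearn.manifold import TSNE

    n = sset.n_spectra
    if 3 * perplexity > n - 1:
        raise ValueError(
            f"perplexity {perplexity} infeasible for N={n}; "
            f"need 3 * perplexity <= N - 1 = {n - 1}"
        )
    if n_iter < 250:
        raise ValueError(f"n_iter must be >= 250, got {n_iter}")
    model = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        init="pca",
        random_state=int(seed),
        method="exact" if n < 50 else "barnes_hut",
    )
    coords = model.fit_transform(sset.intensities)
    return Embedding2D(
        coordinates=np.asarray(coords, dtype=np.float64),
        seed=int(seed),
        perplexity=float(perplexity),
        n_iter=int(n_iter),
    )
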