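"""Spectral data container.

A :class:`SpectrumSet` holds N spectra sampled on one shared, strictly
increasing wavenumber axis (cm^-1).  All preprocessing and analytics
operations take and return instances of this type; operations never mutate
their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectrumSet", "merge_sets"]


@dataclass(frozen=True)
class SpectrumSet:
    """N spectra on a common wavenumber axis.

    Parameters
    ----------
    axis
        Strictly increasing wavenumbers in cm^-1, length M (M >= 2).
    intensities
        N x M matrix of intensities, one row per spectrum.  All values
        must be finite.
    labels
        N unique spectrum identifiers.
    groups
        Optional N class labels (e.g. analyte name).
    """

    axis: np.ndarray
    intensities: np.ndarray
    labels: tuple[str, ...]
    groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=np.float64)
        inten = np.atleast_2d(np.asarray(self.intensities, dtype=np.float64))
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if self.groups is not None:
            groups = tuple(str(g) for g in self.groups)
            object.__setattr__(self, "groups", groups)

        if axis.ndim != 1 or axis.size < 2:
            raise ValueError("axis must be a 1-D array with at least 2 points")
        if not np.all(np.isfinite(axis)):
            raise ValueError("axis contains non-finite values")
        if np.any(np.diff(axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if inten.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        if inten.shape[0] < 1:
            raise ValueError("at least one spectrum is required")
        if inten.shape[1] != axis.size:
            raise ValueError(
                f"intensities have {inten.shape[1]} columns but the axis has "
                f"{axis.size} points"
            )
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities contain non-finite values")
        if len(self.labels) != inten.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {inten.shape[0]} spectra"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("spectrum labels must be unique")
        if self.groups is not None and len(self.groups) != inten.shape[0]:
            raise ValueError(
                f"{len(self.groups)} group labels for {inten.shape[0]} spectra"
            )

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        """New set sharing axis/labels/groups with replaced intensities."""
        return SpectrumSet(self.axis, intensities, self.labels, self.groups)

    def with_axis(self, axis: np.ndarray, intensities: np.ndarray) -> "SpectrumSet":
        """New set with a replaced axis and matching intensities."""
        return SpectrumSet(axis, intensities, self.labels, self.groups)

    def row(self, label: str) -> np.ndarray:
        """Intensity row for one spectrum, selected by label."""
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no spectrum labeled {label!r}") from None
        return self.intensities[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumSet):
            return NotImplemented
        return (
            np.array_equal(self.axis, other.axis)
            and np.array_equal(self.intensities, other.intensities)
            and self.labels == other.labels
            and self.groups == other.groups
        )


def merge_sets(a: SpectrumSet, b: SpectrumSet) -> SpectrumSet:
    """Stack two sets sharing an identical axis into one.

    Raises
    ------
    ValueError
        If the axes differ (exact comparison) or labels collide.
    """
    if not np.array_equal(a.axis, b.axis):
        raise ValueError(
            "cannot merge sets with differing axes; interpolate both to a "
            "common grid first"
        )
    collisions = set(a.labels) & set(b.labels)
    if collisions:
        raise ValueError(f"label collision between sets: {sorted(collisions)}")
    groups: tuple[str, ...] | None
    if a.groups is None and b.groups is None:
        groups = None
    else:
        ga = a.groups if a.groups is not None else ("",) * a.n_spectra
        gb = b.groups if b.groups is not None else ("",) * b.n_spectra
        groups = ga + gb
    return SpectrumSet(
        a.axis,
        np.vstack([a.intensities, b.intensities]),
        a.labels + b.labels,
        groups,
    )
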