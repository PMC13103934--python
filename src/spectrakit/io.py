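"""Reading and writing the supported plain-text spectrum formats.

Two formats are supported:

``two_column``
    One file per spectrum.  Whitespace- or comma-separated, optional
    comment lines starting with ``#``; column 1 is the wavenumber (cm^-1),
    column 2 the intensity.
``wide_table``
    One CSV file for the whole set: a header row, first column named
    ``wavenumber`` (case-insensitive), one further column per spectrum.

Numbers are parsed with decimal points only (no locale comma decimals) and
written with repr-faithful formatting, so a write/read round trip is exact.
A decreasing or duplicated wavenumber axis is an error, never silently
repaired, and two-column files must share an identical axis: the platform
workflow forces a common grid via interpolation, so the library does too.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import SpectrumSet

__all__ = ["read_spectra", "write_spectra"]

_FORMATS = ("two_column", "wide_table")


def _check_axis(axis: np.ndarray, origin: str) -> None:
    diffs = np.diff(axis)
    if np.any(diffs == 0):
        dup = axis[:-1][diffs == 0][0]
        raise ValueError(f"{origin}: duplicate wavenumber {dup!r}")
    if np.any(diffs < 0):
        raise ValueError(
            f"{origin}: wavenumber axis is not strictly increasing; "
            "sort or re-export the file (auto-sorting is not performed)"
        )


def _parse_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    wn: list[float] = []
    inten: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 numeric columns, "
                    f"got {len(fields)}"
                )
            try:
                wn.append(float(fields[0]))
                inten.append(float(fields[1]))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell in {line!r}"
                ) from None
    if len(wn) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    axis = np.array(wn, dtype=np.float64)
    _check_axis(axis, str(path))
    return axis, np.array(inten, dtype=np.float64)


def _read_wide_table(path: Path) -> SpectrumSet:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: wide table needs a wavenumber column plus "
                         "at least one spectrum column")
    first = str(df.columns[0])
    if first.strip().lower() != "wavenumber":
        raise ValueError(
            f"{path}: first column must be named 'wavenumber' "
            f"(case-insensitive), got {first!r}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(d, np.number) for d in df.dtypes]
        ].tolist()
        raise ValueError(f"{path}: non-numeric cell(s) in column(s) {bad}")
    axis = np.asarray(values[:, 0], dtype=np.float64)
    _check_axis(axis, str(path))
    labels = tuple(str(c) for c in df.columns[1:])
    return SpectrumSet(axis, values[:, 1:].T.astype(np.float64), labels)


def read_spectra(
    paths: Sequence[str | os.PathLike], format: str = "two_column"
) -> SpectrumSet:
    """Read spectra from plain-text files into a :class:`SpectrumSet`.

    Parameters
    ----------
    paths
        Files to read.  ``two_column`` accepts any number of per-spectrum
        files (labels default to the file stems); ``wide_table`` accepts
        exactly one CSV (labels come from the header).
    format
        ``"two_column"`` or ``"wide_table"``.

    Raises
    ------
    FileNotFoundError
        For a missing input file.
    ValueError
        For non-numeric cells, duplicate or decreasing wavenumbers, or —
        in two_column mode — files whose axes are not identical (interpolate
        each file to a common grid first).
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input paths given")
    for p in paths:
        if not p.is_file():
            raise FileNotFoundError(f"input file not found: {p}")

    if format == "wide_table":
        if len(paths) != 1:
            raise ValueError("wide_table format expects exactly one file")
        return _read_wide_table(paths[0])

    axis0: np.ndarray | None = None
    rows: list[np.ndarray] = []
    labels: list[str] = []
    for p in paths:
        axis, inten = _parse_two_column(p)
        if axis0 is None:
            axis0 = axis
        elif not np.array_equal(axis, axis0):
            raise ValueError(
                f"{p}: wavenumber axis differs from {paths[0]}; two-column "
                "files must share an identical axis — interpolate the spectra "
                "to a common grid before loading them together"
            )
        rows.append(inten)
        labels.append(p.stem)
    assert axis0 is not None
    if len(set(labels)) != len(labels):
        labels = [f"{lab}_{i}" for i, lab in enumerate(labels)]
    return SpectrumSet(axis0, np.vstack(rows), tuple(labels))


def _fmt(x: float) -> str:
    return repr(float(x))


def write_spectra(
    sset: SpectrumSet, path: str | os.PathLike, format: str = "wide_table"
) -> list[Path]:
    """Write a :class:`SpectrumSet` to disk; returns the files written.

    ``wide_table`` writes a single CSV at ``path``.  ``two_column`` treats
    ``path`` as a directory and writes one ``<label>.txt`` per spectrum.
    Values are formatted with full precision so that
    ``read_spectra(write_spectra(s)) == s``.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)

    if format == "wide_table":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(",".join(["wavenumber", *sset.labels]) + "\n")
            for k in range(sset.n_points):
                cells = [_fmt(sset.axis[k])]
                cells += [_fmt(v) for v in sset.intensities[:, k]]
                fh.write(",".join(cells) + "\n")
        return [path]

    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, label in enumerate(sset.labels):
        fp = path / f"{label}.txt"
        with open(fp, "w", encoding="utf-8") as fh:
            for k in range(sset.n_points):
                fh.write(f"{_fmt(sset.axis[k])} {_fmt(sset.intensities[i, k])}\n")
        written.append(fp)
    return written
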