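"""Pipeline runner with validated configs and replayable provenance.

A :class:`PipelineConfig` is an ordered list of named preprocessing steps
with parameter maps; it validates fully (operation names and parameters,
with defaults expanded) before anything runs.  Every executed step is
recorded in a :class:`ProvenanceLog` with the exact parameters used, so a
log together with the original input reproduces the output bit-identically
via :func:`replay`.
"""

from __future__ import annotations

import datetime
import inspect
import json
from dataclasses import dataclass, field

import yaml

from . import preprocess
from .dataset import SpectrumSet
from .preprocess import BaselineResult

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "ProvenanceEntry",
    "ProvenanceLog",
    "registered_operations",
    "run_pipeline",
    "replay",
]


class PipelineError(RuntimeError):
    """A pipeline step failed; carries the step index and operation name."""

    def __init__(self, index: int, operation: str, cause: Exception):
        self.index = index
        self.operation = operation
        self.cause = cause
        super().__init__(
            f"step {index} ({operation}) failed: {cause}"
        )


def _as_set(result) -> SpectrumSet:
    if isinstance(result, BaselineResult):
        return result.set
    return result


_REGISTRY: dict[str, object] = {
    "interpolate_to_grid": preprocess.interpolate_to_grid,
    "crop": preprocess.crop,
    "despike": preprocess.despike,
    "smooth_savgol": preprocess.smooth_savgol,
    "smooth_fourier": preprocess.smooth_fourier,
    "baseline_airpls": preprocess.baseline_airpls,
    "baseline_polynomial": preprocess.baseline_polynomial,
    "baseline_glfit": preprocess.baseline_glfit,
    "normalize": preprocess.normalize,
}

_ALIASES = {
    "interpolate": "interpolate_to_grid",
    "savgol": "smooth_savgol",
    "fourier": "smooth_fourier",
    "airpls": "baseline_airpls",
}


def registered_operations() -> tuple[str, ...]:
    """Canonical names of the operations a pipeline config may use."""
    return tuple(_REGISTRY)


def _resolve(name: str) -> tuple[str, object]:
    canon = _ALIASES.get(name, name)
    if canon not in _REGISTRY:
        raise ValueError(
            f"unknown operation {name!r}; known: {sorted(_REGISTRY)}"
        )
    return canon, _REGISTRY[canon]


def _validate_params(canon: str, fn, params: dict) -> dict:
    """Check names, fill defaults; returns the fully expanded parameter map."""
    sig = inspect.signature(fn)
    accepted = {p for p in sig.parameters if p != "sset"}
    unknown = set(params) - accepted
    if unknown:
        raise ValueError(
            f"operation {canon!r} got unknown parameter(s) "
            f"{sorted(unknown)}; accepted: {sorted(accepted)}"
        )
    expanded = {}
    for pname, p in sig.parameters.items():
        if pname == "sset":
            continue
        if pname in params:
            expanded[pname] = params[pname]
        elif p.default is not inspect.Parameter.empty:
            expanded[pname] = p.default
        else:
            raise ValueError(
                f"operation {canon!r} is missing required parameter {pname!r}"
            )
    return expanded


@dataclass(frozen=True)
class PipelineConfig:
    """Ordered, validated list of (operation name, parameter map) steps."""

    steps: tuple[tuple[str, dict], ...]

    @classmethod
    def from_steps(cls, steps) -> "PipelineConfig":
        """Build from ``[(name, params), ...]`` or ``[{"op": name, ...}]``.

        Validation resolves every name against the operation registry and
        expands defaults; it fails before any computation runs.
        """
        norm: list[tuple[str, dict]] = []
        for step in steps:
            if isinstance(step, dict):
                step = dict(step)
                try:
                    name = step.pop("op")
                except KeyError:
                    raise ValueError(f"step {step!r} has no 'op' key") from None
                params = step.pop("params", {}) | step
            else:
                name, params = step
                params = dict(params)
            canon, fn = _resolve(str(name))
            norm.append((canon, _validate_params(canon, fn, params)))
        return cls(tuple(norm))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "steps" not in doc:
            raise ValueError(f"{path}: config must be a mapping with a 'steps' list")
        return cls.from_steps(doc["steps"])

    def to_yaml(self, path) -> None:
        doc = {"steps": [{"op": name, **params} for name, params in self.steps]}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class ProvenanceEntry:
    operation: str
    params: dict
    input_shape: tuple[int, int]  # (N, M) before the step
    output_shape: tuple[int, int]
    timestamp: str

    def to_dict(self) -> dict:
        return {
            "operation": self.operation,
            "params": self.params,
            "input_shape": list(self.input_shape),
            "output_shape": list(self.output_shape),
            "timestamp": self.timestamp,
        }


@dataclass
class ProvenanceLog:
    """Append-only record of executed steps with their exact parameters."""

    entries: list[ProvenanceEntry] = field(default_factory=list)

    def append(self, entry: ProvenanceEntry) -> None:
        self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path) -> None:
        """One JSON object per line, one line per step."""
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(json.dumps(e.to_dict()) + "\n")

    @classmethod
    def from_json(cls, path) -> "ProvenanceLog":
        entries = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                d = json.loads(line)
                entries.append(
                    ProvenanceEntry(
                        operation=d["operation"],
                        params=d["params"],
                        input_shape=tuple(d["input_shape"]),
                        output_shape=tuple(d["output_shape"]),
                        timestamp=d["timestamp"],
                    )
                )
        return cls(entries)


def run_pipeline(
    sset: SpectrumSet, config: PipelineConfig
) -> tuple[SpectrumSet, ProvenanceLog]:
    """Apply the configured steps in order to all spectra.

    The log records one entry per executed step with defaults expanded.
    The first failing step aborts the whole run (no partial output) with
    the step index and cause.
    """
    log = ProvenanceLog()
    current = sset
    for i, (name, params) in enumerate(config.steps):
        fn = _REGISTRY[name]
        shape_in = (current.n_spectra, current.n_points)
        try:
            current = _as_set(fn(current, **params))
        except Exception as exc:
            raise PipelineError(i, name, exc) from exc
        log.append(
            ProvenanceEntry(
                operation=name,
                params=dict(params),
                input_shape=shape_in,
                output_shape=(current.n_spectra, current.n_points),
                timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            )
        )
    return current, log


def replay(log: ProvenanceLog, original: SpectrumSet) -> SpectrumSet:
    """Re-execute a provenance log on the original input.

    All registered operations are deterministic, so the result is
    bit-identical to the run that produced the log.
    """
    current = original
    for i, entry in enumerate(log.entries):
        canon, fn = _resolve(entry.operation)
        try:
            current = _as_set(fn(current, **entry.params))
        except Exception as exc:
            raise PipelineError(i, canon, exc) from exc
    return current
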