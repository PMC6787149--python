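"""Characterization of input uncertainty for the PAO metabolic model.

Each uncertain input carries a collection of literature-style measurements.
The sampling range is derived from the collection with a variability level
scaled to data abundance (50/25/5% around the mean for 1, 2-10, or more
measurements), widened where needed so that it covers the observed extremes:

    a = min((1 - var) * x_mean, x_min)
    b = max((1 + var) * x_mean, x_max)

Data-rich inputs (more than 50 points) are instead described by an Erlang
distribution fitted by the method of moments. Temperature and pH are design
parameters sampled between fixed model-validation limits, and the three PHA
constituent weights are Dirichlet-coupled so they always sum to the (uniformly
sampled) total PHA fraction.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GROUPS",
    "ParameterRecord",
    "UncertaintyRange",
    "DistributionSpec",
    "variability_level",
    "uniform_bounds",
    "fit_erlang",
    "build_default_database",
    "load_database",
    "save_database",
    "export_csv",
]

GROUPS = ("metabolic", "kinetic", "arrhenius", "initial_condition", "environmental")

#: more than this many measurements triggers the Erlang fit
ERLANG_THRESHOLD = 50

PHA_WEIGHT_NAMES = ("f_PHB_i", "f_PHV_i", "f_PH2MV_i")


@dataclass(frozen=True)
class UncertaintyRange:
    """Sampling bounds [a, b] derived from a measurement collection."""

    a: float
    b: float
    var: float
    x_mean: float
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.var <= 1.0):
            raise ValueError(f"var must be in (0, 1], got {self.var}")
        if not (self.a <= self.x_min and self.b >= self.x_max):
            raise ValueError("range does not cover the observed extremes")
        if not self.a < self.b:
            raise ValueError(f"degenerate range a={self.a}, b={self.b}")


@dataclass(frozen=True)
class DistributionSpec:
    """Resolved sampling distribution of one input.

    kind is one of ``uniform`` (params ``a``, ``b``), ``erlang`` (integer
    shape ``k``, rate ``lam``) or ``dirichlet_weight`` (concentration
    ``alpha`` plus the name of the coupled weight group).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "uniform":
            if not self.params["a"] < self.params["b"]:
                raise ValueError("uniform spec requires a < b")
        elif self.kind == "erlang":
            k, lam = self.params["k"], self.params["lam"]
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise ValueError("erlang shape must be an integer >= 1")
            if not lam > 0:
                raise ValueError("erlang rate must be positive")
        elif self.kind == "dirichlet_weight":
            if not self.params["alpha"] > 0:
                raise ValueError("dirichlet concentration must be positive")
            if "coupled_group" not in self.params:
                raise ValueError("dirichlet_weight needs a coupled_group")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass
class ParameterRecord:
    """One uncertain model input and its measurement collection."""

    name: str
    group: str
    units: str = ""
    measurements: list[float] = field(default_factory=list)
    fixed_bounds: tuple[float, float] | None = None
    distribution: DistributionSpec | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.name}: unknown group {self.group!r}")
        if not all(math.isfinite(m) for m in self.measurements):
            raise ValueError(f"{self.name}: non-finite measurement")
        if self.fixed_bounds is not None:
            lo, hi = self.fixed_bounds
            if not lo < hi:
                raise ValueError(f"{self.name}: fixed_bounds must satisfy lower < upper")

    def resolve(self) -> DistributionSpec:
        """Derive (and cache) the sampling distribution for this record."""
        if self.distribution is not None:
            return self.distribution
        if self.fixed_bounds is not None:
            lo, hi = self.fixed_bounds
            spec = DistributionSpec("uniform", {"a": float(lo), "b": float(hi)})
        elif len(self.measurements) > ERLANG_THRESHOLD and _has_variance(self.measurements):
            spec = fit_erlang(self.measurements)
        else:
            rng = uniform_bounds(self.measurements)
            spec = DistributionSpec("uniform", {"a": rng.a, "b": rng.b})
        self.distribution = spec
        return spec


def _has_variance(values: Sequence[float]) -> bool:
    return len(set(values)) > 1


def variability_level(n_measurements: int) -> float:
    """Variability tier from the number of reported measurements.

    50% for a single value, 25% for 2-10 values, 5% beyond that. Zero
    measurements cannot define a range: such inputs need a fixed_bounds
    override (pure design parameters like T and pH).
    """
    if n_measurements < 1:
        raise ValueError(
            "no measurements: provide a fixed_bounds override for this parameter"
        )
    if n_measurements == 1:
        return 0.50
    if n_measurements <= 10:
        return 0.25
    return 0.05


def uniform_bounds(measurements: Sequence[float]) -> UncertaintyRange:
    """Sampling range around the sample mean, widened to the observed extremes.

    Degenerate collections (all values identical) fall back to the
    single-measurement 50% tier so the interval stays sampleable.
    """
    values = [float(m) for m in measurements]
    if not values:
        raise ValueError("empty measurement collection")
    if not all(math.isfinite(v) for v in values):
        raise ValueError("non-finite measurement")
    if not _has_variance(values):
        values = [values[0]]
    var = variability_level(len(values))
    x_mean = float(np.mean(values))
    x_min, x_max = float(min(values)), float(max(values))
    a = min((1.0 - var) * x_mean, x_min)
    b = max((1.0 + var) * x_mean, x_max)
    return UncertaintyRange(a=a, b=b, var=var, x_mean=x_mean, x_min=x_min, x_max=x_max)


def fit_erlang(measurements: Sequence[float]) -> DistributionSpec:
    """Method-of-moments Erlang fit for data-rich inputs.

    The integer shape is ``round(mean^2 / variance)`` (clamped to >= 1) and
    the rate is chosen as ``k / mean`` so the fitted mean reproduces the
    sample mean exactly.
    """
    values = np.asarray(measurements, dtype=float)
    if values.size <= ERLANG_THRESHOLD:
        raise ValueError(
            f"Erlang fit needs more than {ERLANG_THRESHOLD} points "
            f"(got {values.size}); use uniform_bounds instead"
        )
    if np.any(values <= 0):
        raise ValueError("Erlang fit requires strictly positive measurements")
    mean = float(values.mean())
    variance = float(values.var(ddof=1))
    if variance <= 0:
        raise ValueError("zero sample variance: Erlang shape is unbounded")
    k = max(1, int(round(mean * mean / variance)))
    lam = k / mean
    return DistributionSpec("erlang", {"k": k, "lam": lam})


# ---------------------------------------------------------------------------
# database I/O


def _record_from_entry(entry: dict) -> ParameterRecord:
    dist = None
    if "distribution" in entry:
        d = dict(entry["distribution"])
        kind = d.pop("kind")
        dist = DistributionSpec(kind, d)
    fb = entry.get("fixed_bounds")
    return ParameterRecord(
        name=entry["name"],
        group=entry["group"],
        units=str(entry.get("units", "")),
        measurements=[float(m) for m in entry.get("measurements", [])],
        fixed_bounds=tuple(float(x) for x in fb) if fb is not None else None,
        distribution=dist,
        description=entry.get("description", ""),
    )


def load_database(path=None) -> list[ParameterRecord]:
    """Load a parameter database from YAML and resolve every distribution."""
    if path is None:
        source = (
            importlib.resources.files("ebpr_gsa.data") / "literature_synthetic.yaml"
        )
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    records = [_record_from_entry(e) for e in raw["parameters"]]
    for rec in records:
        rec.resolve()
    _validate_database(records)
    return records


def build_default_database() -> list[ParameterRecord]:
    """The 39-input default database shipped with the package."""
    return load_database(None)


def _validate_database(records: list[ParameterRecord]) -> None:
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate parameter names in database")
    weights = [r for r in records if r.resolve().kind == "dirichlet_weight"]
    if weights and tuple(sorted(r.name for r in weights)) != tuple(
        sorted(PHA_WEIGHT_NAMES)
    ):
        raise ValueError(
            "dirichlet_weight records must be exactly the three PHA weights"
        )


def save_database(records: Sequence[ParameterRecord], path) -> None:
    """Serialize a database back to YAML (lossless round trip)."""
    entries = []
    for rec in records:
        entry: dict = {"name": rec.name, "group": rec.group, "units": rec.units}
        if rec.description:
            entry["description"] = rec.description
        if rec.measurements:
            entry["measurements"] = [float(m) for m in rec.measurements]
        if rec.fixed_bounds is not None:
            entry["fixed_bounds"] = [float(x) for x in rec.fixed_bounds]
        if rec.distribution is not None and rec.distribution.kind == "dirichlet_weight":
            entry["distribution"] = {
                "kind": "dirichlet_weight",
                **rec.distribution.params,
            }
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": entries}, fh, sort_keys=False)


def export_csv(records: Sequence[ParameterRecord], path) -> None:
    """One-row-per-record report: name, group, bounds / distribution kind."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "group", "units", "kind", "a", "b", "k", "lam"])
        for rec in records:
            spec = rec.resolve()
            if spec.kind == "uniform":
                row = [rec.name, rec.group, rec.units, "uniform",
                       spec.params["a"], spec.params["b"], "", ""]
            elif spec.kind == "erlang":
                row = [rec.name, rec.group, rec.units, "erlang", "", "",
                       spec.params["k"], spec.params["lam"]]
            else:
                row = [rec.name, rec.group, rec.units, "dirichlet_weight",
                       0.0, 1.0, "", ""]
            writer.writerow(row)
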