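"""Synthetic inputs for testing the pipeline without any external data.

Three kinds of fixture: mock literature-measurement collections spanning
the variability tiers (so the range rules and Erlang fitting are
exercised), analytic test functions with known variance decompositions
(so the Sobol/SRC estimators are verifiable), and canned EBPR cycle
scenarios. Everything is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .oracles import ishigami_truth, linear_additive_truth

__all__ = [
    "FixtureSpec",
    "AnalyticModel",
    "mock_literature",
    "analytic_models",
    "paper_scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible set of mock measurement collections."""

    seed: int
    counts: tuple[int, ...] = (1, 7, 33, 90)
    truth: dict | None = None          # name -> ("erlang", k, lam) etc.

    def __post_init__(self):
        if any(c < 1 for c in self.counts):
            raise ValueError("measurement counts must be >= 1")


def mock_literature(spec: FixtureSpec) -> dict[str, list[float]]:
    """Seeded mock measurement collections, one per requested count.

    Collections default to lognormal draws around 1.0; entries of
    ``spec.truth`` may pin a named collection to a stated distribution,
    e.g. ``{"par_90": ("erlang", 3, 2.0)}``, so downstream fits can be
    checked against a known ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, list[float]] = {}
    for count in spec.counts:
        name = f"par_{count}"
        truth = (spec.truth or {}).get(name)
        if truth is not None and truth[0] == "erlang":
            _, k, lam = truth
            values = rng.gamma(k, 1.0 / lam, size=count)
        else:
            values = rng.lognormal(0.0, 0.3, size=count)
        out[name] = [float(v) for v in values]
    return out


@dataclass(frozen=True)
class AnalyticModel:
    """A test function bundled with its closed-form sensitivity truth."""

    name: str
    n_inputs: int
    func: Callable[[np.ndarray], np.ndarray]
    truth: dict
    bounds: tuple[float, float] = (0.0, 1.0)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.func(np.asarray(x, dtype=float))


def _linear(coeffs):
    c = np.asarray(coeffs, dtype=float)

    def f(x):
        return x @ c

    return f


def _ishigami(a, b):
    def f(x):
        return (
            np.sin(x[:, 0])
            + a * np.sin(x[:, 1]) ** 2
            + b * x[:, 2] ** 4 * np.sin(x[:, 0])
        )

    return f


def analytic_models() -> dict[str, AnalyticModel]:
    """The estimator-validation suite.

    ``linear``: additive with unequal coefficients; ``linear_equal``: four
    symmetric inputs (S_i = 1/4); ``ishigami``: the standard non-linear,
    non-monotonic benchmark at (a=7, b=0.1); ``dummy``: a model ignoring
    its last input (S = ST = 0 for it).
    """
    models = {}
    c = np.array([1.0, 2.0, 0.5])
    std_u = 1.0 / np.sqrt(12.0)       # uniform(0,1) inputs
    models["linear"] = AnalyticModel(
        "linear", 3, _linear(c), linear_additive_truth(c, [std_u] * 3)
    )
    c4 = np.ones(4)
    models["linear_equal"] = AnalyticModel(
        "linear_equal", 4, _linear(c4), linear_additive_truth(c4, [std_u] * 4)
    )
    models["ishigami"] = AnalyticModel(
        "ishigami", 3, _ishigami(7.0, 0.1), ishigami_truth(7.0, 0.1),
        bounds=(-np.pi, np.pi),
    )
    c_dummy = np.array([1.0, 1.0, 0.0])
    models["dummy"] = AnalyticModel(
        "dummy", 3, _linear(c_dummy), linear_additive_truth(c_dummy, [std_u] * 3)
    )
    return models


#: canned cycle scenarios: fixed initial conditions + environment.
#: fractions are per-biomass ratios (C-mol/C-mol; P-mol/C-mol for poly-P)
#: multiplied by the biomass concentration to get absolute pools.
SCENARIOS: dict[str, dict[str, float]] = {
    "fig2_fixed_ic": {
        "S_VFA_i": 1.5,          # C-mmol/l total influent VFA
        "r_HAc_HPr_i": 0.67,
        "r_P_C_i": 1.5,
        "X_PAO_i": 4.43,         # C-mmol/l
        "f_PHA_i": 0.14,
        "f_PHB_i": 0.14 * 0.60,  # PHB-dominant constituent split
        "f_PHV_i": 0.14 * 0.25,
        "f_PH2MV_i": 0.14 * 0.15,
        "f_Gly_i": 0.36,
        "f_PP_i": 0.30,
        "T": 20.0,
        "pH": 7.0,
    },
}


def paper_scenario(name: str) -> dict[str, float]:
    """A named initial-condition/environment set for single-cycle runs."""
    try:
        return dict(SCENARIOS[name])
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
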