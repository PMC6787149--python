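"""Quasi-random Saltelli designs and their transform to physical parameters.

The cross-sampling scheme stacks the blocks ``A``, ``B`` and ``A_B^(i)``
(``A`` with column ``i`` replaced by ``B``'s), giving ``N * (M + 2)`` rows
that support simultaneous first- and total-order Sobol index estimation.
Unit-hypercube points come from an (optionally scrambled) Sobol sequence;
every transform is a pure column-wise map so index attribution per column
stays well defined, including the three Dirichlet-coupled PHA weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .uncertainty import PHA_WEIGHT_NAMES, ParameterRecord

__all__ = [
    "SampleDesign",
    "ParameterMatrix",
    "saltelli_design",
    "sobol_matrix",
    "monte_carlo_matrix",
    "transform",
    "dirichlet_weights",
    "save_design",
    "load_design",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleDesign:
    """Saltelli cross-sample on the unit hypercube.

    ``unit_matrix`` holds ``N*(M+2)`` rows: block A, block B, then the M
    hybrid blocks ``A_B^(i)`` in column order.
    """

    n_base: int
    n_params: int
    unit_matrix: np.ndarray
    seed: int | None = None
    scramble: bool = False

    def __post_init__(self) -> None:
        n, m = self.n_base, self.n_params
        if self.unit_matrix.shape != (n * (m + 2), m):
            raise ValueError("unit_matrix shape inconsistent with (n_base, n_params)")
        if not ((self.unit_matrix > 0.0) & (self.unit_matrix < 1.0)).all():
            raise ValueError("unit-hypercube values must lie strictly in (0, 1)")

    @property
    def n_rows(self) -> int:
        return self.n_base * (self.n_params + 2)

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (A, B, AB) with AB of shape (M, N, M)."""
        n, m = self.n_base, self.n_params
        a = self.unit_matrix[:n]
        b = self.unit_matrix[n : 2 * n]
        ab = self.unit_matrix[2 * n :].reshape(m, n, m)
        return a, b, ab


@dataclass
class ParameterMatrix:
    """Physical-unit parameter vectors, one model evaluation per row."""

    values: np.ndarray
    column_names: list[str]
    derived_columns: dict[str, np.ndarray] = field(default_factory=dict)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]


def sobol_matrix(
    n: int, dim: int, seed: int | None = None, scramble: bool = False
) -> np.ndarray:
    """``n`` Sobol points in ``dim`` dimensions, strictly inside (0, 1).

    The unscrambled sequence skips its initial all-zero point; scrambling
    (seeded) randomizes the digits while preserving low discrepancy.
    """
    engine = qmc.Sobol(d=dim, scramble=scramble, rng=seed if scramble else None)
    if not scramble:
        engine.fast_forward(1)
    pts = engine.random(n)
    # guard against exact 0/1 from scrambling round-off
    tiny = np.finfo(float).tiny
    return np.clip(pts, tiny, 1.0 - np.finfo(float).epsneg)


def saltelli_design(
    n_base: int,
    n_params: int,
    seed: int | None = None,
    scramble: bool = False,
) -> SampleDesign:
    """Build the N*(M+2)-row first/total-order Saltelli design."""
    if n_base < 2:
        raise ValueError("n_base must be >= 2")
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if n_base & (n_base - 1):
        logger.warning(
            "n_base=%d is not a power of two; Sobol balance properties degrade",
            n_base,
        )
    base = sobol_matrix(n_base, 2 * n_params, seed=seed, scramble=scramble)
    a, b = base[:, :n_params], base[:, n_params:]
    blocks = [a, b]
    for i in range(n_params):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    return SampleDesign(
        n_base=n_base,
        n_params=n_params,
        unit_matrix=np.vstack(blocks),
        seed=seed,
        scramble=scramble,
    )


def dirichlet_weights(
    unit_values: Sequence[float] | np.ndarray, alpha: Sequence[float]
) -> np.ndarray:
    """Map unit-hypercube values to Dirichlet simplex weights.

    Each unit value is pushed through the inverse CDF of Gamma(alpha_i, 1)
    and the results are normalized; a deterministic, column-wise transform.
    Accepts a single tuple or an (n, k) array of rows.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be strictly positive")
    u = np.atleast_2d(np.asarray(unit_values, dtype=float))
    if u.shape[1] != alpha.size:
        raise ValueError("unit value / alpha length mismatch")
    g = stats.gamma.ppf(u, alpha[np.newaxis, :])
    w = g / g.sum(axis=1, keepdims=True)
    return w[0] if np.asarray(unit_values).ndim == 1 else w


def monte_carlo_matrix(
    database: Sequence[ParameterRecord],
    n: int,
    seed: int | None = None,
    scramble: bool = False,
) -> ParameterMatrix:
    """Plain quasi-random Monte Carlo sample (no Saltelli cross blocks)."""
    u = sobol_matrix(n, len(database), seed=seed, scramble=scramble)
    return _transform_unit(u, database)


def transform(
    design: SampleDesign, database: Sequence[ParameterRecord]
) -> ParameterMatrix:
    """Map a unit-hypercube design to physical parameter vectors.

    Uniform columns map by ``a + u (b - a)``, Erlang columns through the
    gamma inverse CDF, and the three PHA weight columns through the Dirichlet
    transform scaled by the row's total PHA fraction so the constituent
    fractions always sum to it exactly.
    """
    if design.n_params != len(database):
        raise ValueError(
            f"design has {design.n_params} columns, database defines "
            f"{len(database)}"
        )
    return _transform_unit(design.unit_matrix, database)


def _transform_unit(
    u: np.ndarray, database: Sequence[ParameterRecord]
) -> ParameterMatrix:
    names = [rec.name for rec in database]
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("unit values must lie strictly in (0, 1)")

    values = np.empty_like(u)
    weight_idx: list[int] = []
    weight_alpha: list[float] = []
    for j, rec in enumerate(database):
        spec = rec.resolve()
        if spec.kind == "uniform":
            a, b = spec.params["a"], spec.params["b"]
            values[:, j] = a + u[:, j] * (b - a)
        elif spec.kind == "erlang":
            k, lam = spec.params["k"], spec.params["lam"]
            values[:, j] = stats.gamma.ppf(u[:, j], k, scale=1.0 / lam)
        elif spec.kind == "dirichlet_weight":
            weight_idx.append(j)
            weight_alpha.append(spec.params["alpha"])
        else:  # pragma: no cover - DistributionSpec already validates
            raise ValueError(f"missing spec for column {rec.name}")

    if weight_idx:
        order = [names.index(n) for n in PHA_WEIGHT_NAMES]
        if sorted(weight_idx) != sorted(order):
            raise ValueError("PHA weight columns do not match the database")
        w = dirichlet_weights(u[:, order], weight_alpha)
        total = values[:, names.index("f_PHA_i")]
        for pos, j in enumerate(order):
            values[:, j] = w[:, pos] * total

    pm = ParameterMatrix(values=values, column_names=names)
    _attach_derived(pm)
    return pm


def _attach_derived(pm: ParameterMatrix) -> None:
    """Initial liquid-phase concentrations derived from influent ratios."""
    try:
        s_vfa = pm.column("S_VFA_i")
        r = pm.column("r_HAc_HPr_i")
        rpc = pm.column("r_P_C_i")
    except ValueError:
        return
    pm.derived_columns = {
        "S_HAc_i": s_vfa * r,
        "S_HPr_i": s_vfa * (1.0 - r),
        "S_PO4_i": s_vfa * rpc,
    }


# ---------------------------------------------------------------------------
# HDF5 persistence


def save_design(path, design: SampleDesign, matrix: ParameterMatrix | None = None):
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("unit_matrix", data=design.unit_matrix)
        h5.attrs["n_base"] = design.n_base
        h5.attrs["n_params"] = design.n_params
        h5.attrs["seed"] = -1 if design.seed is None else design.seed
        h5.attrs["scramble"] = design.scramble
        if matrix is not None:
            h5.create_dataset("values", data=matrix.values)
            h5.create_dataset(
                "column_names",
                data=np.array(matrix.column_names, dtype=h5py.string_dtype()),
            )
            for key, col in matrix.derived_columns.items():
                h5.create_dataset(f"derived/{key}", data=col)


def load_design(path) -> tuple[SampleDesign, ParameterMatrix | None]:
    import h5py

    with h5py.File(path, "r") as h5:
        seed = int(h5.attrs["seed"])
        design = SampleDesign(
            n_base=int(h5.attrs["n_base"]),
            n_params=int(h5.attrs["n_params"]),
            unit_matrix=h5["unit_matrix"][()],
            seed=None if seed < 0 else seed,
            scramble=bool(h5.attrs["scramble"]),
        )
        matrix = None
        if "values" in h5:
            matrix = ParameterMatrix(
                values=h5["values"][()],
                column_names=[s.decode() for s in h5["column_names"][()]],
                derived_columns={
                    k: h5[f"derived/{k}"][()] for k in h5.get("derived", {})
                },
            )
    return design, matrix
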