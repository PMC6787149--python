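"""Sensitivity measures: standardized regression coefficients and Sobol indices.

SRC come from per-output ordinary least squares on the Monte Carlo sample,
rescaled by input/output standard deviations; their squares approximate
first-order Sobol indices only for near-linear responses, so each output
carries an R^2 linearity diagnostic (rule of thumb: valid when R^2 >= 0.7).

Variance decomposition uses the Saltelli cross-sample: first-order indices
with the Saltelli (2010) estimator

    S_i  = mean(f_B * (f_ABi - f_A)) / Var(Y)

and total-order indices with the Jansen estimator

    ST_i = mean((f_A - f_ABi)^2) / (2 Var(Y)),

with Var(Y) taken on the pooled A and B sample. Confidence intervals come
from a percentile bootstrap over base-sample indices, keeping each
(A, B, A_B^i) tuple intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegressionResult",
    "SobolResult",
    "RankingTable",
    "standardized_regression",
    "split_output_blocks",
    "sobol_indices",
    "bootstrap_ci",
    "normalize_and_rank",
    "LINEARITY_RSQUARED",
]

logger = logging.getLogger(__name__)

#: R^2 rule-of-thumb above which SRC are a valid first-order measure
LINEARITY_RSQUARED = 0.7


@dataclass
class RegressionResult:
    """Standardized regression coefficients per (input, output) pair."""

    beta: np.ndarray               # (M, K)
    raw_b: np.ndarray              # (M, K) unstandardized slopes
    intercepts: np.ndarray         # (K,)
    r_squared: np.ndarray          # (K,)
    residual_variance: np.ndarray  # (K,)
    linear: np.ndarray             # (K,) bool linearity verdicts
    input_names: list[str] | None = None
    output_names: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, index=self.input_names, columns=self.output_names)
        df.loc["R_squared"] = self.r_squared
        return df


@dataclass
class SobolResult:
    """First- and total-order Sobol indices with bootstrap uncertainty."""

    s1: np.ndarray                 # (M, K)
    st: np.ndarray                 # (M, K)
    s1_ci: np.ndarray | None = None
    st_ci: np.ndarray | None = None
    n_base: int = 0
    n_boot: int = 0
    conf_level: float = 0.95
    input_names: list[str] | None = None
    output_names: list[str] | None = None

    def frame(self, which: str = "st") -> pd.DataFrame:
        arr = getattr(self, which)
        return pd.DataFrame(arr, index=self.input_names, columns=self.output_names)


@dataclass
class RankingTable:
    """Per-output orderings and normalized total effects."""

    normalized_st: pd.DataFrame              # rows: inputs, cols: outputs; sums to 1
    per_output: dict[str, list[str]]         # ranked inputs above cut-off
    per_group: dict[str, pd.DataFrame] = field(default_factory=dict)
    cutoffs: dict[str, float] = field(default_factory=dict)


def standardized_regression(
    inputs: np.ndarray,
    outputs: np.ndarray,
    input_names=None,
    output_names=None,
    allow_collinear: bool = False,
) -> RegressionResult:
    """Per-output OLS of the Monte Carlo outputs on all sampled inputs.

    ``beta[m, k] = b[m, k] * sigma_m / sigma_k``. Constant output columns
    get R^2 = 0 (logged); rank-deficient designs raise, naming the
    collinear columns. With ``allow_collinear=True`` the minimum-norm OLS
    solution is used instead: R^2 is invariant to that choice, which is
    what the pipeline needs because the Dirichlet-coupled PHA fractions
    introduce one exact linear dependency by construction.
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(outputs, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, m = x.shape
    if n <= m + 1:
        raise ValueError(f"need more samples than inputs (N={n}, M={m})")
    if x.shape[0] != y.shape[0]:
        raise ValueError("inputs/outputs row mismatch")

    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < m + 1 and not allow_collinear:
        sx = x.std(axis=0)
        suspects = [
            (input_names[j] if input_names else f"x{j}")
            for j in range(m)
            if sx[j] == 0.0
        ]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {m + 1}); "
            f"zero-variance/collinear columns: {suspects or 'cross-collinearity'}"
        )

    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    intercepts, raw_b = coef[0], coef[1:]
    resid = y - design @ coef
    sig_x = x.std(axis=0, ddof=0)
    sig_y = y.std(axis=0, ddof=0)
    var_y = y.var(axis=0, ddof=0)
    k = y.shape[1]
    beta = np.zeros((m, k))
    r2 = np.zeros(k)
    for j in range(k):
        if sig_y[j] == 0.0:
            logger.warning("output %d is constant: R^2 set to 0 by convention", j)
            continue
        beta[:, j] = raw_b[:, j] * sig_x / sig_y[j]
        r2[j] = 1.0 - resid[:, j].var(ddof=0) / var_y[j]
    return RegressionResult(
        beta=beta,
        raw_b=raw_b,
        intercepts=intercepts,
        r_squared=r2,
        residual_variance=resid.var(axis=0, ddof=0),
        linear=r2 >= LINEARITY_RSQUARED,
        input_names=list(input_names) if input_names is not None else None,
        output_names=list(output_names) if output_names is not None else None,
    )


def split_output_blocks(values: np.ndarray, n_base: int, n_params: int):
    """Split Saltelli-ordered evaluations into (f_A, f_B, f_AB) blocks.

    ``values`` has N*(M+2) rows (any trailing output axes preserved);
    ``f_AB`` gains a leading axis of length M. Rows belonging to failed
    simulations should be NaN: every (A, B, AB_i) tuple touching a NaN is
    dropped pairwise by the estimators.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != n_base * (n_params + 2):
        raise ValueError("row count does not match n_base * (n_params + 2)")
    f_a = values[:n_base]
    f_b = values[n_base : 2 * n_base]
    f_ab = values[2 * n_base :].reshape((n_params, n_base) + values.shape[1:])
    return f_a, f_b, f_ab


def _valid_mask(f_a, f_b, f_ab):
    """Base-sample tuples with no failed member anywhere."""
    bad = np.isnan(f_a) | np.isnan(f_b)
    if f_a.ndim > 1:
        bad = bad.any(axis=tuple(range(1, f_a.ndim)))
    bad_ab = np.isnan(f_ab)
    if bad_ab.ndim > 1:
        bad_ab = bad_ab.any(axis=tuple(i for i in range(bad_ab.ndim) if i != 1))
    return ~(bad | bad_ab)


def _estimate(f_a, f_b, f_ab):
    """Saltelli-2010 S1 and Jansen ST for one output; inputs (N,), (M, N).

    Outputs are centered on the pooled A/B mean first, which makes the
    estimates exactly invariant to affine rescaling of the output.
    """
    pooled = np.concatenate([f_a, f_b])
    var = pooled.var(ddof=0)
    if var <= 0.0:
        raise ValueError("degenerate output: Var(Y) = 0")
    mu = pooled.mean()
    f_a = f_a - mu
    f_b = f_b - mu
    f_ab = f_ab - mu
    s1 = np.mean(f_b[None, :] * (f_ab - f_a[None, :]), axis=1) / var
    st = np.mean((f_a[None, :] - f_ab) ** 2, axis=1) / (2.0 * var)
    return s1, st


def sobol_indices(
    output_blocks,
    input_names=None,
    output_names=None,
) -> SobolResult:
    """First- and total-order indices from (f_A, f_B, f_AB) blocks.

    ``f_A``/``f_B`` are (N,) or (N, K); ``f_AB`` adds the leading input
    axis (M, N[, K]). NaN rows (failed simulations) drop their whole
    base-sample tuple.
    """
    f_a, f_b, f_ab = (np.asarray(b, dtype=float) for b in output_blocks)
    n = f_a.shape[0]
    if f_b.shape != f_a.shape or f_ab.shape[1] != n:
        raise ValueError("mismatched Saltelli block shapes")
    if f_a.ndim == 1:
        f_a, f_b, f_ab = f_a[:, None], f_b[:, None], f_ab[:, :, None]
    keep = _valid_mask(f_a, f_b, f_ab)
    if keep.sum() < 2:
        raise ValueError("fewer than two complete Saltelli tuples")
    f_a, f_b, f_ab = f_a[keep], f_b[keep], f_ab[:, keep]

    m, _, k = f_ab.shape
    s1 = np.empty((m, k))
    st = np.empty((m, k))
    for j in range(k):
        s1[:, j], st[:, j] = _estimate(f_a[:, j], f_b[:, j], f_ab[:, :, j])
    return SobolResult(
        s1=s1,
        st=st,
        n_base=int(keep.sum()),
        input_names=list(input_names) if input_names is not None else None,
        output_names=list(output_names) if output_names is not None else None,
    )


def bootstrap_ci(
    output_blocks,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | None = None,
    batch: int = 50,
):
    """Percentile-bootstrap CI half-widths for S1 and ST.

    Resamples base-sample indices with replacement, keeping each
    (A, B, A_B^i) tuple intact; deterministic under a fixed seed.
    Returns ``(s1_ci, st_ci)`` with shape (M, K).
    """
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    if n_boot < 100:
        logger.warning("n_boot=%d < 100: CI estimates will be rough", n_boot)
    f_a, f_b, f_ab = (np.asarray(b, dtype=float) for b in output_blocks)
    if f_a.ndim == 1:
        f_a, f_b, f_ab = f_a[:, None], f_b[:, None], f_ab[:, :, None]
    keep = _valid_mask(f_a, f_b, f_ab)
    f_a, f_b, f_ab = f_a[keep], f_b[keep], f_ab[:, keep]
    n = f_a.shape[0]
    if n < 32:
        raise ValueError("need at least 32 base samples for a bootstrap")

    m, _, k = f_ab.shape
    rng = np.random.default_rng(seed)
    qs = (0.5 * (1 - conf), 1 - 0.5 * (1 - conf))
    s1_samples = np.empty((n_boot, m, k))
    st_samples = np.empty((n_boot, m, k))
    done = 0
    while done < n_boot:
        nb = min(batch, n_boot - done)
        idx = rng.integers(0, n, size=(nb, n))
        a = f_a[idx]                        # (nb, n, k)
        b = f_b[idx]
        ab = f_ab[:, idx]                   # (m, nb, n, k)
        pooled = np.concatenate([a, b], axis=1)
        var = pooled.var(axis=1, ddof=0)    # (nb, k)
        var = np.where(var > 0, var, np.nan)
        mu = pooled.mean(axis=1)[:, None, :]
        a = a - mu
        b = b - mu
        ab = ab - mu[None]
        s1_samples[done : done + nb] = np.moveaxis(
            np.mean(b[None] * (ab - a[None]), axis=2), 0, 1
        ) / var[:, None, :]
        st_samples[done : done + nb] = np.moveaxis(
            np.mean((a[None] - ab) ** 2, axis=2), 0, 1
        ) / (2.0 * var[:, None, :])
        done += nb

    def half_width(samples):
        lo, hi = np.nanquantile(samples, qs, axis=0)
        return 0.5 * (hi - lo)

    s1_hw, st_hw = half_width(s1_samples), half_width(st_samples)
    # constant outputs carry no estimator uncertainty: zero-width CI
    degenerate = np.concatenate([f_a, f_b], axis=0).var(axis=0) == 0.0
    s1_hw[:, degenerate] = 0.0
    st_hw[:, degenerate] = 0.0
    return s1_hw, st_hw


def normalize_and_rank(
    sobol: SobolResult,
    groups: dict[str, str] | None = None,
    cutoffs: dict[str, float] | None = None,
) -> RankingTable:
    """Normalize total-order indices per output (sum = 1) and rank inputs.

    Negative estimates are clamped to 0 before normalizing (logged);
    entries below the display cut-off are suppressed from the ranked lists
    but retained in the normalized table. Ties break by input order.
    """
    cutoffs = {"first": 0.05, "total": 0.3, **(cutoffs or {})}
    st = np.array(sobol.st, dtype=float)
    if np.any(st < 0):
        logger.info("clamping %d negative total-order estimates to 0", (st < 0).sum())
        st = np.clip(st, 0.0, None)
    col_sums = st.sum(axis=0)
    if np.any(col_sums <= 0.0):
        raise ValueError("all-zero total-order column: nothing to normalize")
    normalized = st / col_sums

    m, k = st.shape
    inames = sobol.input_names or [f"x{i}" for i in range(m)]
    onames = sobol.output_names or [f"y{j}" for j in range(k)]
    norm_df = pd.DataFrame(normalized, index=inames, columns=onames)

    per_output: dict[str, list[str]] = {}
    for j, out in enumerate(onames):
        order = np.argsort(-st[:, j], kind="stable")
        per_output[out] = [
            inames[i] for i in order if st[i, j] >= cutoffs["total"]
        ]

    per_group: dict[str, pd.DataFrame] = {}
    if groups:
        for grp in dict.fromkeys(groups.values()):
            members = [n for n in inames if groups.get(n) == grp]
            sub = norm_df.loc[members]
            ranked = {
                out: list(sub[out].sort_values(ascending=False, kind="stable").index)
                for out in onames
            }
            per_group[grp] = pd.DataFrame(ranked)
    return RankingTable(
        normalized_st=norm_df,
        per_output=per_output,
        per_group=per_group,
        cutoffs=cutoffs,
    )


def plot_heatmap(frame: pd.DataFrame, path=None, cutoff: float = 0.0,
                 title: str | None = None):
    """Export an index heatmap (outputs as rows, inputs as columns)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = frame.T.where(frame.T >= cutoff)
    fig, ax = plt.subplots(
        figsize=(0.35 * len(frame.index) + 2, 0.35 * len(frame.columns) + 1.5)
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(data.index)), data.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
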