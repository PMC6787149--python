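"""High-level Model/Results interface for the full sensitivity study.

:class:`GlobalSensitivityAnalysis` is constructed from a parameter database
(and optionally a custom design size); :meth:`~GlobalSensitivityAnalysis.fit`
runs the whole pipeline — Saltelli design, transform, Monte Carlo
propagation, SRC regression and Sobol decomposition with bootstrap CIs —
and returns a :class:`GSAResults` carrying the estimates, their
uncertainties, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import OUTPUT_NAMES
from .propagation import OutputTensor, run_batch, summarize
from .sampling import ParameterMatrix, SampleDesign, saltelli_design, transform
from .sensitivity import (
    RankingTable,
    RegressionResult,
    SobolResult,
    bootstrap_ci,
    normalize_and_rank,
    sobol_indices,
    split_output_blocks,
    standardized_regression,
)
from .uncertainty import ParameterRecord, build_default_database

__all__ = ["GlobalSensitivityAnalysis", "GSAResults"]


class GlobalSensitivityAnalysis:
    """Global sensitivity analysis of the PAO cycle model.

    Parameters
    ----------
    database
        Uncertain-input records; defaults to the shipped 39-input database.
    n_base
        Saltelli base sample size N; the design evaluates N*(M+2) vectors.
    seed
        Controls Sobol-sequence scrambling and the bootstrap; the pipeline
        is fully deterministic given (n_base, seed, scramble).
    scramble
        Scramble the quasi-random sequence (recommended whenever a seed is
        given; the unscrambled sequence is a fixed point set).
    """

    def __init__(
        self,
        database: list[ParameterRecord] | None = None,
        n_base: int = 512,
        seed: int | None = None,
        scramble: bool = False,
        n_grid: int = 301,
        n_jobs: int = 1,
    ):
        self.database = database if database is not None else build_default_database()
        self.n_base = int(n_base)
        self.seed = seed
        self.scramble = scramble
        self.n_grid = int(n_grid)
        self.n_jobs = int(n_jobs)
        self.input_names = [r.name for r in self.database]
        self.groups = {r.name: r.group for r in self.database}

    def fit(self, n_boot: int = 1000, conf: float = 0.95) -> "GSAResults":
        """Run the full design -> simulate -> estimate pipeline."""
        m = len(self.database)
        if 2 * self.n_base <= m + 1:
            raise ValueError(
                f"n_base={self.n_base} too small: the SRC regression runs on "
                f"the 2*n_base A/B rows and needs more rows than the "
                f"{m} inputs"
            )
        design = saltelli_design(
            self.n_base, len(self.database), seed=self.seed, scramble=self.scramble
        )
        matrix = transform(design, self.database)
        tensor = run_batch(
            matrix, n_grid=self.n_grid, n_jobs=self.n_jobs, keep_trajectories=False
        )
        y = tensor.cycle_means.T                       # (rows, K)

        # SRC on the independent A and B blocks only (plain Monte Carlo part)
        n = self.n_base
        mc_rows = np.arange(2 * n)
        ok = ~np.isnan(y[mc_rows]).any(axis=1)
        regression = standardized_regression(
            matrix.values[mc_rows][ok],
            y[mc_rows][ok],
            input_names=self.input_names,
            output_names=list(OUTPUT_NAMES),
            allow_collinear=True,
        )

        blocks = split_output_blocks(y, n, len(self.database))
        sobol = sobol_indices(
            blocks, input_names=self.input_names, output_names=list(OUTPUT_NAMES)
        )
        boot_seed = None if self.seed is None else (self.seed + 0x5EED) % (2**31)
        sobol.s1_ci, sobol.st_ci = bootstrap_ci(
            blocks, n_boot=n_boot, conf=conf, seed=boot_seed
        )
        sobol.n_boot = n_boot
        sobol.conf_level = conf
        ranking = normalize_and_rank(sobol, groups=self.groups)
        return GSAResults(
            model=self,
            design=design,
            matrix=matrix,
            tensor=tensor,
            regression=regression,
            sobol=sobol,
            ranking=ranking,
        )


@dataclass
class GSAResults:
    """Fitted sensitivity estimates with diagnostics and exports."""

    model: GlobalSensitivityAnalysis
    design: SampleDesign
    matrix: ParameterMatrix
    tensor: OutputTensor
    regression: RegressionResult
    sobol: SobolResult
    ranking: RankingTable

    @property
    def max_r_squared(self) -> float:
        return float(np.max(self.regression.r_squared))

    @property
    def max_first_order(self) -> float:
        return float(np.max(self.sobol.s1))

    def output_moments(self) -> pd.DataFrame:
        summary, _ = summarize(self.tensor)
        return pd.DataFrame(
            {"mu": summary.mu, "var": summary.var}, index=list(summary.output_names)
        )

    def summary(self) -> str:
        """Human-readable overview in the spirit of a fit report."""
        reg, sob = self.regression, self.sobol
        lines = [
            "Global sensitivity analysis: PAO anaerobic-aerobic cycle model",
            "=" * 64,
            f"inputs M = {len(self.model.input_names)}   outputs K = {len(OUTPUT_NAMES)}",
            f"Saltelli base N = {self.model.n_base}  "
            f"({self.design.unit_matrix.shape[0]} model evaluations, "
            f"{len(self.tensor.failed_rows)} failed)",
            "",
            "Linearity diagnostic (R^2 per output; SRC valid when >= 0.7):",
        ]
        r2 = pd.Series(reg.r_squared, index=OUTPUT_NAMES)
        lines.append(r2.round(4).to_string())
        lines += [
            "",
            f"max R^2 = {self.max_r_squared:.4f} -> "
            + ("linear regression is adequate"
               if bool(reg.linear.any())
               else "outputs are non-linear in the inputs; SRC unreliable"),
            "",
            f"first-order Sobol indices: max = {self.max_first_order:.4f}",
            f"total-order Sobol indices: max = {float(np.max(sob.st)):.4f}",
        ]
        if sob.st_ci is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                rel = np.nanmean(
                    np.where(sob.st > 0.01, sob.st_ci / sob.st, np.nan)
                )
            lines.append(
                f"bootstrap CI half-width, mean relative to ST: {rel:.1%} "
                f"(conf {sob.conf_level:.0%}, {sob.n_boot} resamples)"
            )
        lines += ["", "top total-order inputs per output (normalized ST):"]
        for out in OUTPUT_NAMES:
            top = self.ranking.normalized_st[out].nlargest(3)
            entry = ", ".join(f"{n} {v:.2f}" for n, v in top.items())
            lines.append(f"  {out:>8s}: {entry}")
        return "\n".join(lines)

    def to_csv(self, outdir) -> None:
        """Write src/sobol/ci/normalized/ranking tables as CSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        inames = self.model.input_names
        onames = list(OUTPUT_NAMES)
        self.regression.to_frame().to_csv(outdir / "src.csv")
        self.sobol.frame("s1").to_csv(outdir / "sobol_s1.csv")
        self.sobol.frame("st").to_csv(outdir / "sobol_st.csv")
        if self.sobol.s1_ci is not None:
            pd.concat(
                {
                    "s1_ci": pd.DataFrame(self.sobol.s1_ci, index=inames, columns=onames),
                    "st_ci": pd.DataFrame(self.sobol.st_ci, index=inames, columns=onames),
                },
                names=["index", "input"],
            ).to_csv(outdir / "sobol_ci.csv")
        self.ranking.normalized_st.to_csv(outdir / "normalized_st.csv")
        rank_df = pd.DataFrame.from_dict(
            self.ranking.per_output, orient="index"
        ).T
        rank_df.to_csv(outdir / "rankings.csv", index=False)

    def plot_heatmaps(self, outdir, cutoff_first: float = 0.05,
                      cutoff_total: float = 0.3) -> None:
        from .sensitivity import plot_heatmap

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        plot_heatmap(self.sobol.frame("s1"), outdir / "sobol_s1.png",
                     cutoff=cutoff_first, title="first-order Sobol indices")
        plot_heatmap(self.sobol.frame("st"), outdir / "sobol_st.png",
                     cutoff=cutoff_total, title="total-order Sobol indices")
        beta2 = pd.DataFrame(
            self.regression.beta**2,
            index=self.model.input_names, columns=list(OUTPUT_NAMES),
        )
        plot_heatmap(beta2, outdir / "src_squared.png",
                     cutoff=cutoff_first, title="squared SRC")
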