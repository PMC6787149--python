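"""Monte Carlo propagation of sampled parameter vectors through the model.

Evaluates one 5 h cycle per row of a parameter matrix, assembles the
T x K x N output tensor (or only the K x N cycle-mean matrix when
trajectories are not needed), and summarizes output distributions. Results
are deterministic for a fixed matrix and independent of evaluation order
and of the number of worker threads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model as _model
from .model import OUTPUT_NAMES, PARAM_NAMES, StoichConstants
from .sampling import ParameterMatrix

__all__ = [
    "OutputTensor",
    "CycleMeans",
    "run_batch",
    "cycle_mean",
    "summarize",
    "save_outputs",
    "load_outputs",
]

#: hard ceiling on the tolerated fraction of failed simulations
MAX_FAILED_FRACTION = 0.01


@dataclass
class OutputTensor:
    """T x K x N simulated outputs for K = 10 components."""

    values: np.ndarray | None          # (T, K, N) or None when means-only
    cycle_means: np.ndarray            # (K, N), NaN for failed rows
    output_names: tuple[str, ...]
    time_grid: np.ndarray
    failed_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.cycle_means.shape[1]

    @property
    def failed_fraction(self) -> float:
        return len(self.failed_rows) / max(self.n_samples, 1)


@dataclass
class CycleMeans:
    """Time-averaged concentrations per sample with per-output moments."""

    means: np.ndarray                  # (K, N)
    output_names: tuple[str, ...]
    mu: np.ndarray                     # (K,)
    var: np.ndarray                    # (K,)


_STATUS_REASONS = {1: "step-size failure", 2: "non-finite state"}


def run_batch(
    matrix: ParameterMatrix | np.ndarray,
    n_grid: int = 301,
    keep_trajectories: bool = False,
    n_jobs: int = 1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    const: StoichConstants | None = None,
) -> OutputTensor:
    """Simulate every row of a parameter matrix.

    Failures are recorded per row (means set to NaN), not raised — unless
    they exceed :data:`MAX_FAILED_FRACTION`, which signals a mis-specified
    parameter range. ``n_jobs`` only sets compiled-loop threads; results
    are bitwise identical for any worker count.
    """
    import numba

    from . import _kernel

    values = matrix.values if isinstance(matrix, ParameterMatrix) else np.asarray(matrix)
    if values.ndim != 2 or values.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"parameter matrix must have {len(PARAM_NAMES)} columns")
    if isinstance(matrix, ParameterMatrix) and list(matrix.column_names) != list(PARAM_NAMES):
        raise ValueError("parameter-matrix columns do not match the model inputs")

    cvec = (const or _model._default_constants()).vector()
    values = np.ascontiguousarray(values, dtype=np.float64)
    old_threads = numba.get_num_threads()
    numba.set_num_threads(min(max(1, n_jobs), numba.config.NUMBA_NUM_THREADS))
    try:
        if keep_trajectories:
            traj, status = _kernel.batch_trajectories(values, cvec, n_grid, rtol, atol)
            tensor = np.ascontiguousarray(np.moveaxis(traj, 0, -1))  # (T, K, N)
            means = np.empty((10, values.shape[0]))
            for i in range(values.shape[0]):
                means[:, i] = (
                    cycle_mean_grid(traj[i]) if status[i] == 0 else np.nan
                )
        else:
            m, status = _kernel.batch_cycle_means(values, cvec, n_grid, rtol, atol)
            tensor = None
            means = m.T.copy()
    finally:
        numba.set_num_threads(old_threads)

    failed = [
        (int(i), _STATUS_REASONS.get(int(s), f"status {int(s)}"))
        for i, s in enumerate(status)
        if s != 0
    ]
    out = OutputTensor(
        values=tensor,
        cycle_means=means,
        output_names=OUTPUT_NAMES,
        time_grid=np.linspace(0.0, 5.0, n_grid),
        failed_rows=failed,
    )
    if out.failed_fraction > MAX_FAILED_FRACTION:
        raise RuntimeError(
            f"{len(failed)}/{out.n_samples} simulations failed "
            f"(> {MAX_FAILED_FRACTION:.0%}): mis-specified parameter ranges? "
            f"first failures: {failed[:5]}"
        )
    return out


def cycle_mean_grid(states: np.ndarray) -> np.ndarray:
    """Trapezoidal time-average of a (T, K) trajectory on its uniform grid."""
    t = states.shape[0]
    w = np.ones(t)
    w[0] = w[-1] = 0.5
    return w @ states / (t - 1)


def cycle_mean(trajectory, time_grid: np.ndarray | None = None) -> np.ndarray:
    """K-vector of trapezoidal time-averages over the 5 h cycle."""
    if isinstance(trajectory, _model.Trajectory):
        states = trajectory.outputs
        times = trajectory.times
    else:
        states = np.asarray(trajectory)
        times = time_grid
    if times is not None:
        dt = np.diff(times)
        if states.shape[0] != times.size or not np.allclose(dt, dt[0]):
            raise ValueError("trajectory is not on the shared uniform grid")
    return cycle_mean_grid(states)


def summarize(
    cycle_means: np.ndarray | OutputTensor, n_bins: int = 30
) -> tuple[CycleMeans, dict[str, np.ndarray]]:
    """Per-output moments and normalized histograms of the cycle means.

    Histogram counts are normalized to occurrence fractions in [0, 1].
    Failed (NaN) samples are excluded; at least two valid samples are
    required.
    """
    means = (
        cycle_means.cycle_means
        if isinstance(cycle_means, OutputTensor)
        else np.asarray(cycle_means, dtype=float)
    )
    valid = means[:, ~np.isnan(means).any(axis=0)]
    if valid.shape[1] < 2:
        raise ValueError("need at least two non-failed samples to summarize")
    mu = valid.mean(axis=1)
    var = valid.var(axis=1)
    histograms: dict[str, np.ndarray] = {}
    for k, name in enumerate(OUTPUT_NAMES[: means.shape[0]]):
        counts, edges = np.histogram(valid[k], bins=n_bins)
        histograms[name] = np.vstack([edges[:-1], edges[1:], counts / valid.shape[1]])
    summary = CycleMeans(
        means=means, output_names=OUTPUT_NAMES[: means.shape[0]], mu=mu, var=var
    )
    return summary, histograms


# ---------------------------------------------------------------------------
# persistence


def save_outputs(path, tensor: OutputTensor) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        if tensor.values is not None:
            h5.create_dataset("tensor", data=tensor.values,
                              chunks=(tensor.values.shape[0], 10, 1))
        h5.create_dataset("cycle_means", data=tensor.cycle_means)
        h5.create_dataset("time_grid", data=tensor.time_grid)
        h5.create_dataset(
            "output_names",
            data=np.array(tensor.output_names, dtype=h5py.string_dtype()),
        )
        h5.create_dataset(
            "failed_rows",
            data=np.array([i for i, _ in tensor.failed_rows], dtype=np.int64),
        )


def load_outputs(path) -> OutputTensor:
    import h5py

    with h5py.File(path, "r") as h5:
        return OutputTensor(
            values=h5["tensor"][()] if "tensor" in h5 else None,
            cycle_means=h5["cycle_means"][()],
            output_names=tuple(s.decode() for s in h5["output_names"][()]),
            time_grid=h5["time_grid"][()],
            failed_rows=[(int(i), "recorded failure") for i in h5["failed_rows"][()]],
        )
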