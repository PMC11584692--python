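"""Parameter calibration against normalized time-course datasets.

All observations are relative levels (densitometry/ELISA style): either
normalized to the series maximum or to the pre-stimulus control baseline.
The objective is a weighted sum of squared residuals between the normalized
simulation (interpolated to the dataset timepoints) and the dataset values,
summed over all datasets simultaneously.

Optimization is a bounded generalized pattern search in log-parameter
space, so the multiplicative 0.5x-2x bounds become a symmetric box and
steps are relative.  Polling is opportunistic (move on first improving
direction, last successful direction tried first) with mesh expansion on
success and contraction on failure — derivative-free and deterministic
under a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ModelNetwork, ParameterSet
from .simulate import SimSettings, Trajectory
from .protocols import StimulusProtocol, run_protocol
from .scoring import NormalizationError, normalized_marker

log = logging.getLogger(__name__)

#: objective contribution of a failed simulation (large finite penalty)
FAILURE_PENALTY = 1e6


@dataclass
class CalibrationDataset:
    dataset_id: str
    protocol: StimulusProtocol
    observable: str
    timepoints: np.ndarray
    values: np.ndarray
    normalization: str = "to_max"  # or "to_baseline"
    weight: float = 1.0
    module: str | None = None
    true_params: dict[str, float] | None = None  # provenance for recovery

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.size != self.values.size or self.timepoints.size < 2:
            raise ValueError(
                f"dataset {self.dataset_id}: need >= 2 matching time/value pairs"
            )
        if self.normalization not in ("to_max", "to_baseline"):
            raise ValueError(f"dataset {self.dataset_id}: unknown normalization")
        if self.weight <= 0:
            raise ValueError(f"dataset {self.dataset_id}: weight must be positive")
        if np.any(self.values < 0):
            raise ValueError(f"dataset {self.dataset_id}: negative values")
        if self.normalization == "to_max" and self.values.max() > 1 + 1e-6:
            raise ValueError(
                f"dataset {self.dataset_id}: to_max values must be <= 1"
            )


def normalize_observable(
    traj: Trajectory, observable: str, normalization: str
) -> tuple[np.ndarray, np.ndarray]:
    """Observable series on the post-stimulus grid, normalized like the data.

    ``to_max`` divides by the series maximum over the protocol; ``to_baseline``
    divides by the pre-stimulus control value.  Secreted cytokines are read
    as cumulative secretion (consistent with scoring).
    """
    times, series = normalized_marker(traj, observable, None) \
        if _is_scored_marker(traj, observable) else _raw_series(traj, observable)
    if normalization == "to_max":
        peak = series.max()
        if peak <= 0:
            raise NormalizationError(f"{observable}: zero maximum")
        return times, series / peak
    if normalization == "to_baseline":
        base = series[0]
        if base <= 0:
            raise NormalizationError(f"{observable}: zero baseline")
        return times, series / base
    raise ValueError(f"unknown normalization {normalization!r}")


def _is_scored_marker(traj: Trajectory, observable: str) -> bool:
    return observable in traj.cumulative


def _raw_series(traj, observable):
    sel = traj.times >= -1e-12
    return traj.times[sel], traj.get(observable)[sel]


def objective(
    network: ModelNetwork,
    params: ParameterSet,
    datasets: list[CalibrationDataset],
    quiescent_state: np.ndarray,
    settings: SimSettings | None = None,
) -> float:
    """Weighted sum of squared residuals over all datasets."""
    if not datasets:
        raise ValueError("no datasets")
    # one simulation per distinct protocol
    groups: dict[int, list[CalibrationDataset]] = {}
    for ds in datasets:
        groups.setdefault(id(ds.protocol), []).append(ds)
    total = 0.0
    for dss in groups.values():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = run_protocol(
                    network, params, quiescent_state, dss[0].protocol, settings
                )
        except Exception as exc:  # noqa: BLE001 - penalty, keep searching
            log.warning("objective: simulation failed (%s); penalty applied", exc)
            total += FAILURE_PENALTY * len(dss)
            continue
        for ds in dss:
            times, series = normalize_observable(traj, ds.observable,
                                                 ds.normalization)
            pred = np.interp(ds.timepoints, times, series)
            if ds.normalization == "to_max":
                # the data are normalized to the measured maximum, so the
                # prediction is renormalized over the same timepoints
                peak = pred.max()
                if peak <= 0:
                    total += FAILURE_PENALTY
                    continue
                pred = pred / peak
            total += ds.weight * float(np.sum((pred - ds.values) ** 2))
    return total


@dataclass
class FitResult:
    values: dict[str, float]
    objective: float
    start_objective: float
    iterations: int
    n_evaluations: int
    converged: bool
    free_param_ids: list[str] = field(default_factory=list)
    per_dataset_sse: dict[str, float] = field(default_factory=dict)


def pattern_search_fit(
    network: ModelNetwork,
    params0: ParameterSet,
    free_param_ids: list[str],
    datasets: list[CalibrationDataset],
    quiescent_state: np.ndarray,
    max_iterations: int = 10000,
    seed: int = 0,
    initial_mesh: float = 0.25,
    mesh_tolerance: float = 1e-3,
    settings: SimSettings | None = None,
) -> FitResult:
    """Bounded derivative-free pattern search in log-parameter space.

    Never returns a point worse than ``params0``; deterministic under seed.
    Free parameters are constrained to their bounds in ``params0`` (default
    0.5x-2x of baseline).
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not free_param_ids:
        raise ValueError("no free parameters")
    missing = [p for p in free_param_ids if p not in params0.values]
    if missing:
        raise KeyError(f"unknown parameters: {missing}")
    rng = np.random.default_rng(seed)
    k = len(free_param_ids)
    x0 = np.log([params0.values[p] for p in free_param_ids])
    lo = np.log([params0.bounds.get(p, (0.5 * params0.values[p],))[0]
                 for p in free_param_ids])
    hi = np.log([params0.bounds.get(p, (None, 2.0 * params0.values[p]))[-1]
                 for p in free_param_ids])

    def make_params(x: np.ndarray) -> ParameterSet:
        vals = dict(params0.values)
        for pid, xi in zip(free_param_ids, x):
            vals[pid] = float(np.exp(xi))
        return ParameterSet(vals)

    evals = 0

    def f(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        return objective(network, make_params(x), datasets, quiescent_state,
                         settings)

    x = x0.copy()
    fx = f(x)
    f_start = fx
    mesh = initial_mesh
    directions = [(j, s) for j in range(k) for s in (+1.0, -1.0)]
    iterations = 0
    while iterations < max_iterations and mesh >= mesh_tolerance:
        iterations += 1
        rng.shuffle(directions)
        improved = False
        for di, (j, s) in enumerate(directions):
            cand = x.copy()
            cand[j] = np.clip(cand[j] + s * mesh, lo[j], hi[j])
            if cand[j] == x[j]:
                continue
            fc = f(cand)
            if fc < fx:
                x, fx = cand, fc
                # successful direction polls first next time
                directions.insert(0, directions.pop(di))
                improved = True
                break
        if improved:
            mesh = min(mesh * 2.0, initial_mesh)
        else:
            mesh *= 0.5
    best = make_params(x)
    per_ds = {
        ds.dataset_id: objective(network, best, [ds], quiescent_state, settings)
        for ds in datasets
    }
    return FitResult(
        values={p: best.values[p] for p in free_param_ids},
        objective=fx,
        start_objective=f_start,
        iterations=iterations,
        n_evaluations=evals,
        converged=mesh < mesh_tolerance,
        free_param_ids=list(free_param_ids),
        per_dataset_sse=per_ds,
    )


def evaluate_recovery(
    true_params: ParameterSet | dict[str, float],
    fit_result: FitResult,
    free_param_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Relative error of recovered parameters vs ground truth."""
    truth = true_params.values if isinstance(true_params, ParameterSet) else true_params
    pids = list(free_param_ids or fit_result.free_param_ids)
    recs = []
    for pid in pids:
        t, v = truth[pid], fit_result.values[pid]
        recs.append({"parameter": pid, "true": t, "fitted": v,
                     "rel_error": abs(v - t) / t})
    df = pd.DataFrame(recs)
    summary = {
        "median_rel_error": float(df["rel_error"].median()),
        "max_rel_error": float(df["rel_error"].max()),
    }
    return df, summary
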