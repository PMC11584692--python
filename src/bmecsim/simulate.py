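"""Stiff-capable simulation harness and quiescent-state construction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    SECRETED_MARKERS,
    ModelNetwork,
    ParameterSet,
    SimulationError,
)
from .rhs import CompiledRHS, assemble_rhs

#: control cell-culture environment: 21% O2, 5.05 mmol/L glucose
CONTROL_ENVIRONMENT = {"O2": 0.21, "glucose": 5.05}


@dataclass
class SimSettings:
    rtol: float = 1e-6
    atol: float = 1e-9  # absolute tolerance per unit of species scale
    method: str = "LSODA"
    grid_dt: float = 0.1  # sampling step away from phase boundaries
    fine_dt: float = 0.01  # sampling step near phase boundaries
    fine_window: float = 0.5  # width (h) of the finely sampled window
    clamp_warn_fraction: float = 1e-3


@dataclass
class Trajectory:
    times: np.ndarray
    amounts: np.ndarray  # time x species
    species_ids: list[str]
    phase_marks: list[tuple[float, str]] = field(default_factory=list)
    clamp_count: int = 0
    min_before_clamp: float = 0.0
    cumulative: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.amounts.shape != (self.times.size, len(self.species_ids)):
            raise ValueError("trajectory shape mismatch")

    def get(self, sid: str) -> np.ndarray:
        from .network import SPECIES_ALIASES

        sid = SPECIES_ALIASES.get(sid, sid)
        try:
            j = self.species_ids.index(sid)
        except ValueError:
            raise KeyError(f"species {sid!r} not in trajectory") from None
        return self.amounts[:, j]

    def at(self, t: float) -> np.ndarray:
        """State vector linearly interpolated at time ``t``."""
        return np.array(
            [np.interp(t, self.times, self.amounts[:, j])
             for j in range(self.amounts.shape[1])]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, species, amount, phase) table."""
        marks = sorted(self.phase_marks) or [(self.times[0], "run")]
        starts = np.array([m[0] for m in marks])
        labels = [m[1] for m in marks]
        which = np.clip(np.searchsorted(starts, self.times, side="right") - 1, 0, None)
        phase = [labels[i] for i in which]
        recs = []
        for j, sid in enumerate(self.species_ids):
            recs.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "species": sid,
                        "amount": self.amounts[:, j],
                        "phase": phase,
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)


def _sample_grid(t0: float, t1: float, settings: SimSettings) -> np.ndarray:
    span = t1 - t0
    fine = min(settings.fine_window, span / 2)
    pieces = [np.arange(t0, t0 + fine, settings.fine_dt)]
    if t0 + fine < t1 - fine:
        pieces.append(np.arange(t0 + fine, t1 - fine, settings.grid_dt))
    pieces.append(np.arange(t1 - fine, t1, settings.fine_dt))
    grid = np.unique(np.concatenate(pieces + [np.array([t0, t1])]))
    return grid[(grid >= t0) & (grid <= t1)]


def simulate(
    network: ModelNetwork,
    params: ParameterSet,
    initial_state: np.ndarray,
    t_end: float,
    settings: SimSettings | None = None,
    environment: dict[str, float] | None = None,
    rhs: CompiledRHS | None = None,
    t_offset: float = 0.0,
    t_eval: np.ndarray | None = None,
    label: str = "run",
) -> Trajectory:
    """Integrate the network ODEs for ``t_end`` hours from ``initial_state``.

    ``environment`` overrides the clamped environment species (O2 fraction,
    glucose) for this run.  Numerically negative amounts are clamped to zero
    after integration, with the count recorded on the trajectory.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    settings = settings or SimSettings()
    rhs = rhs or assemble_rhs(network, params)
    y0 = np.asarray(initial_state, dtype=float).copy()
    if y0.min() < 0:
        raise ValueError("initial state must be nonnegative")
    if environment:
        for sid, val in environment.items():
            y0[network.species_index(sid)] = val

    scale = np.maximum(network.initial_state(), 1e-3)
    atol = settings.atol * scale
    grid = (
        _sample_grid(0.0, float(t_end), settings)
        if t_eval is None
        else np.asarray(t_eval, dtype=float)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_ivp(
            rhs,
            (0.0, float(t_end)),
            y0,
            method=settings.method,
            t_eval=grid,
            rtol=settings.rtol,
            atol=atol,
        )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad_t, bad_sp = _locate_failure(sol, network)
        raise SimulationError(
            f"integration failed ({sol.message}) near t={bad_t:.3g} h"
            + (f", species {bad_sp}" if bad_sp else "")
        )
    amounts = sol.y.T.copy()
    min_before_clamp = float(amounts.min())
    neg = amounts < 0
    clamp_count = int(neg.sum())
    if clamp_count:
        amounts[neg] = 0.0
        frac = clamp_count / amounts.size
        if frac > settings.clamp_warn_fraction:
            warnings.warn(
                f"{frac:.2%} of samples clamped to zero (stiffness artifacts)",
                RuntimeWarning,
                stacklevel=2,
            )
    traj = Trajectory(
        times=sol.t + t_offset,
        amounts=amounts,
        species_ids=list(network.species_ids),
        phase_marks=[(t_offset, label)],
        clamp_count=clamp_count,
        min_before_clamp=min_before_clamp,
    )
    _attach_cumulative(traj, rhs)
    return traj


def _locate_failure(sol, network: ModelNetwork) -> tuple[float, str]:
    if sol.t.size == 0:
        return 0.0, ""
    bad = ~np.isfinite(sol.y)
    if bad.any():
        j, i = np.argwhere(bad)[0]
        return float(sol.t[i]), network.species_ids[int(j)]
    return float(sol.t[-1]), ""


def _attach_cumulative(traj: Trajectory, rhs: CompiledRHS) -> None:
    """Cumulative secretion of the secreted cytokines along the trajectory.

    Secreted cytokine readouts are cumulative amounts (integral of the
    production flux), so transient secretion episodes are not erased by
    clearance; see the scoring module for their normalization.
    """
    present = [m for m in SECRETED_MARKERS if m in traj.species_ids]
    if not present:
        return
    idx = [rhs.network.species_index(m) for m in present]
    prod = np.maximum(rhs.stoich[idx, :], 0.0)  # markers x reactions
    rates = np.empty((traj.times.size, len(present)))
    for i in range(traj.times.size):
        rates[i] = prod @ rhs.fluxes(traj.amounts[i])
    dt = np.diff(traj.times)
    cum = np.zeros_like(rates)
    cum[1:] = np.cumsum(0.5 * (rates[1:] + rates[:-1]) * dt[:, None], axis=0)
    for k, m in enumerate(present):
        traj.cumulative[m] = cum[:, k]


def concatenate(trajs: list[Trajectory]) -> Trajectory:
    """Join phase trajectories (each already time-offset) into one."""
    if not trajs:
        raise ValueError("nothing to concatenate")
    times = [trajs[0].times]
    amounts = [trajs[0].amounts]
    marks = list(trajs[0].phase_marks)
    cum = {k: [v] for k, v in trajs[0].cumulative.items()}
    for tr in trajs[1:]:
        times.append(tr.times[1:])
        amounts.append(tr.amounts[1:])
        marks.extend(tr.phase_marks)
        for k in cum:
            cum[k].append(tr.cumulative[k][1:] + cum[k][-1][-1])
    out = Trajectory(
        times=np.concatenate(times),
        amounts=np.vstack(amounts),
        species_ids=list(trajs[0].species_ids),
        phase_marks=marks,
        clamp_count=sum(t.clamp_count for t in trajs),
        min_before_clamp=min(t.min_before_clamp for t in trajs),
    )
    out.cumulative = {k: np.concatenate(v) for k, v in cum.items()}
    return out


@dataclass
class QuiescenceReport:
    success: bool
    max_fold: float
    min_fold: float
    per_species: pd.DataFrame  # species, initial, min_fold, max_fold
    refinements: int = 0
    converged: bool = True

    def worst_species(self) -> list[str]:
        df = self.per_species
        bad = df[(df["max_fold"] > self._hi) | (df["min_fold"] < self._lo)]
        return list(bad["species"])

    _lo: float = 0.9
    _hi: float = 1.1


def find_quiescent_state(
    network: ModelNetwork,
    params: ParameterSet,
    band_low: float = 0.9,
    band_high: float = 1.1,
    horizon: float = 168.0,
    max_refinements: int = 5,
    settings: SimSettings | None = None,
) -> tuple[np.ndarray, QuiescenceReport]:
    """Construct/verify the quiescent state under control conditions.

    Simulates ``horizon`` hours from the configured initial amounts under the
    control environment and checks that every species' fold-ratio to its
    initial value stays within [band_low, band_high].  On failure the initial
    state is re-seeded from the long-run mean (damped fixed-point refinement)
    up to ``max_refinements`` times; non-convergence is reported honestly.
    """
    settings = settings or SimSettings()
    rhs = assemble_rhs(network, params)
    state = network.initial_state()
    control_env = {
        k: v for k, v in CONTROL_ENVIRONMENT.items() if k in network.species_ids
    }
    refinements = 0
    while True:
        traj = simulate(
            network,
            params,
            state,
            horizon,
            settings=settings,
            environment=control_env,
            rhs=rhs,
            label="control",
        )
        init = traj.amounts[0]
        tiny = 1e-12 * np.maximum(network.initial_state(), 1e-3)
        safe_init = np.where(init > tiny, init, 1.0)
        folds = np.where(init[None, :] > tiny, traj.amounts / safe_init, 1.0)
        max_fold = folds.max(axis=0)
        min_fold = folds.min(axis=0)
        report = QuiescenceReport(
            success=bool(np.all(max_fold <= band_high) and np.all(min_fold >= band_low)),
            max_fold=float(max_fold.max()),
            min_fold=float(min_fold.min()),
            per_species=pd.DataFrame(
                {
                    "species": network.species_ids,
                    "initial": init,
                    "min_fold": min_fold,
                    "max_fold": max_fold,
                }
            ),
            refinements=refinements,
        )
        report._lo, report._hi = band_low, band_high
        if report.success or refinements >= max_refinements:
            report.converged = report.success
            return state, report
        # damped re-seed from the long-run mean of the final quarter
        tail = traj.times >= traj.times[-1] - 0.25 * horizon
        target = traj.amounts[tail].mean(axis=0)
        state = 0.5 * (state + target)
        for i in network.environment_indices():
            state[i] = network.initial_state()[i]
        refinements += 1
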