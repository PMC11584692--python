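"""Virtual-cell cohorts and in-silico target interventions.

A virtual cell is the base model with per-cell multipliers on a chosen set
of sensitive parameters (normal heterogeneity centered at 1, resampled into
[0.5, 2]).  Heterogeneity is intrinsic: it shapes the cell's own baseline,
and every score is normalized to that baseline so heterogeneity does not
masquerade as dysfunction.  An intervention is an acute multiplier on a
named target group (succinate / p53 / HIF1a / IkB), applied from stimulus
onset like a drug given together with OGD/R.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .default_model import TARGET_GROUPS
from .network import ModelNetwork, ParameterSet
from .simulate import SimSettings
from .protocols import StimulusProtocol, make_ogdr_protocol, run_protocol
from .scoring import ScoreSeries, cell_function_score

log = logging.getLogger(__name__)

#: parameters varied across virtual cells by default: the consistently
#: top-ranked contributors to the cell-function score in the LHS/PRCC
#: sensitivity analysis (ROS generation/clearance, succinate turnover,
#: antioxidant feedback, NFkB feedback) — see analysis/04_sensitivity.py
DEFAULT_VARIED_PARAMETERS = [
    "kt_Keap1",
    "kd_Keap1",
    "kt_NRF2",
    "kd_NRF2_Keap1",
    "kd_ROS_NRF2",
    "kt_SDH",
    "kd_SDH",
    "k_ROS_RET",
    "kt_Succinate",
    "kd_Succinate",
    "kd_TIGAR",
    "kd_IKB_mrna",
]


@dataclass
class VirtualCell:
    cell_id: str
    multipliers: dict[str, float]
    intervention: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, m in {**self.multipliers, **self.intervention}.items():
            if m <= 0:
                raise ValueError(f"cell {self.cell_id}: multiplier {pid}={m} <= 0")


def generate_cohort(
    base_params: ParameterSet,
    varied_param_ids: list[str],
    n_cells: int = 100,
    seed: int = 0,
    sd: float = 0.25,
    low: float = 0.5,
    high: float = 2.0,
) -> list[VirtualCell]:
    """Heterogeneous cohort: N(1, sd) multipliers resampled into [low, high]."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not varied_param_ids:
        raise ValueError("varied_param_ids must be nonempty")
    missing = [p for p in varied_param_ids if p not in base_params.values]
    if missing:
        raise KeyError(f"unknown parameters: {missing}")
    rng = np.random.default_rng(seed)

    def draw() -> float:
        if sd == 0:
            return 1.0
        while True:
            v = rng.normal(1.0, sd)
            if low <= v <= high:
                return float(v)

    return [
        VirtualCell(
            cell_id=f"cell_{i:04d}",
            multipliers={pid: draw() for pid in varied_param_ids},
            provenance={"heterogeneity_seed": seed, "sd": sd,
                        "range": [low, high]},
        )
        for i in range(n_cells)
    ]


def apply_intervention(
    cells: list[VirtualCell],
    target: str,
    low: float = 0.5,
    high: float = 0.8,
    seed: int = 0,
    mode: str = "inhibit",
    groups: dict[str, list[str]] | None = None,
) -> list[VirtualCell]:
    """Assign each cell an intervention multiplier on a target's parameters.

    Each cell receives one uniform draw in [low, high] (variability in
    intervention efficacy), applied to every parameter of the target group;
    mode 'enhance' uses the reciprocal range.
    """
    groups = groups or TARGET_GROUPS
    if target not in groups:
        raise KeyError(f"unknown target {target!r}; choose from {sorted(groups)}")
    group = groups[target]
    if not group:
        raise ValueError(f"target {target!r} has an empty parameter group")
    if mode not in ("inhibit", "enhance"):
        raise ValueError("mode must be 'inhibit' or 'enhance'")
    rng = np.random.default_rng(seed)
    out = []
    for cell in cells:
        u = float(rng.uniform(low, high))
        if mode == "enhance":
            u = 1.0 / u
        out.append(
            VirtualCell(
                cell_id=cell.cell_id,
                multipliers=dict(cell.multipliers),
                intervention={pid: u for pid in group},
                provenance={**cell.provenance,
                            "intervention": {"target": target, "mode": mode,
                                             "range": [low, high],
                                             "seed": seed}},
            )
        )
    return out


@dataclass
class CohortResult:
    cells: list[VirtualCell]
    scores: dict[str, ScoreSeries]
    failures: dict[str, str] = field(default_factory=dict)

    def endpoints(self) -> pd.DataFrame:
        recs = []
        for cid, sc in self.scores.items():
            recs.append({"cell_id": cid, **sc.endpoint()})
        return pd.DataFrame(recs)

    def summary(self) -> dict[str, float]:
        ep = self.endpoints()["cell_function"]
        return {
            "n_cells": len(self.scores),
            "n_failed": len(self.failures),
            "median_cf": float(ep.median()),
            "iqr_cf": float(ep.quantile(0.75) - ep.quantile(0.25)),
        }


def simulate_cohort(
    network: ModelNetwork,
    base_params: ParameterSet,
    cells: list[VirtualCell],
    quiescent_state: np.ndarray,
    protocol: StimulusProtocol | None = None,
    settings: SimSettings | None = None,
    max_failure_fraction: float = 0.10,
) -> CohortResult:
    """Score every virtual cell under the protocol (default OGD 6 h / R 24 h).

    Each cell's baseline is its own pre-equilibrated control state;
    intervention multipliers apply from stimulus onset only.
    """
    protocol = protocol or make_ogdr_protocol(6.0, 24.0)
    scores: dict[str, ScoreSeries] = {}
    failures: dict[str, str] = {}
    for cell in cells:
        params = base_params.scaled(cell.multipliers)
        stim = params.scaled(cell.intervention) if cell.intervention else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = run_protocol(
                    network, params, quiescent_state, protocol, settings,
                    stimulus_params=stim,
                )
            scores[cell.cell_id] = cell_function_score(traj)
        except Exception as exc:  # noqa: BLE001 - collect, then threshold
            failures[cell.cell_id] = str(exc)
    if failures:
        log.warning("%d/%d cells failed: %s", len(failures), len(cells),
                    list(failures.items())[:3])
    if len(failures) > max_failure_fraction * len(cells):
        raise RuntimeError(
            f"{len(failures)}/{len(cells)} virtual cells failed to simulate"
        )
    return CohortResult(list(cells), scores, failures)


def simulate_target_modulation(
    network: ModelNetwork,
    params: ParameterSet,
    quiescent_state: np.ndarray,
    target: str,
    strength: float,
    protocol: StimulusProtocol | None = None,
    settings: SimSettings | None = None,
    groups: dict[str, list[str]] | None = None,
) -> tuple[ScoreSeries, ScoreSeries]:
    """Matched treated/control score series for one standard cell.

    ``strength`` in (0, 1] multiplies the target's parameter group from
    stimulus onset; strength 1 reproduces the control run exactly.
    """
    if not 0 < strength <= 1:
        raise ValueError("strength must be in (0, 1]")
    groups = groups or TARGET_GROUPS
    if target not in groups:
        raise KeyError(f"unknown target {target!r}; choose from {sorted(groups)}")
    protocol = protocol or make_ogdr_protocol(6.0, 24.0)
    control = cell_function_score(
        run_protocol(network, params, quiescent_state, protocol, settings)
    )
    stim = params.scaled({pid: strength for pid in groups[target]})
    treated = cell_function_score(
        run_protocol(network, params, quiescent_state, protocol, settings,
                     stimulus_params=stim)
    )
    return treated, control


def summarize_cohort(
    treated: CohortResult, control: CohortResult
) -> dict:
    """Population summary of per-cell endpoint CF fold changes.

    Pairs cells by id; fold change = treated endpoint CF / control endpoint
    CF.  Fraction improved uses strict > 1.
    """
    common = sorted(set(treated.scores) & set(control.scores))
    if not common:
        raise ValueError("no common cell ids between treated and control")
    if set(c.cell_id for c in treated.cells) != set(c.cell_id for c in control.cells):
        raise ValueError("treated and control cohorts have mismatched cell ids")
    folds = np.array(
        [
            treated.scores[c].endpoint()["cell_function"]
            / control.scores[c].endpoint()["cell_function"]
            for c in common
        ]
    )
    q1, med, q3 = np.percentile(folds, [25, 50, 75])
    hist, edges = np.histogram(np.log2(folds), bins=20)
    return {
        "cell_ids": common,
        "fold_changes": folds.tolist(),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "fraction_improved": float(np.mean(folds > 1.0)),
        "histogram_log2": {"counts": hist.tolist(), "edges": edges.tolist()},
    }
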