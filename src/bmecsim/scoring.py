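"""Module outputs, composite cell-function scores and the OGD x reox
phenotype grid.

Scores follow the published definitions:

* inflammation output      = [IL-6] * [IL-1b] * [CCL2]
* growth-factor output     = [Ang2] * [SEMA3G] * [BDNF]
* tight-junction output    = [ZO-1] * [Claudin5]
* proliferation score      = [Ang2] * [SEMA3G] * [BDNF] * [ZO-1] * [Claudin5]
* damage score             = [IL-6] * [IL-1b] * [CCL2] * [ROS] * [ONOO-] * [Casp3]
* cell-function (CF) score = proliferation / damage

with every factor normalized to its value under control conditions, so all
scores equal 1 at the control baseline.  Secreted cytokines enter as
cumulative secretion normalized to the control cumulative secretion over
the same elapsed time (transient secretion episodes are not erased by media
clearance); all other markers enter as normalized instantaneous amounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MARKERS, SECRETED_MARKERS, ModelNetwork, ParameterSet
from .rhs import assemble_rhs
from .simulate import SimSettings, Trajectory
from .protocols import StimulusProtocol, make_ogdr_protocol, run_protocol

MODULE_MARKERS = {
    "inflammation": ["IL6", "IL1b", "CCL2"],
    "growth": ["Ang2", "SEMA3G", "BDNF"],
    "tight_junction": ["ZO1", "Claudin5"],
}
PROLIFERATION_MARKERS = ["Ang2", "SEMA3G", "BDNF", "ZO1", "Claudin5"]
DAMAGE_MARKERS = ["IL6", "IL1b", "CCL2", "ROS", "ONOO", "Casp3"]

DEFAULT_OGD_DURATIONS = [1.0, 3.0, 4.0, 6.0, 24.0]
DEFAULT_REOX_DURATIONS = [1.0, 6.0, 12.0, 18.0, 24.0]

#: floor (as a fraction of baseline) applied before log2, avoiding -inf
LOG2_CLIP = 1e-6


class NormalizationError(ValueError):
    pass


def _baseline_state(traj: Trajectory) -> np.ndarray:
    state = getattr(traj, "baseline_state", None)
    if state is None:
        state = traj.amounts[0]
    return np.asarray(state, dtype=float)


def _baseline_secretion_rate(traj: Trajectory, marker: str) -> float:
    """Control secretion rate inferred from the pre-stimulus segment.

    Falls back to the first cumulative increment when the trajectory has no
    pre-equilibration samples.
    """
    cum = traj.cumulative[marker]
    pre = traj.times <= 0
    if pre.sum() >= 2:
        dt = traj.times[pre][-1] - traj.times[pre][0]
        if dt > 0:
            return (cum[pre][-1] - cum[pre][0]) / dt
    dt = traj.times[-1] - traj.times[0]
    return (cum[-1] - cum[0]) / dt if dt > 0 else 0.0


def normalized_marker(
    traj: Trajectory,
    marker: str,
    baseline: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(times >= 0, normalized marker series) for one functional marker."""
    sel = traj.times >= -1e-12
    times = traj.times[sel]
    if marker in SECRETED_MARKERS and marker in traj.cumulative:
        rate0 = (baseline or {}).get(f"{marker}_rate") or _baseline_secretion_rate(
            traj, marker
        )
        if rate0 <= 0:
            raise NormalizationError(f"nonpositive baseline secretion rate: {marker}")
        cum = traj.cumulative[marker][sel]
        cum = cum - cum[0]
        elapsed = times - times[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(elapsed > 0, cum / (rate0 * np.maximum(elapsed, 1e-12)), 1.0)
        return times, vals
    base = (baseline or {}).get(marker)
    if base is None:
        base = float(_baseline_state(traj)[traj.species_ids.index(marker)])
    if base <= 0:
        raise NormalizationError(f"nonpositive baseline for marker {marker}")
    try:
        series = traj.get(marker)[sel]
    except KeyError:
        raise NormalizationError(f"trajectory lacks marker {marker}") from None
    return times, series / base


def module_output(
    traj: Trajectory,
    which: str,
    baseline: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Product of normalized marker series for one functional module."""
    try:
        markers = MODULE_MARKERS[which]
    except KeyError:
        raise KeyError(
            f"unknown module output {which!r}; choose from {sorted(MODULE_MARKERS)}"
        ) from None
    times = None
    out = None
    for m in markers:
        times, vals = normalized_marker(traj, m, baseline)
        out = vals if out is None else out * vals
    return times, out


@dataclass
class ScoreSeries:
    times: np.ndarray
    proliferation: np.ndarray
    damage: np.ndarray
    cell_function: np.ndarray
    normalization_baseline: dict[str, float] = field(default_factory=dict)

    def endpoint(self) -> dict[str, float]:
        return {
            "proliferation": float(self.proliferation[-1]),
            "damage": float(self.damage[-1]),
            "cell_function": float(self.cell_function[-1]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "proliferation": self.proliferation,
                "damage": self.damage,
                "cell_function": self.cell_function,
            }
        )


def cell_function_score(
    traj: Trajectory, baseline: dict[str, float] | None = None
) -> ScoreSeries:
    """Proliferation, damage and CF score time courses from a trajectory."""
    used: dict[str, float] = {}
    prol = None
    times = None
    for m in PROLIFERATION_MARKERS:
        times, vals = normalized_marker(traj, m, baseline)
        prol = vals if prol is None else prol * vals
        used[m] = (baseline or {}).get(
            m, float(_baseline_state(traj)[traj.species_ids.index(m)])
        )
    dmg = None
    for m in DAMAGE_MARKERS:
        _, vals = normalized_marker(traj, m, baseline)
        dmg = vals if dmg is None else dmg * vals
        if m in SECRETED_MARKERS:
            used[f"{m}_rate"] = (baseline or {}).get(
                f"{m}_rate", _baseline_secretion_rate(traj, m)
            )
        else:
            used[m] = (baseline or {}).get(
                m, float(_baseline_state(traj)[traj.species_ids.index(m)])
            )
    return ScoreSeries(times, prol, dmg, prol / dmg, used)


@dataclass
class PhenotypeGrid:
    ogd_durations: list[float]
    reox_durations: list[float]
    markers: list[str]
    values: np.ndarray  # markers x (ogd x reox), log2 fold change

    def condition_labels(self) -> list[str]:
        return [
            f"OGD{g:g}h_re{r:g}h"
            for g in self.ogd_durations
            for r in self.reox_durations
        ]

    def value(self, marker: str, ogd: float, reox: float) -> float:
        i = self.markers.index(marker)
        j = self.ogd_durations.index(ogd) * len(self.reox_durations) + (
            self.reox_durations.index(reox)
        )
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, m in enumerate(self.markers):
            for gi, g in enumerate(self.ogd_durations):
                for ri, r in enumerate(self.reox_durations):
                    recs.append(
                        {
                            "marker": m,
                            "ogd_h": g,
                            "reox_h": r,
                            "log2fc": self.values[i, gi * len(self.reox_durations) + ri],
                        }
                    )
        return pd.DataFrame(recs)

    def heatmap(self, path: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 4.2))
        lim = np.nanmax(np.abs(self.values)) or 1.0
        im = ax.imshow(self.values, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
        ax.set_yticks(range(len(self.markers)), self.markers)
        ax.set_xticks(range(self.values.shape[1]), self.condition_labels(),
                      rotation=90, fontsize=6)
        fig.colorbar(im, ax=ax, label="log2 fold change vs control")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def phenotype_grid(
    network: ModelNetwork,
    params: ParameterSet,
    quiescent_state: np.ndarray,
    ogd_durations: list[float] | None = None,
    reox_durations: list[float] | None = None,
    settings: SimSettings | None = None,
    pre_equilibration: float = 24.0,
) -> PhenotypeGrid:
    """Marker log2 fold changes across OGD x reoxygenation conditions.

    Each marker is sampled at the end of the reoxygenation period,
    normalized to the control baseline and log2-transformed.  An OGD
    duration of 0 runs plain control culture for the reox period.
    """
    ogd_durations = list(
        DEFAULT_OGD_DURATIONS if ogd_durations is None else ogd_durations
    )
    reox_durations = list(
        DEFAULT_REOX_DURATIONS if reox_durations is None else reox_durations
    )
    if not ogd_durations or not reox_durations:
        raise ValueError("duration lists must be nonempty")
    values = np.empty((len(MARKERS), len(ogd_durations) * len(reox_durations)))
    for gi, g in enumerate(ogd_durations):
        for ri, r in enumerate(reox_durations):
            proto = make_ogdr_protocol(g, r, pre_equilibration=pre_equilibration)
            try:
                traj = run_protocol(network, params, quiescent_state, proto, settings)
            except Exception as exc:
                raise RuntimeError(
                    f"phenotype grid cell OGD={g} h, reox={r} h failed: {exc}"
                ) from exc
            col = gi * len(reox_durations) + ri
            for i, m in enumerate(MARKERS):
                _, vals = normalized_marker(traj, m)
                values[i, col] = np.log2(max(vals[-1], LOG2_CLIP))
    return PhenotypeGrid(ogd_durations, reox_durations, list(MARKERS), values)


def score_protocol(
    network: ModelNetwork,
    params: ParameterSet,
    quiescent_state: np.ndarray,
    protocol: StimulusProtocol | None = None,
    settings: SimSettings | None = None,
) -> ScoreSeries:
    """Convenience: run a protocol (default OGD 6 h / reox 24 h) and score it."""
    protocol = protocol or make_ogdr_protocol(6.0, 24.0)
    traj = run_protocol(network, params, quiescent_state, protocol, settings)
    return cell_function_score(traj)
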