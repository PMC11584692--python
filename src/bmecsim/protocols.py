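"""Stimulus protocols: dose conversion, multi-phase environments, OGD/R.

A protocol is an ordered list of phases, each fixing the clamped environment
(O2 fraction, glucose mmol/L) and optionally adding ligand boluses
(molecules per cell) at phase start.  Phases are integrated sequentially;
the terminal state of one phase (plus the next phase's boluses) seeds the
next, so the state handoff at the OGD -> reoxygenation boundary matches the
experimental media-change procedure.  Time zero is the end of
pre-equilibration, i.e. stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ModelNetwork, ParameterSet, SimulationError
from .rhs import assemble_rhs
from .simulate import (
    CONTROL_ENVIRONMENT,
    SimSettings,
    Trajectory,
    concatenate,
    simulate,
)

AVOGADRO = 6.02214076e23

#: default "close to zero" deprivation levels; hard zeros create stiffness
#: singularities in the saturating O2/glucose terms
DEPRIVED_O2 = 0.001
DEPRIVED_GLUCOSE = 0.05


def convert_dose(
    concentration_ng_ml: float,
    molecular_weight_g_mol: float,
    cell_density_per_ml: float,
) -> float:
    """Convert a media dose in ng/ml to molecules per cell.

    molecules/cell = c[ng/ml] * 1e-9 / MW * N_A / density[cells/ml].
    """
    if concentration_ng_ml < 0:
        raise ValueError("concentration must be nonnegative")
    if molecular_weight_g_mol <= 0 or cell_density_per_ml <= 0:
        raise ValueError("molecular weight and cell density must be positive")
    return (
        concentration_ng_ml
        * 1e-9
        / molecular_weight_g_mol
        * AVOGADRO
        / cell_density_per_ml
    )


@dataclass
class Phase:
    label: str
    duration: float
    environment: dict[str, float] = field(default_factory=dict)
    ligand_doses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"phase {self.label!r}: duration must be > 0")
        bad = set(self.environment) - {"O2", "glucose"}
        if bad:
            raise ValueError(f"phase {self.label!r}: unknown environment keys {bad}")
        if any(v < 0 for v in self.environment.values()):
            raise ValueError(f"phase {self.label!r}: negative environment value")
        if self.environment.get("O2", 0.0) > 1.0:
            raise ValueError(f"phase {self.label!r}: O2 fraction must be <= 1")


@dataclass
class StimulusProtocol:
    phases: list[Phase]
    pre_equilibration: float = 24.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        if self.pre_equilibration < 0:
            raise ValueError("pre_equilibration must be >= 0")

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)


def control_phase(duration: float, label: str = "control") -> Phase:
    return Phase(label, duration, dict(CONTROL_ENVIRONMENT))


def make_control_protocol(
    hours: float = 24.0, pre_equilibration: float = 24.0
) -> StimulusProtocol:
    return StimulusProtocol([control_phase(hours)], pre_equilibration)


def make_ogdr_protocol(
    ogd_hours: float,
    reox_hours: float,
    pre_equilibration: float = 24.0,
    deprived_o2: float = DEPRIVED_O2,
    deprived_glucose: float = DEPRIVED_GLUCOSE,
) -> StimulusProtocol:
    """Oxygen-glucose deprivation followed by reoxygenation.

    Zero-duration phases are omitted; (0, r) is plain control culture.
    """
    if ogd_hours < 0 or reox_hours < 0:
        raise ValueError("durations must be nonnegative")
    phases: list[Phase] = []
    if ogd_hours > 0:
        phases.append(
            Phase("OGD", ogd_hours, {"O2": deprived_o2, "glucose": deprived_glucose})
        )
    if reox_hours > 0:
        phases.append(control_phase(reox_hours, "reoxygenation"))
    if not phases:
        raise ValueError("protocol would be empty (both durations zero)")
    return StimulusProtocol(phases, pre_equilibration)


def make_ligand_protocol(
    ligand: str,
    dose_molecules_per_cell: float,
    hours: float,
    pre_equilibration: float = 24.0,
    environment: dict[str, float] | None = None,
) -> StimulusProtocol:
    env = dict(CONTROL_ENVIRONMENT)
    env.update(environment or {})
    return StimulusProtocol(
        [Phase(f"{ligand}_stimulus", hours, env, {ligand: dose_molecules_per_cell})],
        pre_equilibration,
    )


def make_hypoxia_protocol(
    o2_fraction: float, hours: float, pre_equilibration: float = 24.0
) -> StimulusProtocol:
    return StimulusProtocol(
        [Phase("hypoxia", hours, {"O2": o2_fraction, "glucose": 5.05})],
        pre_equilibration,
    )


def run_protocol(
    network: ModelNetwork,
    params: ParameterSet,
    quiescent_state: np.ndarray,
    protocol: StimulusProtocol,
    settings: SimSettings | None = None,
    stimulus_params: ParameterSet | None = None,
) -> Trajectory:
    """Simulate a multi-phase protocol with sequential state handoff.

    Returns a trajectory whose time axis is hours since stimulus onset
    (pre-equilibration occupies negative times).  The state at t=0 is
    attached as ``baseline_state`` and serves as the per-run control
    baseline for scoring.

    ``stimulus_params``, if given, replace ``params`` from stimulus onset
    onward (pre-equilibration and the baseline always use ``params``).
    This represents an acute pharmacological modulation applied together
    with the stimulus, as opposed to an intrinsic property of the cell.
    """
    settings = settings or SimSettings()
    rhs = assemble_rhs(network, params)
    stim_rhs = rhs if stimulus_params is None else assemble_rhs(network, stimulus_params)
    state = np.asarray(quiescent_state, dtype=float).copy()
    segments: list[Trajectory] = []
    t = -protocol.pre_equilibration
    if protocol.pre_equilibration > 0:
        seg = _run_phase(
            network, params, state,
            control_phase(protocol.pre_equilibration, "pre_equilibration"),
            settings, rhs, t,
        )
        segments.append(seg)
        state = seg.amounts[-1].copy()
        t = 0.0
    baseline_state = state.copy()
    for phase in protocol.phases:
        for lig, dose in phase.ligand_doses.items():
            if dose < 0:
                raise ValueError(f"negative ligand dose for {lig}")
            state[network.species_index(lig)] += dose
        seg = _run_phase(
            network, stimulus_params or params, state, phase, settings, stim_rhs, t
        )
        segments.append(seg)
        state = seg.amounts[-1].copy()
        t += phase.duration
    traj = concatenate(segments)
    traj.baseline_state = baseline_state  # type: ignore[attr-defined]
    return traj


def _run_phase(network, params, state, phase, settings, rhs, t_offset) -> Trajectory:
    try:
        return simulate(
            network,
            params,
            state,
            phase.duration,
            settings=settings,
            environment=phase.environment,
            rhs=rhs,
            t_offset=t_offset,
            label=phase.label,
        )
    except SimulationError as exc:
        raise SimulationError(f"phase {phase.label!r}: {exc}") from exc
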