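"""Synthetic calibration corpora and qualitative-shape fixtures.

The synthetic generator stands in for the digitized experimental corpus the
model was calibrated against: sparse normalized time courses of protein and
metabolite readouts under ligand stimuli, hypoxia and OGD/R, with
multiplicative lognormal noise (densitometry/ELISA-style positive data with
roughly constant CV).  Datasets record their generating parameters so
parameter-recovery experiments are self-contained.

Shape fixtures encode, as machine-checkable assertions, the qualitative
dynamics the model must reproduce (succinate accumulation and rapid
post-reox oxidation, the reoxygenation ROS burst, the pAMPK double peak,
p53 rise-and-return, HIF kinetics, cytokine monotonicity in OGD duration,
growth-factor return to baseline, OGD-duration-dependent caspase
reversibility, and ROS-driven tight-junction decline with FGF protection).
All windows and tolerances live in DEFAULT_FIXTURES, in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import find_peaks

from .network import ModelNetwork, ParameterSet
from .simulate import SimSettings, Trajectory
from .protocols import (
    StimulusProtocol,
    convert_dose,
    make_hypoxia_protocol,
    make_ligand_protocol,
    make_ogdr_protocol,
    run_protocol,
)
from .calibration import CalibrationDataset, normalize_observable
from .scoring import normalized_marker
from .protocols import Phase


# ---------------------------------------------------------------------------
# noise + dataset generation
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    kind: str = "multiplicative_lognormal"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return values.copy()
        if self.kind == "multiplicative_lognormal":
            return values * rng.lognormal(0.0, self.sigma, size=values.shape)
        return np.maximum(values + rng.normal(0.0, self.sigma, values.shape), 0.0)


def generate_timecourse_dataset(
    network: ModelNetwork,
    true_params: ParameterSet,
    quiescent_state: np.ndarray,
    protocol: StimulusProtocol,
    observable: str,
    timepoints: np.ndarray,
    noise: NoiseModel | None = None,
    normalization: str = "to_max",
    dataset_id: str | None = None,
    weight: float = 1.0,
    module: str | None = None,
    rng: np.random.Generator | None = None,
    _traj: Trajectory | None = None,
) -> CalibrationDataset:
    """Simulate with the true parameters, sample, perturb, normalize."""
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.max() > protocol.total_duration + 1e-9:
        raise ValueError("timepoints extend past the protocol duration")
    noise = noise or NoiseModel(sigma=0.0)
    rng = rng or np.random.default_rng(noise.seed)
    traj = _traj if _traj is not None else run_protocol(
        network, true_params, quiescent_state, protocol
    )
    times, series = normalize_observable(traj, observable, normalization)
    sampled = np.interp(timepoints, times, series)
    noisy = noise.apply(sampled, rng)
    if normalization == "to_max":
        noisy = noisy / noisy.max()
    return CalibrationDataset(
        dataset_id=dataset_id or f"{observable}_{noise.seed}",
        protocol=protocol,
        observable=observable,
        timepoints=timepoints,
        values=noisy,
        normalization=normalization,
        weight=weight,
        module=module,
        true_params=dict(true_params.values),
    )


#: stimulus conditions of the default calibration corpus: per-condition
#: protocol factory, observables with module labels, sampling grid
def _default_suite_spec() -> list[dict]:
    tnf = convert_dose(100, 17_500, 1e6)
    lps = convert_dose(300, 10_000, 1e6)
    vegf = convert_dose(50, 40_000, 1e6)
    fgf = convert_dose(1000, 17_000, 1e6)
    lig_t = np.array([0.0, 0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 8])
    slow_t = np.array([0.0, 1, 2, 4, 6, 8, 12, 16, 20, 24])
    ogdr_t = np.array([0.0, 1, 3, 5, 6, 6.5, 7, 8, 10, 12, 16, 24, 30])
    return [
        {
            "condition": "TNFa_100ng_ml",
            "protocol": make_ligand_protocol("TNFa", tnf, 8.0),
            "timepoints": lig_t,
            "normalization": "to_max",
            "observables": {
                "RIPK1_Ub": "inflammation", "TAK1_p": "inflammation",
                "IKK_p": "inflammation", "NFkB_nuc": "inflammation",
            },
        },
        {
            "condition": "LPS_300ng_ml",
            "protocol": make_ligand_protocol("LPS", lps, 8.0),
            "timepoints": lig_t,
            "normalization": "to_max",
            "observables": {
                "TRAF6_Ub": "inflammation", "p38_p": "inflammation",
                "JNK_p": "inflammation", "ERK_p": "inflammation",
                "A20": "inflammation",
            },
        },
        {
            "condition": "VEGF_50ng_ml",
            "protocol": make_ligand_protocol("VEGF", vegf, 8.0),
            "timepoints": lig_t,
            "normalization": "to_max",
            "observables": {
                "VEGFR_pY1175": "survival", "PLCg_p": "survival",
                "MEK_p": "survival", "ERK_p": "survival",
                "Ca_cyt": "survival", "eNOS_p": "survival",
                "AMPK_p": "survival", "ULK_p": "survival",
                "VEGFR_pY951": "survival", "PI3K_p": "survival",
                "AKT_p": "survival",
            },
        },
        {
            "condition": "FGF_1ug_ml",
            "protocol": make_ligand_protocol("FGF", fgf, 8.0),
            "timepoints": lig_t,
            "normalization": "to_max",
            "observables": {
                "FGFR_p": "survival", "PKC_p": "survival", "AKT_p": "survival",
            },
        },
        {
            "condition": "hypoxia_1pct",
            "protocol": make_hypoxia_protocol(0.01, 24.0),
            "timepoints": slow_t,
            "normalization": "to_baseline",
            "observables": {
                "HIF1a": "hypoxia", "HIF2a": "hypoxia", "Lon": "hypoxia",
                "BDNF": "hypoxia", "SEMA3G": "hypoxia", "Ang2": "hypoxia",
                "p53": "hypoxia", "MDM2": "hypoxia", "TIGAR": "hypoxia",
                "NADPH": "metabolism", "PFKFB3": "metabolism",
            },
        },
        {
            "condition": "OGDR_6_24",
            "protocol": make_ogdr_protocol(6.0, 24.0),
            "timepoints": ogdr_t,
            "normalization": "to_baseline",
            "observables": {
                "Succinate": "oxidative_stress", "ROS": "oxidative_stress",
                "iNOS": "oxidative_stress", "NO": "oxidative_stress",
                "ONOO": "oxidative_stress", "BH4": "oxidative_stress",
                "BH2": "oxidative_stress", "NRF2": "oxidative_stress",
                "ZO1": "oxidative_stress", "Claudin5": "oxidative_stress",
                "ATP": "metabolism", "AMPK_p": "metabolism",
                "p53": "hypoxia", "Casp3": "hypoxia", "HIF1a": "hypoxia",
                "IL6": "inflammation", "IL1b": "inflammation",
                "CCL2": "inflammation",
            },
        },
    ]


def generate_calibration_suite(
    network: ModelNetwork,
    true_params: ParameterSet,
    quiescent_state: np.ndarray,
    spec: list[dict] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[CalibrationDataset]:
    """A corpus of normalized time courses spanning all five modules.

    The default condition set mirrors the calibration stimuli (TNFa 100
    ng/ml, LPS 300 ng/ml, VEGF 50 ng/ml, FGF 1 ug/ml, 1% O2 hypoxia, OGD
    6 h / reox 24 h) and totals well over 300 data points.
    """
    spec = spec if spec is not None else _default_suite_spec()
    if not spec:
        raise ValueError("empty suite specification")
    noise = noise or NoiseModel(sigma=0.05, seed=seed)
    rng = np.random.default_rng(seed)
    datasets = []
    for cond in spec:
        traj = run_protocol(network, true_params, quiescent_state,
                            cond["protocol"])
        for obs, module in cond["observables"].items():
            datasets.append(
                generate_timecourse_dataset(
                    network, true_params, quiescent_state, cond["protocol"],
                    obs, cond["timepoints"], noise,
                    cond["normalization"],
                    dataset_id=f"{cond['condition']}:{obs}",
                    module=module, rng=rng, _traj=traj,
                )
            )
    return datasets


def suite_to_frame(datasets: list[CalibrationDataset]):
    """Tidy export of a calibration corpus."""
    import pandas as pd

    recs = []
    for ds in datasets:
        for t, v in zip(ds.timepoints, ds.values):
            recs.append(
                {"dataset_id": ds.dataset_id, "time_h": t, "value": v,
                 "observable": ds.observable,
                 "normalization": ds.normalization, "weight": ds.weight,
                 "module": ds.module}
            )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# qualitative shape fixtures
# ---------------------------------------------------------------------------

@dataclass
class Constraint:
    kind: str
    observable: str
    run: str = "main"
    window: tuple[float, float] | None = None
    bounds: tuple[float, float] | None = None
    threshold: float | None = None
    other_run: str | None = None
    runs: list[str] | None = None

    def evaluate(self, trajs: dict[str, Trajectory]) -> tuple[bool, str]:
        check = _CHECKS[self.kind]
        return check(self, trajs)


@dataclass
class ShapeFixture:
    name: str
    protocols: dict[str, tuple]
    constraints: list[Constraint]


def _norm(traj: Trajectory, obs: str) -> tuple[np.ndarray, np.ndarray]:
    return normalized_marker(traj, obs)


def _window(t, y, w):
    sel = (t >= w[0]) & (t <= w[1])
    return t[sel], y[sel]


def _check_monotone_increasing(c, trajs):
    t, y = _window(*_norm(trajs[c.run], c.observable), c.window)
    drops = np.diff(y) < -1e-9 * max(1.0, np.abs(y).max())
    ok = not drops.any()
    return ok, f"{c.observable} monotone on {c.window}: {'ok' if ok else 'violations'}"


def _check_fall_after(c, trajs):
    # rise up to window[0], then fall by >= threshold of the rise within window
    t, y = _norm(trajs[c.run], c.observable)
    t0, t1 = c.window
    peak = np.interp(t0, t, y)
    rise = peak - y[0]
    later = np.interp(t1, t, y)
    ok = rise > 0 and (peak - later) >= c.threshold * rise
    return ok, (f"{c.observable} fell {(peak - later):.2f} of rise {rise:.2f} "
                f"by t={t1}")


def _check_peak_after(c, trajs):
    t, y = _norm(trajs[c.run], c.observable)
    tmax = t[int(np.argmax(y))]
    ok = tmax > c.threshold
    return ok, f"{c.observable} max at t={tmax:.2f} (required > {c.threshold})"


def _check_two_peaks(c, trajs):
    t, y = _norm(trajs[c.run], c.observable)
    sel = t >= 0
    t, y = t[sel], y[sel]
    peaks, _ = find_peaks(y, prominence=0.5)
    times = t[peaks]
    w1, w2 = c.window, c.bounds
    in1 = [p for p in times if w1[0] <= p <= w1[1]]
    in2 = [p for p in times if w2[0] <= p <= w2[1]]
    ok = len(times) >= 2 and bool(in1) and bool(in2)
    return ok, f"{c.observable} peaks at {np.round(times, 2).tolist()}"


def _check_final_within(c, trajs):
    t, y = _norm(trajs[c.run], c.observable)
    ok = c.bounds[0] <= y[-1] <= c.bounds[1]
    return ok, f"{c.observable} final {y[-1]:.3f} in {c.bounds}"


def _check_elevated_at(c, trajs):
    t, y = _norm(trajs[c.run], c.observable)
    v = np.interp(c.window[0], t, y)
    ok = v >= c.threshold
    return ok, f"{c.observable} at t={c.window[0]} is {v:.2f}x (>= {c.threshold})"


def _check_declining(c, trajs):
    t, y = _norm(trajs[c.run], c.observable)
    a, b = (np.interp(x, t, y) for x in c.window)
    ok = b < a
    return ok, f"{c.observable} {a:.2f} -> {b:.2f} over {c.window}"


def _check_endpoint_monotone_runs(c, trajs):
    vals = [_norm(trajs[r], c.observable)[1][-1] for r in c.runs]
    tol = c.threshold or 0.0
    ok = all(vals[i + 1] >= vals[i] - tol for i in range(len(vals) - 1))
    return ok, f"{c.observable} endpoints {np.round(vals, 3).tolist()}"


def _check_endpoint_within_frac_of_max(c, trajs):
    vals = np.array([_norm(trajs[r], c.observable)[1][-1] for r in c.runs])
    ok = vals.min() >= (1 - c.threshold) * vals.max()
    return ok, f"{c.observable} endpoints {np.round(vals, 3).tolist()}"


def _check_endpoint_lower_than_run(c, trajs):
    v = _norm(trajs[c.run], c.observable)[1][-1]
    w = _norm(trajs[c.other_run], c.observable)[1][-1]
    margin = c.threshold or 0.0
    ok = v < w - margin
    return ok, f"{c.observable}: {c.run}={v:.3f} vs {c.other_run}={w:.3f}"


def _check_abs_log2_endpoint_lower_than_run(c, trajs):
    v = abs(np.log2(max(_norm(trajs[c.run], c.observable)[1][-1], 1e-9)))
    w = abs(np.log2(max(_norm(trajs[c.other_run], c.observable)[1][-1], 1e-9)))
    ok = v < w
    return ok, f"|log2 {c.observable}|: {c.run}={v:.3f} vs {c.other_run}={w:.3f}"


def _check_endpoint_below(c, trajs):
    v = _norm(trajs[c.run], c.observable)[1][-1]
    ok = v < c.threshold
    return ok, f"{c.observable} endpoint {v:.3f} (required < {c.threshold})"


_CHECKS: dict[str, Callable] = {
    "monotone_increasing": _check_monotone_increasing,
    "fall_after": _check_fall_after,
    "peak_after": _check_peak_after,
    "two_peaks": _check_two_peaks,
    "final_within": _check_final_within,
    "elevated_at": _check_elevated_at,
    "declining": _check_declining,
    "endpoint_monotone_runs": _check_endpoint_monotone_runs,
    "endpoint_within_frac_of_max": _check_endpoint_within_frac_of_max,
    "endpoint_lower_than_run": _check_endpoint_lower_than_run,
    "abs_log2_endpoint_lower_than_run": _check_abs_log2_endpoint_lower_than_run,
    "endpoint_below": _check_endpoint_below,
}


def _ogdr(g: float, r: float) -> tuple:
    return ("ogdr", g, r)


def default_shape_fixtures() -> list[ShapeFixture]:
    """The qualitative-dynamics gate for the default model under OGD/R."""
    main = {"main": _ogdr(6, 24)}
    return [
        ShapeFixture(
            "succinate_accumulation_and_rapid_oxidation", main,
            [
                Constraint("monotone_increasing", "Succinate", window=(1, 6)),
                Constraint("fall_after", "Succinate", window=(6, 8),
                           threshold=0.5),
            ],
        ),
        ShapeFixture(
            "ros_burst_at_reoxygenation", main,
            [Constraint("peak_after", "ROS", threshold=6.0)],
        ),
        ShapeFixture(
            "pampk_double_peak", main,
            [Constraint("two_peaks", "AMPK_p", window=(0.5, 6.2),
                        bounds=(10.0, 14.0))],
        ),
        ShapeFixture(
            "p53_rise_and_return", main,
            [
                Constraint("elevated_at", "p53", window=(6.0,), threshold=1.2),
                Constraint("final_within", "p53", bounds=(0.8, 1.2)),
            ],
        ),
        ShapeFixture(
            "hif1a_rise_then_decline", main,
            [
                Constraint("elevated_at", "HIF1a", window=(6.0,), threshold=1.2),
                Constraint("declining", "HIF1a", window=(6.0, 12.0)),
            ],
        ),
        ShapeFixture(
            "cytokines_monotone_in_ogd_duration",
            {"ogd1": _ogdr(1, 24), "ogd3": _ogdr(3, 24), "ogd6": _ogdr(6, 24)},
            [
                Constraint("endpoint_monotone_runs", cyt,
                           runs=["ogd1", "ogd3", "ogd6"], threshold=1e-6)
                for cyt in ("IL6", "IL1b", "CCL2")
            ],
        ),
        ShapeFixture(
            "growth_factors_return_to_baseline",
            {"short": _ogdr(6, 1), "long": _ogdr(6, 24)},
            [
                Constraint("abs_log2_endpoint_lower_than_run", gf, run="long",
                           other_run="short")
                for gf in ("Ang2", "SEMA3G", "BDNF")
            ],
        ),
        ShapeFixture(
            "caspase_reversibility_depends_on_ogd_duration",
            {"s6": _ogdr(3, 6), "s24": _ogdr(3, 24),
             "l1": _ogdr(24, 1), "l12": _ogdr(24, 12), "l24": _ogdr(24, 24)},
            [
                # short OGD: caspase-3 declines with longer reoxygenation
                Constraint("endpoint_lower_than_run", "Casp3", run="s24",
                           other_run="s6", threshold=0.0),
                # long OGD: stays within 10% of the reox-period maximum
                Constraint("endpoint_within_frac_of_max", "Casp3",
                           runs=["l1", "l12", "l24"], threshold=0.10),
            ],
        ),
        ShapeFixture(
            "tight_junction_decline_with_fgf_protection",
            {"main": _ogdr(6, 24), "fgf": ("ogdr+FGF", 6, 24)},
            [
                Constraint("endpoint_below", "ZO1", threshold=0.9),
                Constraint("endpoint_below", "Claudin5", threshold=0.9),
                Constraint("endpoint_lower_than_run", "ZO1", run="main",
                           other_run="fgf", threshold=0.05),
                Constraint("endpoint_lower_than_run", "Claudin5", run="main",
                           other_run="fgf", threshold=0.05),
            ],
        ),
    ]


@dataclass
class FixtureReport:
    passed: bool
    results: list[tuple[str, bool, str]]

    def failures(self) -> list[tuple[str, str]]:
        return [(n, d) for n, ok, d in self.results if not ok]


def _protocol_from_key(key: tuple) -> StimulusProtocol:
    kind = key[0]
    if kind == "ogdr":
        return make_ogdr_protocol(key[1], key[2])
    if kind == "ogdr+FGF":
        proto = make_ogdr_protocol(key[1], key[2])
        proto.phases[0].ligand_doses["FGF"] = convert_dose(1000, 17_000, 1e6)
        return proto
    if kind == "control":
        return StimulusProtocol([Phase("control", key[1],
                                       {"O2": 0.21, "glucose": 5.05})])
    raise KeyError(f"unknown protocol key {key}")


def check_fixtures(
    network: ModelNetwork,
    params: ParameterSet,
    quiescent_state: np.ndarray,
    fixtures: list[ShapeFixture] | None = None,
    settings: SimSettings | None = None,
) -> FixtureReport:
    """Evaluate all shape fixtures, sharing simulations across fixtures."""
    fixtures = fixtures if fixtures is not None else default_shape_fixtures()
    cache: dict[tuple, Trajectory] = {}
    results = []
    for fx in fixtures:
        trajs = {}
        for label, key in fx.protocols.items():
            if key not in cache:
                cache[key] = run_protocol(
                    network, params, quiescent_state,
                    _protocol_from_key(key), settings,
                )
            trajs[label] = cache[key]
        for c in fx.constraints:
            ok, detail = c.evaluate(trajs)
            results.append((f"{fx.name}:{c.kind}:{c.observable}", ok, detail))
    return FixtureReport(all(ok for _, ok, _ in results), results)
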