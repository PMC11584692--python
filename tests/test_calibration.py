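"""Observable normalization, objective, pattern search and recovery."""

import numpy as np
import pytest

from bmecsim import (
    CalibrationDataset,
    ParameterSet,
    Phase,
    StimulusProtocol,
    evaluate_recovery,
    normalize_observable,
    objective,
    pattern_search_fit,
    run_protocol,
)
from bmecsim.calibration import FitResult
from conftest import make_decay_network

CONTROL = {"O2": 0.21, "glucose": 5.05}


def _toy_protocol(hours=4.0):
    return StimulusProtocol([Phase("run", hours, dict(CONTROL))],
                            pre_equilibration=0.0)


@pytest.fixture(scope="module")
def decay_setup():
    """Single exponential decay; every normalization has a closed form."""
    net, params = make_decay_network(kd=0.5, initial=100.0)
    # drop the environment clamp: the toy model has no O2/glucose species
    proto = StimulusProtocol([Phase("run", 4.0, {})], pre_equilibration=0.0)
    return net, params, proto


class TestNormalizeObservable:
    def test_constant_series_to_baseline_is_ones(self, model, quiescent):
        net, params = model
        proto = StimulusProtocol([Phase("c", 4.0, dict(CONTROL))],
                                 pre_equilibration=0.0)
        traj = run_protocol(net, params, quiescent, proto)
        _, vals = normalize_observable(traj, "p53", "to_baseline")
        assert np.allclose(vals, 1.0, atol=1e-6)

    def test_to_max_peaks_at_exactly_one(self, decay_setup):
        net, params, proto = decay_setup
        traj = run_protocol(net, params, net.initial_state(), proto)
        _, vals = normalize_observable(traj, "A", "to_max")
        assert vals.max() == pytest.approx(1.0)
        assert vals[0] == pytest.approx(1.0)  # decay peaks at t=0

    def test_to_max_arithmetic(self):
        """series (1, 2, 4) normalized to max is (0.25, 0.5, 1.0)."""
        from bmecsim import Trajectory

        traj = Trajectory(np.array([0.0, 1.0, 2.0]),
                          np.array([[1.0], [2.0], [4.0]]), ["A"])
        _, vals = normalize_observable(traj, "A", "to_max")
        assert vals == pytest.approx([0.25, 0.5, 1.0])


class TestObjective:
    def test_self_consistency_zero(self, decay_setup):
        net, params, proto = decay_setup
        traj = run_protocol(net, params, net.initial_state(), proto)
        tp = np.array([0.0, 1.0, 2.0, 3.0])
        _, series = normalize_observable(traj, "A", "to_baseline")
        ds = CalibrationDataset("self", proto, "A", tp,
                                np.interp(tp, traj.times, series),
                                "to_baseline")
        assert objective(net, params, [ds], net.initial_state()) < 1e-12

    def test_hand_sum_of_squares(self, decay_setup):
        """Residuals (0.1, -0.2) with weight 1 give objective 0.05."""
        net, params, proto = decay_setup
        tp = np.array([1.0, 2.0])
        pred = np.exp(-0.5 * tp)  # kd = 0.5, to_baseline
        ds = CalibrationDataset("r", proto, "A", tp,
                                pred + np.array([0.1, -0.2]), "to_baseline")
        got = objective(net, params, [ds], net.initial_state())
        assert got == pytest.approx(0.01 + 0.04, rel=1e-4)

    def test_weights_scale_linearly(self, decay_setup):
        net, params, proto = decay_setup
        tp = np.array([1.0, 2.0])
        vals = np.exp(-0.5 * tp) + 0.1
        one = CalibrationDataset("w1", proto, "A", tp, vals, "to_baseline",
                                 weight=1.0)
        two = CalibrationDataset("w2", proto, "A", tp, vals, "to_baseline",
                                 weight=2.0)
        state = net.initial_state()
        assert objective(net, params, [two], state) == pytest.approx(
            2 * objective(net, params, [one], state)
        )

    def test_empty_datasets_rejected(self, decay_setup):
        net, params, _ = decay_setup
        with pytest.raises(ValueError):
            objective(net, params, [], net.initial_state())


class TestDatasetValidation:
    def test_mismatched_lengths(self, decay_setup):
        _, _, proto = decay_setup
        with pytest.raises(ValueError):
            CalibrationDataset("bad", proto, "A", np.array([0.0, 1.0]),
                               np.array([1.0]), "to_max")

    def test_to_max_values_cannot_exceed_one(self, decay_setup):
        _, _, proto = decay_setup
        with pytest.raises(ValueError):
            CalibrationDataset("bad", proto, "A", np.array([0.0, 1.0]),
                               np.array([0.5, 1.5]), "to_max")


class TestPatternSearch:
    def test_recovers_decay_rate_from_noiseless_data(self, decay_setup):
        """Convex 1-parameter problem: argmin found to < 1e-3 relative."""
        net, params, proto = decay_setup
        tp = np.linspace(0.25, 4.0, 12)
        ds = CalibrationDataset("d", proto, "A", tp, np.exp(-0.5 * tp),
                                "to_baseline")
        start = ParameterSet.with_default_bounds({"kd_A": 0.8})
        fit = pattern_search_fit(net, start, ["kd_A"], [ds],
                                 net.initial_state(), max_iterations=200,
                                 seed=0, mesh_tolerance=1e-6)
        assert fit.values["kd_A"] == pytest.approx(0.5, rel=1e-3)
        assert fit.converged

    def test_objective_never_increases_from_start(self, decay_setup):
        net, params, proto = decay_setup
        tp = np.linspace(0.25, 4.0, 8)
        ds = CalibrationDataset("d", proto, "A", tp, np.exp(-0.5 * tp),
                                "to_baseline")
        start = ParameterSet.with_default_bounds({"kd_A": 0.9})
        fit = pattern_search_fit(net, start, ["kd_A"], [ds],
                                 net.initial_state(), max_iterations=5)
        assert fit.objective <= fit.start_objective

    def test_flat_objective_returns_start_after_mesh_collapse(
        self, decay_setup
    ):
        """A dataset insensitive to the free parameter leaves it unmoved."""
        net, params, proto = decay_setup
        ds = CalibrationDataset("flat", proto, "A", np.array([0.0, 0.0]),
                                np.array([1.0, 1.0]), "to_baseline")
        start = ParameterSet.with_default_bounds({"kd_A": 0.7})
        fit = pattern_search_fit(net, start, ["kd_A"], [ds],
                                 net.initial_state(), max_iterations=500)
        assert fit.values["kd_A"] == pytest.approx(0.7)
        assert fit.converged

    def test_deterministic_under_seed(self, decay_setup):
        net, params, proto = decay_setup
        tp = np.linspace(0.25, 4.0, 6)
        ds = CalibrationDataset("d", proto, "A", tp,
                                np.exp(-0.5 * tp) * 1.02, "to_baseline")
        start = ParameterSet.with_default_bounds({"kd_A": 0.8})
        fits = [
            pattern_search_fit(net, start, ["kd_A"], [ds],
                               net.initial_state(), max_iterations=30, seed=4)
            for _ in range(2)
        ]
        assert fits[0].values == fits[1].values
        assert fits[0].n_evaluations == fits[1].n_evaluations

    def test_invalid_arguments(self, decay_setup):
        net, params, proto = decay_setup
        ds = CalibrationDataset("d", proto, "A", np.array([0.0, 1.0]),
                                np.array([1.0, 0.6]), "to_baseline")
        with pytest.raises(ValueError):
            pattern_search_fit(net, params, ["kd_A"], [ds],
                               net.initial_state(), max_iterations=0)
        with pytest.raises(KeyError):
            pattern_search_fit(net, params, ["nope"], [ds],
                               net.initial_state())


class TestEvaluateRecovery:
    def _fit(self, values):
        return FitResult(values, 0.0, 1.0, 1, 1, True,
                         free_param_ids=list(values))

    def test_exact_fit_zero_errors(self):
        df, s = evaluate_recovery({"a": 2.0, "b": 1.0},
                                  self._fit({"a": 2.0, "b": 1.0}))
        assert np.allclose(df["rel_error"], 0.0)
        assert s["median_rel_error"] == 0.0

    def test_doubled_fit_unit_errors(self):
        df, s = evaluate_recovery({"a": 2.0}, self._fit({"a": 4.0}))
        assert df["rel_error"].iloc[0] == pytest.approx(1.0)
        assert s["max_rel_error"] == pytest.approx(1.0)

    def test_summary_matches_hand_recomputation(self):
        truth = {"a": 1.0, "b": 2.0, "c": 4.0}
        fitted = {"a": 1.1, "b": 1.0, "c": 5.0}
        df, s = evaluate_recovery(truth, self._fit(fitted))
        errs = sorted(abs(fitted[k] - truth[k]) / truth[k] for k in truth)
        assert s["median_rel_error"] == pytest.approx(errs[1])
        assert s["max_rel_error"] == pytest.approx(max(errs))
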