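"""Virtual-cell generation, interventions, and population summaries."""

import numpy as np
import pytest

from bmecsim import (
    DEFAULT_VARIED_PARAMETERS,
    apply_intervention,
    generate_cohort,
    simulate_cohort,
    simulate_target_modulation,
    summarize_cohort,
)
from bmecsim.cohort import CohortResult, VirtualCell
from bmecsim.scoring import ScoreSeries


class TestGenerateCohort:
    def test_size_and_range(self, model):
        _, params = model
        cells = generate_cohort(params, DEFAULT_VARIED_PARAMETERS, 100, seed=0)
        assert len(cells) == 100
        for c in cells:
            assert set(c.multipliers) == set(DEFAULT_VARIED_PARAMETERS)
            assert all(0.5 <= m <= 2.0 for m in c.multipliers.values())

    def test_sd_zero_degenerates_to_baseline(self, model):
        _, params = model
        cells = generate_cohort(params, ["kt_Succinate"], 5, seed=0, sd=0.0)
        assert all(c.multipliers["kt_Succinate"] == 1.0 for c in cells)

    def test_seeded_determinism(self, model):
        _, params = model
        a = generate_cohort(params, DEFAULT_VARIED_PARAMETERS, 20, seed=5)
        b = generate_cohort(params, DEFAULT_VARIED_PARAMETERS, 20, seed=5)
        assert all(x.multipliers == y.multipliers for x, y in zip(a, b))

    def test_law_of_large_numbers_mean(self, model):
        _, params = model
        cells = generate_cohort(params, ["kt_Succinate", "kd_Succinate"],
                                10_000, seed=1)
        for pid in ("kt_Succinate", "kd_Succinate"):
            mean = np.mean([c.multipliers[pid] for c in cells])
            assert abs(mean - 1.0) < 0.02

    def test_invalid_arguments(self, model):
        _, params = model
        with pytest.raises(ValueError):
            generate_cohort(params, ["kt_Succinate"], 0)
        with pytest.raises(ValueError):
            generate_cohort(params, [], 10)
        with pytest.raises(KeyError):
            generate_cohort(params, ["nope"], 10)


class TestApplyIntervention:
    def test_identity_intervention(self, model):
        _, params = model
        cells = generate_cohort(params, ["kt_Succinate"], 10, seed=0)
        same = apply_intervention(cells, "succinate", low=1.0, high=1.0)
        assert all(
            all(v == 1.0 for v in c.intervention.values()) for c in same
        )
        assert all(a.multipliers == b.multipliers for a, b in zip(cells, same))

    def test_intervention_range_composition(self, model):
        """Composed succinate multipliers stay within [0.5*0.5, 2.0*0.8]."""
        _, params = model
        cells = generate_cohort(params, DEFAULT_VARIED_PARAMETERS, 100, seed=0)
        treated = apply_intervention(cells, "succinate", 0.5, 0.8, seed=1)
        for c in treated:
            for pid, u in c.intervention.items():
                assert 0.5 <= u <= 0.8
                composed = c.multipliers.get(pid, 1.0) * u
                assert 0.5 * 0.5 <= composed <= 2.0 * 0.8

    def test_seeded_determinism(self, model):
        _, params = model
        cells = generate_cohort(params, ["kt_Succinate"], 25, seed=0)
        a = apply_intervention(cells, "succinate", seed=9)
        b = apply_intervention(cells, "succinate", seed=9)
        assert all(x.intervention == y.intervention for x, y in zip(a, b))

    def test_enhance_mode_uses_reciprocal_range(self, model):
        _, params = model
        cells = generate_cohort(params, ["kt_Succinate"], 20, seed=0)
        up = apply_intervention(cells, "IkB", 0.5, 0.8, seed=0, mode="enhance")
        for c in up:
            for u in c.intervention.values():
                assert 1 / 0.8 <= u <= 1 / 0.5

    def test_unknown_target(self, model):
        _, params = model
        cells = generate_cohort(params, ["kt_Succinate"], 3, seed=0)
        with pytest.raises(KeyError):
            apply_intervention(cells, "mitochondria")


class TestSimulateCohort:
    def test_identical_cells_have_zero_cf_variance(self, model, quiescent):
        net, params = model
        cells = [VirtualCell(f"c{i}", {"kt_Succinate": 1.0}) for i in range(3)]
        res = simulate_cohort(net, params, cells, quiescent)
        ends = res.endpoints()["cell_function"]
        assert ends.std() == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_ids_rejected_in_summary(self):
        sc = ScoreSeries(np.array([0.0, 1.0]), np.ones(2), np.ones(2),
                         np.ones(2))
        a = CohortResult([VirtualCell("a", {})], {"a": sc})
        b = CohortResult([VirtualCell("b", {})], {"b": sc})
        with pytest.raises(ValueError):
            summarize_cohort(a, b)


class TestSummarize:
    @staticmethod
    def _res(cf_by_cell):
        scores = {}
        cells = []
        for cid, cf in cf_by_cell.items():
            scores[cid] = ScoreSeries(
                np.array([0.0, 1.0]), np.ones(2), np.ones(2),
                np.array([1.0, cf]),
            )
            cells.append(VirtualCell(cid, {}))
        return CohortResult(cells, scores)

    def test_identical_arms_fold_one_fraction_zero(self):
        a = self._res({"a": 0.5, "b": 2.0})
        s = summarize_cohort(a, a)
        assert s["fold_changes"] == [1.0, 1.0]
        assert s["fraction_improved"] == 0.0  # strict >

    def test_hand_built_pairs(self):
        treated = self._res({"a": 2.0, "b": 1.0, "c": 3.0})
        control = self._res({"a": 1.0, "b": 2.0, "c": 1.0})
        s = summarize_cohort(treated, control)
        assert sorted(s["fold_changes"]) == [0.5, 2.0, 3.0]
        assert s["median"] == pytest.approx(2.0)
        assert s["fraction_improved"] == pytest.approx(2 / 3)


class TestTargetModulation:
    def test_strength_one_is_identity(self, model, quiescent):
        net, params = model
        treated, control = simulate_target_modulation(
            net, params, quiescent, "succinate", 1.0
        )
        assert np.allclose(treated.cell_function, control.cell_function)

    def test_invalid_strength_and_target(self, model, quiescent):
        net, params = model
        with pytest.raises(ValueError):
            simulate_target_modulation(net, params, quiescent, "succinate", 0.0)
        with pytest.raises(KeyError):
            simulate_target_modulation(net, params, quiescent, "caspase", 0.5)
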