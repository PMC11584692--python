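"""LHS design, PRCC against a brute-force oracle, and target ranking."""

import numpy as np
import pytest
from scipy import stats

from bmecsim import lhs_sample, prcc, rank_targets
from bmecsim.sensitivity import LHSDesign, SensitivityResult


def brute_force_prcc(X, y):
    """Independent oracle: residualize ranks by explicit least squares."""
    rx = np.apply_along_axis(stats.rankdata, 0, X)
    ry = stats.rankdata(y)
    k = X.shape[1]
    out = np.empty(k)
    for j in range(k):
        others = np.column_stack([np.ones(len(ry)), np.delete(rx, j, axis=1)])
        bx, *_ = np.linalg.lstsq(others, rx[:, j], rcond=None)
        by, *_ = np.linalg.lstsq(others, ry, rcond=None)
        ex = rx[:, j] - others @ bx
        ey = ry - others @ by
        out[j] = np.corrcoef(ex, ey)[0, 1]
    return out


class TestLHS:
    def test_one_sample_per_stratum(self):
        d = lhs_sample(["a"], 4, 0.5, 2.0, seed=0)
        edges = np.linspace(0.5, 2.0, 5)
        counts, _ = np.histogram(d.multipliers[:, 0], bins=edges)
        assert list(counts) == [1, 1, 1, 1]

    def test_stratification_holds_per_column(self):
        d = lhs_sample(list("abcde"), 50, seed=3)
        edges = np.linspace(0.5, 2.0, 51)
        for j in range(5):
            counts, _ = np.histogram(d.multipliers[:, j], bins=edges)
            assert np.all(counts == 1)

    def test_same_seed_identical_design(self):
        a = lhs_sample(["x", "y"], 16, seed=42)
        b = lhs_sample(["x", "y"], 16, seed=42)
        assert np.array_equal(a.multipliers, b.multipliers)
        c = lhs_sample(["x", "y"], 16, seed=43)
        assert not np.array_equal(a.multipliers, c.multipliers)

    def test_marginals_close_to_uniform(self):
        d = lhs_sample(["a", "b", "c"], 1000, seed=1)
        for j in range(3):
            ks = stats.kstest(d.multipliers[:, j],
                              stats.uniform(0.5, 1.5).cdf)
            assert ks.statistic < 0.05

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            lhs_sample(["a"], 1)
        with pytest.raises(ValueError):
            lhs_sample(["a"], 10, low=2.0, high=0.5)


class TestPRCC:
    def test_perfect_dependence(self):
        d = lhs_sample(["a", "b", "c"], 100, seed=0)
        y = d.multipliers[:, 0].copy()
        res = prcc(d, y[:, None], ["out"])
        assert res.prcc[0, 0] > 0.99
        assert np.abs(res.prcc[1:, 0]).max() < 0.2
        assert res.p_values[0, 0] < 1e-10

    def test_constant_output_degenerate_case(self):
        d = lhs_sample(["a", "b"], 30, seed=0)
        res = prcc(d, np.full((30, 1), 3.14), ["out"])
        assert np.all(res.prcc == 0) and np.all(res.p_values == 1)

    def test_signed_mixture_matches_brute_force(self):
        """y = 2*rank(x1) - rank(x2) + noise, checked to 1e-6 vs oracle."""
        rng = np.random.default_rng(7)
        d = lhs_sample(["x1", "x2", "x3"], 150, seed=5)
        rx = np.apply_along_axis(stats.rankdata, 0, d.multipliers)
        y = 2 * rx[:, 0] - rx[:, 1] + rng.normal(0, 5, 150)
        res = prcc(d, y[:, None], ["out"])
        assert res.prcc[0, 0] > 0 and res.prcc[1, 0] < 0
        oracle = brute_force_prcc(d.multipliers, y)
        assert np.abs(res.prcc[:, 0] - oracle).max() < 1e-6

    @pytest.mark.parametrize("k,n", [(2, 40), (3, 80), (5, 200)])
    def test_oracle_agreement_random_instances(self, k, n):
        rng = np.random.default_rng(100 * k + n)
        d = lhs_sample([f"p{i}" for i in range(k)], n, seed=k)
        y = (d.multipliers @ rng.normal(size=k)) ** 3 + rng.normal(0, 0.1, n)
        res = prcc(d, y[:, None], ["out"])
        oracle = brute_force_prcc(d.multipliers, y)
        assert np.abs(res.prcc[:, 0] - oracle).max() < 1e-6

    def test_invariance_under_monotone_input_transform(self):
        d = lhs_sample(["a", "b", "c"], 120, seed=9)
        y = np.exp(d.multipliers[:, 1]) + 0.3 * d.multipliers[:, 2]
        base = prcc(d, y[:, None], ["out"]).prcc[:, 0]
        warped = LHSDesign(
            d.parameter_ids,
            np.column_stack([np.log(d.multipliers[:, 0]),
                             d.multipliers[:, 1] ** 5,
                             d.multipliers[:, 2]]),
            d.seed,
        )
        assert np.allclose(prcc(warped, y[:, None], ["out"]).prcc[:, 0], base,
                           atol=1e-12)

    def test_null_output_calibration(self):
        """Output independent of inputs: |PRCC| below the 3/sqrt(n) band."""
        rng = np.random.default_rng(11)
        n = 400
        d = lhs_sample(["a", "b", "c", "d"], n, seed=2)
        y = rng.normal(size=n)
        res = prcc(d, y[:, None], ["out"])
        assert np.abs(res.prcc).max() < 3 / np.sqrt(n)

    def test_collinear_columns_raise_named_error(self):
        d = lhs_sample(["a", "b"], 40, seed=0)
        dup = LHSDesign(["a", "b", "b_copy"],
                        np.column_stack([d.multipliers, d.multipliers[:, 1]]),
                        0)
        y = np.arange(40.0)
        with pytest.raises(np.linalg.LinAlgError, match="b_copy"):
            prcc(dup, y[:, None], ["out"])

    def test_too_few_samples_rejected(self):
        d = lhs_sample(["a", "b"], 8, seed=0)
        with pytest.raises(ValueError, match="10"):
            prcc(d, np.arange(8.0)[:, None], ["out"])


class TestRankTargets:
    def _result(self, prccs, ps):
        k = len(prccs)
        return SensitivityResult(
            [f"p{i}" for i in range(k)], ["out"],
            np.array(prccs)[:, None], np.array(ps)[:, None], 100,
        )

    def test_absolute_value_sort(self):
        res = self._result([0.9, -0.95, 0.1], [0.001, 0.001, 0.001])
        assert [p for p, _, _ in rank_targets(res, "out")] == ["p1", "p0", "p2"]

    def test_insignificant_entries_excluded(self):
        res = self._result([0.9, -0.95, 0.1], [0.2, 0.6, 0.9])
        assert rank_targets(res, "out") == []

    def test_unknown_output_raises(self):
        res = self._result([0.5], [0.01])
        with pytest.raises(KeyError):
            rank_targets(res, "nope")

    def test_tie_break_lexicographic(self):
        res = SensitivityResult(
            ["zz", "aa"], ["out"], np.array([[0.5], [0.5]]),
            np.array([[0.01], [0.01]]), 100,
        )
        assert [p for p, _, _ in rank_targets(res, "out")] == ["aa", "zz"]


class TestDefaultModelSensitivity:
    def test_succinate_turnover_among_top_contributors(self, model, quiescent):
        """Succinate synthesis/turnover rates rank among the dominant
        parameters for the inflammation and tight-junction outputs."""
        from bmecsim import evaluate_design

        net, params = model
        pids = sorted(params.values)
        design = lhs_sample(pids, 500, seed=1)
        outputs = evaluate_design(net, params, design, quiescent)
        res = prcc(design, outputs)
        for output in ("inflammation", "tight_junction"):
            m = res.output_ids.index(output)
            order = np.argsort(-np.abs(res.prcc[:, m]))
            ranks = {pids[j]: pos + 1 for pos, j in enumerate(order)}
            succ = [ranks["kt_Succinate"], ranks["kd_Succinate"]]
            assert min(succ) <= 10, (output, succ)
            assert max(succ) <= 30, (output, succ)

    def test_identity_multipliers_reproduce_unperturbed_run(
        self, model, quiescent, ogdr_trajectory
    ):
        from bmecsim import cell_function_score, evaluate_design

        net, params = model
        ones = LHSDesign(["kt_Succinate"], np.ones((2, 1)), 0)
        out = evaluate_design(net, params, ones, quiescent,
                              output_ids=["cell_function"])
        expected = cell_function_score(ogdr_trajectory).cell_function[-1]
        assert out[:, 0] == pytest.approx(expected, rel=1e-6)
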