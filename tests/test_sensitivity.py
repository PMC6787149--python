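"""SRC regression and Sobol variance decomposition against analytic oracles."""

import numpy as np
import pytest

from ebpr_gsa.fixtures import analytic_models
from ebpr_gsa.sampling import saltelli_design
from ebpr_gsa.sensitivity import (
    bootstrap_ci,
    normalize_and_rank,
    sobol_indices,
    split_output_blocks,
    standardized_regression,
)


def evaluate_on_design(model, n_base):
    design = saltelli_design(n_base, model.n_inputs)
    lo, hi = model.bounds
    x = lo + design.unit_matrix * (hi - lo)
    return x, model(x)


@pytest.fixture(scope="module")
def models():
    return analytic_models()


@pytest.fixture(scope="module")
def ishigami_blocks(models):
    n = 2**14
    _, y = evaluate_on_design(models["ishigami"], n)
    return split_output_blocks(y, n, 3)


class TestStandardizedRegression:
    def test_perfect_single_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(200, 1))
        reg = standardized_regression(x, 3.0 * x[:, 0])
        assert reg.beta[0, 0] == pytest.approx(1.0)
        assert reg.r_squared[0] == pytest.approx(1.0)
        assert bool(reg.linear[0])

    def test_two_orthogonal_predictors_share_variance(self):
        # y = x1 + x2 with equal input variances: beta = 1/sqrt(2) each
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40_000, 2))
        x = (x - x.mean(0)) / x.std(0)
        x[:, 1] -= x[:, 0] * (x[:, 0] @ x[:, 1]) / (x[:, 0] @ x[:, 0])
        y = x[:, 0] + x[:, 1]
        reg = standardized_regression(x, y)
        np.testing.assert_allclose(reg.beta[:, 0], 1 / np.sqrt(2), atol=1e-4)
        assert np.sum(reg.beta[:, 0] ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_has_no_signal(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(10_000, 5))
        y = rng.standard_normal(10_000)
        reg = standardized_regression(x, y)
        assert np.abs(reg.beta).max() < 0.05
        assert reg.r_squared[0] < 0.01
        assert not bool(reg.linear[0])

    def test_rank_deficiency_names_offender(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(100, 3))
        x[:, 2] = 4.0                      # zero-variance column
        with pytest.raises(ValueError, match="x2"):
            standardized_regression(x, x[:, 0], input_names=["x0", "x1", "x2"])

    def test_collinear_design_allowed_when_requested(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(100, 3))
        x[:, 2] = x[:, 0] + x[:, 1]
        reg = standardized_regression(x, x[:, 0] + 0.5, allow_collinear=True)
        assert reg.r_squared[0] == pytest.approx(1.0)

    def test_constant_output_gets_zero_r_squared(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(50, 2))
        reg = standardized_regression(x, np.full(50, 1.23))
        assert reg.r_squared[0] == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            standardized_regression(np.ones((3, 5)), np.ones(3))


class TestSobolEstimators:
    def test_ishigami_first_order_within_002(self, models, ishigami_blocks):
        truth = models["ishigami"].truth
        res = sobol_indices(ishigami_blocks)
        np.testing.assert_allclose(res.s1.ravel(), truth["s1"], atol=0.02)

    def test_ishigami_total_order_within_002(self, models, ishigami_blocks):
        truth = models["ishigami"].truth
        res = sobol_indices(ishigami_blocks)
        np.testing.assert_allclose(res.st.ravel(), truth["st"], atol=0.02)

    def test_additive_model_has_no_interactions(self, models):
        model = models["linear_equal"]
        n = 2**12
        _, y = evaluate_on_design(model, n)
        res = sobol_indices(split_output_blocks(y, n, model.n_inputs))
        np.testing.assert_allclose(res.s1.ravel(), 0.25, atol=0.01)
        np.testing.assert_allclose(res.st.ravel(), 0.25, atol=0.01)
        assert res.s1.sum() == pytest.approx(1.0, abs=0.02)

    def test_dummy_input_has_null_indices(self, models):
        model = models["dummy"]
        n = 2**12
        _, y = evaluate_on_design(model, n)
        blocks = split_output_blocks(y, n, model.n_inputs)
        res = sobol_indices(blocks)
        s1_ci, st_ci = bootstrap_ci(blocks, n_boot=300, seed=0)
        assert abs(res.s1[2, 0]) <= max(s1_ci[2, 0], 1e-3)
        assert abs(res.st[2, 0]) <= max(st_ci[2, 0], 1e-3)

    def test_estimates_converge_with_sample_size(self, models):
        truth = models["ishigami"].truth["s1"]
        errs = []
        for n in (2**8, 2**11, 2**14):
            _, y = evaluate_on_design(models["ishigami"], n)
            res = sobol_indices(split_output_blocks(y, n, 3))
            errs.append(np.abs(res.s1.ravel() - truth).max())
        assert errs[2] < errs[0]

    def test_affine_output_rescaling_leaves_indices_unchanged(self, ishigami_blocks):
        f_a, f_b, f_ab = ishigami_blocks
        res = sobol_indices(ishigami_blocks)
        scaled = sobol_indices((5.0 * f_a - 2.0, 5.0 * f_b - 2.0, 5.0 * f_ab - 2.0))
        np.testing.assert_allclose(res.s1, scaled.s1, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(res.st, scaled.st, rtol=1e-9, atol=1e-12)

    def test_failed_tuples_dropped_pairwise(self, ishigami_blocks):
        f_a, f_b, f_ab = (b.copy() for b in ishigami_blocks)
        f_a[5] = np.nan
        f_ab[1, 17] = np.nan
        res = sobol_indices((f_a, f_b, f_ab))
        assert res.n_base == f_a.shape[0] - 2

    def test_degenerate_output_rejected(self):
        n = 64
        flat = np.ones(n)
        with pytest.raises(ValueError, match="Var"):
            sobol_indices((flat, flat, np.ones((2, n))))

    def test_mismatched_blocks_rejected(self):
        with pytest.raises(ValueError, match="block"):
            sobol_indices((np.ones(8), np.ones(8), np.ones((2, 6))))


class TestBootstrap:
    def test_deterministic_under_seed(self, ishigami_blocks):
        a = bootstrap_ci(ishigami_blocks, n_boot=200, seed=9)
        b = bootstrap_ci(ishigami_blocks, n_boot=200, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_constant_output_zero_width(self):
        n = 64
        rng = np.random.default_rng(0)
        y = rng.uniform(size=n)
        flat = np.ones((n, 1))
        f_a = np.column_stack([y, flat[:, 0]])
        f_b = np.column_stack([rng.uniform(size=n), flat[:, 0]])
        f_ab = np.stack([f_a, f_b])
        s1_ci, st_ci = bootstrap_ci((f_a, f_b, f_ab), n_boot=150, seed=1)
        np.testing.assert_array_equal(s1_ci[:, 1], 0.0)
        np.testing.assert_array_equal(st_ci[:, 1], 0.0)

    def test_stability_under_more_resamples(self, ishigami_blocks):
        a, _ = bootstrap_ci(ishigami_blocks, n_boot=400, seed=3)
        b, _ = bootstrap_ci(ishigami_blocks, n_boot=800, seed=3)
        assert np.all(np.abs(a - b) <= 0.2 * np.maximum(a, b) + 1e-4)

    def test_coverage_of_analytic_truth(self, models, ishigami_blocks):
        truth = models["ishigami"].truth["s1"]
        res = sobol_indices(ishigami_blocks)
        s1_ci, _ = bootstrap_ci(ishigami_blocks, n_boot=1000, conf=0.95, seed=7)
        assert np.all(np.abs(res.s1.ravel() - truth) <= s1_ci.ravel() + 1e-3)

    def test_small_sample_rejected(self):
        n = 8
        with pytest.raises(ValueError, match="32"):
            bootstrap_ci((np.ones(n), np.ones(n), np.ones((2, n))), n_boot=100)


class TestNormalizeAndRank:
    def _result(self, st_rows):
        from ebpr_gsa.sensitivity import SobolResult

        st = np.asarray(st_rows, dtype=float)[:, None]
        return SobolResult(s1=st * 0.5, st=st, input_names=["a", "b", "c"],
                           output_names=["y"])

    def test_already_normalized_rows_unchanged(self):
        table = normalize_and_rank(self._result([0.2, 0.3, 0.5]))
        np.testing.assert_allclose(table.normalized_st["y"], [0.2, 0.3, 0.5])

    def test_proportional_rescale(self):
        table = normalize_and_rank(self._result([1.0, 1.0, 2.0]))
        np.testing.assert_allclose(table.normalized_st["y"], [0.25, 0.25, 0.5])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        table = normalize_and_rank(self._result(rng.uniform(0.01, 1.0, 3)))
        assert table.normalized_st["y"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_estimates_clamped(self):
        table = normalize_and_rank(self._result([-0.05, 0.5, 0.5]))
        np.testing.assert_allclose(table.normalized_st["y"], [0.0, 0.5, 0.5])

    def test_cutoff_filters_display_ranking(self):
        table = normalize_and_rank(self._result([0.1, 0.35, 0.6]))
        assert table.per_output["y"] == ["c", "b"]

    def test_group_rankings_cover_groups(self):
        table = normalize_and_rank(
            self._result([0.3, 0.2, 0.5]),
            groups={"a": "g1", "b": "g1", "c": "g2"},
        )
        assert list(table.per_group["g1"]["y"]) == ["a", "b"]
        assert list(table.per_group["g2"]["y"]) == ["c"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_and_rank(self._result([0.0, 0.0, 0.0]))
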