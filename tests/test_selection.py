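"""Stratified splitting, Mann-Whitney filtering, LASSO, and the voted
selection procedure."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ovradiomics import (
    FilterConfig,
    ResamplePlan,
    TableSimConfig,
    VotedLassoModel,
    lasso_fit,
    mwu_test,
    radscore,
    retention_count,
    simulate_feature_table,
    stratified_split,
)


class TestStratifiedSplit:
    def test_665_at_80_20(self):
        y = np.array([1] * 436 + [0] * 229)
        tr, te = stratified_split(y, 0.8, seed=0)
        assert len(tr) == 532 and len(te) == 133
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == 665

    def test_class_proportions_preserved(self):
        y = np.array([1] * 436 + [0] * 229)
        tr, _ = stratified_split(y, 0.8, seed=3)
        # per-class train counts are round(n_c * f): exact stratification
        assert (y[tr] == 1).sum() == round(436 * 0.8)
        assert (y[tr] == 0).sum() == round(229 * 0.8)

    def test_same_seed_identical(self):
        y = np.repeat([0, 1], [40, 60])
        t1 = stratified_split(y, 0.8, seed=9)
        t2 = stratified_split(y, 0.8, seed=9)
        np.testing.assert_array_equal(t1[0], t2[0])
        np.testing.assert_array_equal(t1[1], t2[1])

    def test_tiny_class_raises(self):
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="class"):
            stratified_split(y, 0.8, seed=0)


def exact_mwu_p(x, y):
    """Oracle: enumerate every label assignment of the pooled sample."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        us.append(ranks[list(comb)].sum() - n * (n + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestMwuTest:
    def test_textbook_example(self):
        u, p = mwu_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_samples_p_one(self):
        _, p = mwu_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0, abs=0.01)

    def test_matches_enumeration_oracle_small_samples(self, rng):
        # all two-sample shapes with n+m <= 12 (tie-free draws)
        for n, m in [(2, 3), (3, 3), (4, 4), (3, 7), (5, 6), (6, 6), (4, 8)]:
            for _ in range(3):
                x = rng.normal(size=n)
                y = rng.normal(size=m)
                _, p = mwu_test(x, y)
                assert p == pytest.approx(exact_mwu_p(x, y), abs=1e-12)

    def test_exact_vs_normal_approximation(self, rng):
        # n = m = 8: the two p-value routes agree within 0.02
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            p_exact = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            p_norm = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mwu_test([], [1.0])


class TestLassoFit:
    def test_huge_penalty_shrinks_all_to_zero(self, rng):
        X = rng.normal(size=(50, 5))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.integers(0, 2, 50)
        coefs, _ = lasso_fit(X, y, lam=1e4)
        assert np.all(coefs == 0.0)

    def test_orthonormal_soft_threshold_oracle(self, rng):
        # linear-link LASSO on a design with X'X = n I: the solution is
        # the soft-thresholded OLS estimate S(beta, lam)
        n, p = 64, 6
        base = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        q, _ = np.linalg.qr(base)
        X = q[:, 1:] * np.sqrt(n)  # orthogonal, mean-zero, norm sqrt(n)
        beta = np.array([2.0, -1.0, 0.5, 0.0, 0.1, -0.3])
        y = X @ beta  # noiseless
        ols = X.T @ y / n
        for lam in (0.05, 0.4, 1.5):
            coefs, _ = lasso_fit(X, y, lam=lam, family="linear")
            expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            np.testing.assert_allclose(coefs, expected, atol=1e-5)

    def test_cv_recovers_strong_single_feature(self):
        # effect 2.0, n = 400: the informative coefficient is nonzero in
        # nearly every seed at the cross-validated lambda
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            t = simulate_feature_table(
                TableSimConfig(
                    n_patients=400, n_features=8, n_informative=1,
                    effect_sizes=2.0, prevalence=0.5, seed=seed,
                )
            )
            X = (t.X - t.X.mean(0)) / t.X.std(0)
            coefs, _ = lasso_fit(X, t.y, seed=seed)
            hits += coefs[0] != 0.0
        assert hits >= math.ceil(0.95 * n_seeds)


class TestRetention:
    def test_pool_of_200_retains_exactly_20(self):
        assert retention_count(200) == 20

    @pytest.mark.parametrize(
        "pool,expected",
        [(1, 1), (9, 1), (10, 1), (11, 2), (50, 5), (199, 20), (500, 20)],
    )
    def test_cap_and_ceiling(self, pool, expected):
        assert retention_count(pool) == expected


@pytest.fixture(scope="module")
def planted_result():
    t = simulate_feature_table(
        TableSimConfig(
            n_patients=400, n_features=60, n_informative=5,
            effect_sizes=(1.2, 1.1, 1.0, 1.0, 1.0), seed=21,
        )
    )
    model = VotedLassoModel(t, plan=ResamplePlan(n_resamples=30, base_seed=5))
    return t, model.fit()


class TestVotedLasso:
    def test_planted_features_out_vote_nulls(self, planted_result):
        t, res = planted_result
        planted = res.frequencies[t.informative]
        nulls = res.frequencies.drop(t.informative)
        assert planted.min() > nulls.max()

    def test_frequencies_bounded(self, planted_result):
        _, res = planted_result
        assert (res.frequencies >= 0).all()
        assert (res.frequencies <= res.n_resamples).all()

    def test_retained_subset_of_pool(self, planted_result):
        _, res = planted_result
        assert set(res.retained) <= set(res.pool)
        assert len(res.retained) == retention_count(len(res.pool))

    def test_deterministic_from_base_seed(self):
        t = simulate_feature_table(
            TableSimConfig(n_patients=150, n_features=20, seed=3)
        )
        plan = ResamplePlan(n_resamples=8, base_seed=11)
        r1 = VotedLassoModel(t, plan=plan).fit()
        r2 = VotedLassoModel(t, plan=plan).fit()
        assert r1.frequencies.equals(r2.frequencies)
        assert r1.avg_coefficients.equals(r2.avg_coefficients)
        assert r1.retained == r2.retained

    def test_coef_average_includes_zeros(self, planted_result):
        _, res = planted_result
        # averaged-over-all coefficient magnitude is bounded by the mean
        # over selected resamples scaled by the vote share
        name = res.retained[0]
        share = res.frequencies[name] / res.n_resamples
        per_sel = [
            rec.selected[name] for rec in res.records if name in rec.selected
        ]
        assert res.avg_coefficients[name] == pytest.approx(
            np.mean(per_sel) * share, rel=1e-9
        )

    def test_no_selection_raises(self):
        # two pure-noise features at tiny n: the filter kills everything
        t = simulate_feature_table(
            TableSimConfig(
                n_patients=24, n_features=2, n_informative=0,
                effect_sizes=(), prevalence=0.5, seed=2,
            )
        )
        model = VotedLassoModel(
            t,
            plan=ResamplePlan(n_resamples=3, base_seed=0),
            filter_config=FilterConfig(alpha=1e-6),
        )
        with pytest.raises(ValueError, match="ever selected"):
            model.fit()

    def test_serialization_roundtrip(self, planted_result, tmp_path):
        import json

        _, res = planted_result
        res.to_json(tmp_path / "sel.json")
        doc = json.loads((tmp_path / "sel.json").read_text())
        assert doc["retained"] == res.retained
        assert doc["n_resamples"] == res.n_resamples


class TestRadscore:
    def _result_with(self, weights):
        t = simulate_feature_table(
            TableSimConfig(n_patients=100, n_features=10, seed=1)
        )
        res = VotedLassoModel(
            t, plan=ResamplePlan(n_resamples=4, base_seed=2),
            target_fraction=0.6,
        ).fit()
        res.avg_coefficients[:] = 0.0
        retained = res.retained
        for name, w in zip(retained, weights):
            res.avg_coefficients[name] = w
        return res

    def test_zero_weights_zero_score(self):
        res = self._result_with([])
        x = {name: 2.0 for name in res.feature_names}
        assert radscore(x, res) == 0.0

    def test_single_feature_arithmetic(self):
        res = self._result_with([0.5])
        x = dict.fromkeys(res.feature_names, 0.0)
        x[res.retained[0]] = 2.0
        assert radscore(x, res) == pytest.approx(1.0)

    def test_two_feature_arithmetic(self):
        res = self._result_with([0.5, 0.3])
        x = dict.fromkeys(res.feature_names, 0.0)
        x[res.retained[0]] = 2.0
        x[res.retained[1]] = -1.0
        assert radscore(x, res) == pytest.approx(2.0 * 0.5 - 1.0 * 0.3)

    def test_linearity(self):
        res = self._result_with([0.7, -0.2, 0.1])
        rng = np.random.default_rng(0)
        x = dict(zip(res.feature_names, rng.normal(size=10)))
        ax = {k: 3.0 * v for k, v in x.items()}
        assert radscore(ax, res) == pytest.approx(3.0 * radscore(x, res))

    def test_missing_feature_named_in_error(self):
        res = self._result_with([0.5])
        x = dict.fromkeys(res.feature_names, 1.0)
        missing = res.retained[0]
        del x[missing]
        with pytest.raises(KeyError, match=missing):
            radscore(x, res)
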