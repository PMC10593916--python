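"""Tests for the mixed-effects, permutation and effect-size statistics."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import neurostim as ns
from neurostim import stats as nstats


def _table(values, subjects=None, regions=None):
    n = len(values)
    return pd.DataFrame({
        "subject_id": subjects if subjects is not None else ["s0"] * n,
        "image_id": [f"i{k}" for k in range(n)],
        "repeat_index": [1] * n,
        "region": regions if regions is not None else ["R"] * n,
        "response": values,
    })


class TestZScore:
    def test_moments(self):
        rng = np.random.default_rng(0)
        t = _table(rng.normal(2.0, 3.0, size=50))
        z = ns.zscore_responses(t)
        assert abs(z["response"].mean()) < 1e-12
        assert z["response"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_population_sd_convention(self):
        z = ns.zscore_responses(_table([1.0, 2.0, 3.0, 4.0]))
        # divide-by-n sd of {1,2,3,4} is sqrt(5)/2
        np.testing.assert_allclose(
            z["response"], [-1.34164079, -0.4472136, 0.4472136, 1.34164079])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=30)
        z1 = ns.zscore_responses(_table(v))["response"]
        z2 = ns.zscore_responses(_table(5.0 * v - 2.0))["response"]
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_constant_scope_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ns.zscore_responses(_table([1.0, 1.0, 1.0]))

    def test_scoped_by_subject_and_region(self):
        t = _table([1.0, 3.0, 10.0, 30.0],
                   subjects=["a", "a", "b", "b"])
        z = ns.zscore_responses(t)
        np.testing.assert_allclose(z["response"], [-1, 1, -1, 1])


def _lme_data(rng, S=6, n_per=40, effect=0.4, sig_a=0.6, sig_e=1.0):
    subj = np.repeat(np.arange(S), n_per)
    x = np.tile(np.r_[np.zeros(n_per // 2), np.ones(n_per // 2)], S)
    alpha = rng.normal(0, sig_a, S)
    y = effect * x + alpha[subj] + rng.normal(0, sig_e, S * n_per)
    return y, x, subj


class TestFitLME:
    def test_no_condition_difference_gives_zero_beta(self):
        y = np.array([1.0, 1.0, 2.0, 2.0, 5.0, 5.0, 3.0, 3.0])
        x = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        subj = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert ns.fit_lme(y, x, subj).beta == pytest.approx(0.0, abs=1e-10)

    def test_balanced_no_offsets_equals_mean_difference(self):
        rng = np.random.default_rng(2)
        y, x, subj = _lme_data(rng, sig_a=0.0)
        fit = ns.fit_lme(y, x, subj)
        # balanced design: the GLS condition effect equals the OLS
        # difference of condition means at any variance ratio
        assert fit.beta == pytest.approx(y[x == 1].mean() - y[x == 0].mean(),
                                         abs=1e-10)

    def test_profiled_closed_forms_match_dense_gls(self):
        """The per-subject sufficient-statistic forms equal a dense-matrix
        GLS oracle at fixed variance ratios."""
        rng = np.random.default_rng(3)
        y, x, subj = _lme_data(rng, S=2, n_per=4)
        X = np.column_stack([np.ones_like(y), x])
        prob = nstats._RemlProblem(y, X, subj)
        Z = np.zeros((len(y), 2))
        Z[np.arange(len(y)), subj] = 1.0
        for theta in (0.0, 0.3, 2.0, 50.0):
            V = np.eye(len(y)) + theta * Z @ Z.T
            Vi = np.linalg.inv(V)
            beta_oracle = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            beta, _, _, _ = prob.fit_at(theta)
            np.testing.assert_allclose(beta, beta_oracle, atol=1e-10)

    def test_matches_statsmodels_reml(self):
        from statsmodels.regression.mixed_linear_model import MixedLM
        rng = np.random.default_rng(4)
        for _ in range(4):
            y, x, subj = _lme_data(rng)
            fit = ns.fit_lme(y, x, subj)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ml = MixedLM(y, np.column_stack([np.ones_like(y), x]),
                             groups=subj).fit(reml=True)
            assert fit.beta == pytest.approx(ml.params[1], abs=1e-8)
            assert fit.random_sd == pytest.approx(
                float(np.sqrt(np.asarray(ml.cov_re)[0, 0])), abs=5e-3)
            assert fit.resid_sd == pytest.approx(float(np.sqrt(ml.scale)),
                                                 abs=5e-3)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        y, x, subj = _lme_data(rng)
        b1 = ns.fit_lme(y, x, subj).beta
        b2 = ns.fit_lme(y + 17.3, x, subj).beta
        assert b1 == pytest.approx(b2, abs=1e-9)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match="two conditions"):
            ns.fit_lme(np.zeros(4), np.zeros(4), np.array([0, 0, 1, 1]))


class TestPermutationTest:
    def test_constant_responses_p_is_one(self):
        y = np.ones(12)
        x = np.tile([0, 1], 6)
        subj = np.repeat([0, 1], 6)
        res = ns.permutation_test(y, x, subj, n_perm=50, seed=0)
        assert res.beta_obs == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == 1.0

    def test_matches_exhaustive_enumeration_one_subject(self):
        """Sampled p within Monte-Carlo error of the exact p over all 20
        arrangements of 3+3 labels."""
        y = np.array([0.2, 1.1, -0.4, 2.0, 2.6, 1.8])
        x0 = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        subj = np.zeros(6, dtype=int)
        beta_obs = float(nstats._perm_betas(y, x0[:, None], subj)[0])
        betas = []
        for ones in itertools.combinations(range(6), 3):
            x = np.zeros(6)
            x[list(ones)] = 1.0
            betas.append(float(nstats._perm_betas(y, x[:, None], subj)[0]))
        exact_p = np.mean(np.abs(betas) >= abs(beta_obs))
        n_perm = 2000
        res = ns.permutation_test(y, x0, subj, n_perm=n_perm, seed=3)
        se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
        assert abs(res.p_two_sided - exact_p) <= 3 * se + 1e-9

    def test_vectorized_null_matches_per_column_reml(self):
        rng = np.random.default_rng(6)
        y, x, subj = _lme_data(rng, S=3, n_per=8)
        res = ns.permutation_test(y, x, subj, n_perm=20, seed=1)
        assert len(res.null_betas) == 20
        # refit a few permutations through the scalar path
        rng2 = np.random.default_rng(1)
        Xp = np.empty((len(y), 20))
        for i in range(3):
            rows = np.flatnonzero(subj == i)
            block = np.broadcast_to(x[rows], (20, rows.size))
            Xp[rows] = rng2.permuted(block, axis=1).T
        for k in (0, 7, 19):
            scalar = ns.fit_lme(y, Xp[:, k], subj).beta
            assert res.null_betas[k] == pytest.approx(scalar, abs=1e-7)

    def test_within_subject_scheme_preserves_block_counts(self):
        y, x, subj = _lme_data(np.random.default_rng(7), S=3, n_per=10)
        res = ns.permutation_test(y, x, subj, n_perm=10, seed=2)
        assert res.null_betas.shape == (10,)
        # a label permutation cannot change the per-subject label sums,
        # so the observed beta is one draw from the same family
        assert np.isfinite(res.beta_obs)


class TestFdrBH:
    def test_all_ones_none_rejected(self):
        assert not ns.fdr_bh(np.ones(7), 0.05).any()

    def test_hand_example(self):
        flags = ns.fdr_bh([0.001, 0.2, 0.9], 0.05)
        np.testing.assert_array_equal(flags, [True, False, False])

    def test_matches_bruteforce_step_up(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            m = rng.integers(1, 11)
            p = rng.random(m)
            got = ns.fdr_bh(p, 0.05)
            # independent step-up: largest k with p_(k) <= k q / m
            order = np.argsort(p)
            k_star = 0
            for k in range(1, m + 1):
                if p[order[k - 1]] <= k * 0.05 / m:
                    k_star = k
            expected = np.zeros(m, dtype=bool)
            expected[order[:k_star]] = True
            np.testing.assert_array_equal(got, expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ns.fdr_bh([0.5, 1.2], 0.05)


class TestCohensD:
    def test_identical_groups_zero(self):
        assert ns.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_value_minus_two(self):
        assert ns.cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 12)
        assert ns.cohens_d(3.7 * a, 3.7 * b) == pytest.approx(
            ns.cohens_d(a, b))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            ns.cohens_d([1.0, 1.0], [2.0, 2.0])


def _repeat_table(measured, n_rep=2, subject="s0"):
    rows = []
    for iid, vals in measured.items():
        for rep, v in enumerate(vals, start=1):
            rows.append({"subject_id": subject, "image_id": iid,
                         "repeat_index": rep, "region": "R", "response": v})
    return pd.DataFrame(rows)


class TestEncodingAccuracy:
    def test_perfect_predictions(self):
        t = _repeat_table({f"i{k}": (k + 0.1, k - 0.1) for k in range(5)})
        preds = {f"i{k}": float(k) for k in range(5)}
        assert ns.encoding_accuracy(preds, t) == pytest.approx(1.0)

    def test_single_repeat_images_excluded(self):
        base = {f"i{k}": (k + 0.2, k - 0.2) for k in range(4)}
        t1 = _repeat_table(base)
        with_extra = pd.concat(
            [t1, _repeat_table({"solo": (99.0,)})], ignore_index=True)
        preds = {f"i{k}": float(k) for k in range(4)}
        preds["solo"] = -50.0
        assert ns.encoding_accuracy(preds, with_extra) == pytest.approx(
            ns.encoding_accuracy(preds, t1))

    def test_hand_computed_pearson(self):
        meas = {"a": (1.0, 3.0), "b": (2.0, 2.0), "c": (5.0, 3.0),
                "d": (0.0, 2.0), "e": (4.0, 4.0)}
        preds = {"a": 1.5, "b": 2.5, "c": 3.0, "d": 0.5, "e": 4.5}
        t = _repeat_table(meas)
        x = np.array([1.5, 2.5, 3.0, 0.5, 4.5])
        y = np.array([2.0, 2.0, 4.0, 1.0, 4.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert ns.encoding_accuracy(preds, t) == pytest.approx(expected)

    def test_too_few_images_rejected(self):
        t = _repeat_table({"a": (1.0, 2.0), "b": (0.0, 1.0)})
        with pytest.raises(ValueError, match="at least 3"):
            ns.encoding_accuracy({"a": 1.0, "b": 0.0}, t)


class TestSimilarityMatrix:
    def _two_subject_table(self, rows_a, rows_b):
        return pd.concat([
            _repeat_table(rows_a, subject="a"),
            _repeat_table(rows_b, subject="b")], ignore_index=True)

    def test_identical_noiseless_subjects_all_ones(self):
        meas = {f"i{k}": (float(k), float(k)) for k in range(4)}
        sim = ns.subject_similarity_matrix(
            self := self._two_subject_table(meas, meas), "R")
        np.testing.assert_allclose(sim.to_numpy(), 1.0)

    def test_symmetric_offdiagonal(self):
        rng = np.random.default_rng(10)
        a = {f"i{k}": tuple(rng.normal(k, 1, 2)) for k in range(6)}
        b = {f"i{k}": tuple(rng.normal(-k, 1, 2)) for k in range(6)}
        sim = ns.subject_similarity_matrix(self._two_subject_table(a, b), "R")
        assert sim.loc["a", "b"] == pytest.approx(sim.loc["b", "a"])

    def test_hand_computed_entries(self):
        a = {"i0": (1.0, 2.0), "i1": (2.0, 4.0), "i2": (3.0, 3.0),
             "i3": (4.0, 7.0)}
        b = {"i0": (2.0, 1.0), "i1": (1.0, 2.0), "i2": (4.0, 4.0),
             "i3": (3.0, 5.0)}
        sim = ns.subject_similarity_matrix(self._two_subject_table(a, b), "R")
        means_a = np.array([1.5, 3.0, 3.0, 5.5])
        means_b = np.array([1.5, 1.5, 4.0, 4.0])
        expected_off = np.corrcoef(means_a, means_b)[0, 1]
        expected_diag_a = np.corrcoef([1, 2, 3, 4], [2, 4, 3, 7])[0, 1]
        assert sim.loc["a", "b"] == pytest.approx(expected_off)
        assert sim.loc["a", "a"] == pytest.approx(expected_diag_a)

    def test_no_common_images_rejected(self):
        t = self_t = pd.concat([
            _repeat_table({"x": (1.0, 2.0)}, subject="a"),
            _repeat_table({"y": (1.0, 2.0)}, subject="b")],
            ignore_index=True)
        with pytest.raises(ValueError, match="common"):
            ns.subject_similarity_matrix(t, "R")


class TestAccuracyVsD:
    def test_perfect_linear_relation(self):
        acc = np.linspace(0.1, 0.9, 6)
        d = 2.0 * acc + 0.3
        r, p = ns.accuracy_vs_d_correlation(acc, d, n_perm=200, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_three_point_enumeration(self):
        # unevenly spaced x keeps the six permutation |r| values distinct
        acc = np.array([0.1, 0.4, 0.9])
        d = np.array([0.3, 0.2, 0.8])
        r_obs = np.corrcoef(acc, d)[0, 1]
        rs = [np.corrcoef(acc, np.array(perm))[0, 1]
              for perm in itertools.permutations(d)]
        exact_p = np.mean(np.abs(rs) >= abs(r_obs) - 1e-12)
        r, p = ns.accuracy_vs_d_correlation(acc, d, n_perm=3000, seed=1)
        se = np.sqrt(exact_p * (1 - exact_p) / 3000)
        assert r == pytest.approx(r_obs)
        assert abs(p - exact_p) <= 3 * se + 1e-9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ns.accuracy_vs_d_correlation([1, 2], [1, 2])


class TestHierarchyTrend:
    def _frame(self, t_by_level, subjects=("s0", "s1")):
        rows = []
        for subj in subjects:
            for region, lvl_t in t_by_level.items():
                for ctype in ("SelfVsGroup", "SelfVsOther"):
                    rows.append({"subject_id": subj, "region": region,
                                 "contrast_type": ctype, "t_stat": lvl_t})
        return pd.DataFrame(rows)

    def test_constant_t_stats_zero_slope(self):
        df = self._frame({"A": 1.5, "B": 1.5, "C": 1.5})
        fit, _ = ns.hierarchy_trend_lme(df, {"A": 1, "B": 2, "C": 3},
                                        n_perm=20, seed=0)
        assert fit.beta == pytest.approx(0.0, abs=1e-9)

    def test_linear_trend_equals_ols_slope(self):
        levels = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}
        df = self._frame({r: 0.7 * lvl - 0.2 for r, lvl in levels.items()})
        fit, _ = ns.hierarchy_trend_lme(df, levels, n_perm=20, seed=0)
        assert fit.beta == pytest.approx(0.7, abs=1e-8)

    def test_single_level_rejected(self):
        df = self._frame({"A": 1.0})
        with pytest.raises(ValueError, match="two hierarchy levels"):
            ns.hierarchy_trend_lme(df, {"A": 1})


class TestNatSynCompare:
    def test_identical_vectors(self):
        v = np.array([0.2, 0.4, 0.6, 0.8])
        t, r = ns.nat_syn_accuracy_compare(v, v)
        assert t == 0.0
        assert r == pytest.approx(1.0)

    def test_hand_computed_paired_t(self):
        a = np.array([0.5, 0.7, 0.6, 0.9])
        b = np.array([0.4, 0.5, 0.7, 0.6])
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        t, r = ns.nat_syn_accuracy_compare(a, b)
        assert t == pytest.approx(expected_t)
        assert r == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_swap_negates_t(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0.6, 0.1, 8), rng.normal(0.5, 0.1, 8)
        t1, _ = ns.nat_syn_accuracy_compare(a, b)
        t2, _ = ns.nat_syn_accuracy_compare(b, a)
        assert t1 == pytest.approx(-t2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ns.nat_syn_accuracy_compare([1, 2, 3], [1, 2])
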