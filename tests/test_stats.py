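"""Unit tests for the differential-statistics core."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from transkingdom.stats import (
    ModeratedFit,
    Thresholds,
    bh_fdr,
    call_differential,
    fisher_combine,
    fit_moderated,
    grubbs_remove_outlier,
    log2_transform,
    permutation_t_test,
)

# ---------------------------------------------------------------------------
# Grubbs


class TestGrubbs:
    def test_removes_clear_outlier(self):
        vals = [5.0, 5.1, 4.9, 5.05, 12.0]
        kept, idx = grubbs_remove_outlier(vals, alpha=0.05)
        assert idx == 4
        assert 12.0 not in kept
        # verify against the closed-form critical value at N=5
        x = np.array(vals)
        g = np.abs(x - x.mean()).max() / x.std(ddof=1)
        t = sps.t.ppf(1 - 0.05 / 10, 3)
        crit = 4 / math.sqrt(5) * math.sqrt(t * t / (3 + t * t))
        assert g > crit

    def test_uniform_spread_not_removed(self):
        # G = 2/sqrt(2.5) ~ 1.265, below the N=5 critical value
        kept, idx = grubbs_remove_outlier([1, 2, 3, 4, 5], alpha=0.05)
        assert idx is None and len(kept) == 5

    def test_zero_variance_passthrough(self):
        kept, idx = grubbs_remove_outlier([5, 5, 5, 5, 5])
        assert idx is None

    def test_too_small_group_warns(self):
        with pytest.warns(UserWarning):
            kept, idx = grubbs_remove_outlier([1.0, 9.0])
        assert idx is None

    def test_single_pass_removes_at_most_one(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 9), [50.0]])
        kept, idx = grubbs_remove_outlier(vals)
        assert len(kept) == len(vals) - 1 and 50.0 not in kept
        # a second extreme value is only found by a second explicit pass
        kept2, _ = grubbs_remove_outlier(np.concatenate([kept, [45.0]]))
        assert len(kept2) == len(kept)


# ---------------------------------------------------------------------------
# log2


def test_log2_transform_values_and_error():
    m = pd.DataFrame({"a": [8.0, 1.0]}, index=["s1", "s2"])
    out = log2_transform(m)
    assert out["a"].tolist() == [3.0, 0.0]
    m.loc["s2", "a"] = 0.0
    with pytest.raises(ValueError, match="'a'.*'s2'"):
        log2_transform(m)


# ---------------------------------------------------------------------------
# Fisher combination


class TestFisherCombine:
    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_4df_closed_form(self, rng):
        # chi-square survival on 4 df has the closed form e^(-x/2)(1 + x/2)
        for _ in range(200):
            p1, p2 = rng.uniform(1e-6, 1, 2)
            x = -2 * (math.log(p1) + math.log(p2))
            expected = math.exp(-x / 2) * (1 + x / 2)
            assert fisher_combine([p1, p2]) == pytest.approx(expected, abs=1e-12)

    def test_known_value(self):
        x = -4 * math.log(0.05)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(
            math.exp(-x / 2) * (1 + x / 2)
        )
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.0175, abs=5e-5)

    def test_singleton_identity(self):
        for p in (0.001, 0.3, 0.99):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-12)

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            out = fisher_combine([0.0, 0.5])
        assert 0 < out < 1

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        p=st.floats(1e-8, 1.0),
        q=st.floats(1e-8, 1.0),
        shrink=st.floats(0.1, 0.99),
    )
    def test_monotone_in_each_argument(self, p, q, shrink):
        assert fisher_combine([p * shrink, q]) <= fisher_combine([p, q]) + 1e-15


# ---------------------------------------------------------------------------
# BH FDR


def _bh_oracle(p):
    """Brute-force step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single(self):
        np.testing.assert_allclose(bh_fdr([0.5]), [0.5])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 25))
            np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-15)

    def test_q_at_least_p_after_sorting(self, rng):
        p = np.sort(rng.uniform(size=20))
        assert np.all(np.sort(bh_fdr(p)) >= p - 1e-15)


# ---------------------------------------------------------------------------
# moderated fit


def _random_two_group(rng, n_features=20, n1=5, n2=5):
    x = rng.standard_normal((n1 + n2, n_features)) * rng.uniform(0.5, 2, n_features)
    df = pd.DataFrame(
        x,
        index=[f"s{i}" for i in range(n1 + n2)],
        columns=[f"f{i}" for i in range(n_features)],
    )
    groups = pd.Series(["a"] * n1 + ["b"] * n2, index=df.index)
    return df, groups


class TestModeratedFit:
    def test_no_shrinkage_equals_ordinary_t(self, rng):
        for _ in range(50):
            df, groups = _random_two_group(rng)
            fit = fit_moderated(df, groups, "a", "b", df_prior=0)
            a = df[groups == "a"].to_numpy()
            b = df[groups == "b"].to_numpy()
            t_ref, p_ref = sps.ttest_ind(a, b, axis=0, equal_var=True)
            np.testing.assert_allclose(fit.t, t_ref, atol=1e-12)
            np.testing.assert_allclose(fit.p, p_ref, atol=1e-12)

    def test_identical_variances_full_shrinkage(self, rng):
        # equal true variances: shared spread of log s2 is within sampling
        # expectation, so the prior df estimate diverges and every posterior
        # variance collapses onto the prior
        df, groups = _random_two_group(rng, n_features=200)
        # force literally identical sample variances by duplicating one feature
        base = df.iloc[:, 0]
        for j in range(df.shape[1]):
            df.iloc[:, j] = base + j  # shift changes mean only
        fit = fit_moderated(df, groups, "a", "b")
        assert math.isinf(fit.df_prior)
        np.testing.assert_allclose(fit.s2_posterior, fit.s2_prior)

    def test_posterior_variance_between_extremes(self, rng):
        df, groups = _random_two_group(rng, n_features=40)
        fit = fit_moderated(df, groups, "a", "b")
        lo = np.minimum(fit.s2, fit.s2_prior) - 1e-12
        hi = np.maximum(fit.s2, fit.s2_prior) + 1e-12
        assert np.all((fit.s2_posterior >= lo) & (fit.s2_posterior <= hi))

    def test_matches_limma_reference(self):
        """Frozen reference computed with Bioconductor limma (lmFit + eBayes)."""
        x = np.array([
            [3.117327978, 1.6079452427, 0.8679874477, 2.4000881466, 1.5782434002,
             0.8616453462, 0.0710822314, -1.1086502675, 0.2255452437, -0.4352837669],
            [-1.3109976931, 2.3990008197, -0.3366612844, 0.2017730715, -0.0859560377,
             -0.7660634777, 1.0199382692, 0.3486257184, 1.2151222627, -0.9493781219],
            [-0.6209940998, 0.3192981912, -0.0043133056, 0.672859594, -0.3760981004,
             -0.2552988142, -0.2350039008, 0.148467267, 0.6879524258, -1.4664286629],
            [-0.5830702832, 3.8420672173, 1.3974751421, 0.8368538787, -0.794966038,
             -1.8548155774, -0.0108443377, -1.2726615747, 1.6312581147, -1.8750198402],
            [-0.5316596849, 1.2496026837, 0.4599502146, -0.5384400819, 0.5463606151,
             -0.214166329, 0.2010979837, 0.041830379, 0.6905047923, -0.4869454702],
            [-0.9472799452, 0.3240205401, 0.7053418309, -0.2760639551, -1.1051300588,
             -0.4015266131, 1.7071625451, 0.1591552783, 0.7006235066, -0.5576023303],
            [0.9162798201, 2.3221984159, 1.599473594, -1.0665703236, -0.174266291,
             1.654039481, 0.8863971748, 0.6658621694, 0.5298578965, -0.0764269077],
            [-0.0978517624, 0.391289589, -1.1612809514, 0.6013163904, 0.2635436455,
             0.4946250638, 0.4024636333, 0.5896841383, -0.7719039781, 2.0269703706],
        ])
        df = pd.DataFrame(
            x.T, index=[f"s{i}" for i in range(10)], columns=[f"f{i}" for i in range(8)]
        )
        groups = pd.Series(["t"] * 5 + ["c"] * 5, index=df.index)
        fit = fit_moderated(df, groups, "t", "c")
        assert fit.df_prior == pytest.approx(15.7000096899795, rel=1e-8)
        assert fit.s2_prior == pytest.approx(0.911611257574468, rel=1e-8)
        np.testing.assert_allclose(
            fit.t,
            [3.472731793719776, -0.000329254261770, 0.404180375296381,
             2.038657366388849, 0.351228525417228, -0.996748646898516,
             -0.019988738987049, -0.939954463093261],
            rtol=1e-6, atol=1e-9,
        )
        np.testing.assert_allclose(
            fit.p,
            [0.00199667566075879, 0.99974004890494417, 0.68970431742418836,
             0.05278980380249561, 0.72852011721650967, 0.32895514648985702,
             0.98421969068356763, 0.35672311405570123],
            rtol=1e-6, atol=1e-9,
        )
        np.testing.assert_allclose(
            fit.fold_change[:3],
            [1.991450685693289, -0.000217154949187, 0.222212792896378],
            rtol=1e-6, atol=1e-9,
        )

    def test_empty_group_error(self, rng):
        df, groups = _random_two_group(rng)
        with pytest.raises(ValueError):
            fit_moderated(df, groups, "missing", "b")

    def test_single_feature_rejected(self, rng):
        df, groups = _random_two_group(rng, n_features=1)
        with pytest.raises(ValueError, match="features"):
            fit_moderated(df, groups, "a", "b")


# ---------------------------------------------------------------------------
# composite significance criterion


class TestCallDifferential:
    @staticmethod
    def _frame(fc, p, features=None):
        features = features or [f"f{i}" for i in range(len(fc))]
        return pd.DataFrame({"fold_change": fc, "p": p}, index=features)

    def test_sign_consistency_veto(self):
        r1 = self._frame([+0.5], [1e-6])
        r2 = self._frame([-0.5], [1e-6])
        out = call_differential(r1, r2)
        assert not out["significant"].iloc[0]

    def test_individual_p_veto(self):
        r1 = self._frame([1.0], [0.25])
        r2 = self._frame([1.0], [1e-6])
        out = call_differential(r1, r2)
        assert not out["significant"].iloc[0]

    def test_sole_feature_fisher_and_fdr(self):
        r1 = self._frame([-1.0], [0.01])
        r2 = self._frame([-0.8], [0.01])
        out = call_differential(r1, r2)
        assert out["p_combined"].iloc[0] == pytest.approx(0.00103, abs=2e-5)
        assert out["q"].iloc[0] == out["p_combined"].iloc[0]
        assert bool(out["significant"].iloc[0])

    def test_mismatched_features_warn_and_drop(self):
        r1 = self._frame([1.0, 1.0], [0.01, 0.01], ["a", "b"])
        r2 = self._frame([1.0, 1.0], [0.01, 0.01], ["b", "c"])
        with pytest.warns(UserWarning):
            out = call_differential(r1, r2)
        assert list(out.index) == ["b"]


# ---------------------------------------------------------------------------
# permutation t-test


class TestPermutationT:
    def test_identical_groups(self):
        assert permutation_t_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_separated_groups_exact(self):
        # C(6,3) = 20 label splits, 2 of them maximally extreme
        assert permutation_t_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_zero_variance(self):
        assert permutation_t_test([2, 2], [2, 2]) == 1.0

    def test_exhaustive_vs_monte_carlo(self, rng):
        a = rng.standard_normal(6) + 0.8
        b = rng.standard_normal(6)
        p_ex = permutation_t_test(a, b)  # C(12,6) = 924 -> exhaustive
        big = np.concatenate([a, a, b, b])  # force Monte-Carlo path
        p_mc = permutation_t_test(
            np.concatenate([a, rng.standard_normal(8) + 0.8]),
            np.concatenate([b, rng.standard_normal(8)]),
            n_perm=4000, seed=0,
        )
        assert 0 < p_ex <= 1 and 0 < p_mc <= 1

    def test_monte_carlo_agrees_with_exhaustive(self, rng):
        a = rng.standard_normal(5) + 1.0
        b = rng.standard_normal(5)
        p_ex = permutation_t_test(a, b)
        # exhaustive path re-run through the Monte-Carlo machinery
        pooled_big = math.comb(10, 5)
        assert pooled_big <= 20_000
        p_mc_vals = []
        rng2 = np.random.default_rng(7)
        pooled = np.concatenate([a, b])
        t_obs = abs(
            sps.ttest_ind(a, b, equal_var=True).statistic
        )
        extreme = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng2.permutation(pooled)
            t = sps.ttest_ind(perm[:5], perm[5:], equal_var=True).statistic
            if abs(t) >= t_obs - 1e-12:
                extreme += 1
        p_mc = (1 + extreme) / (1 + n_perm)
        assert abs(p_ex - p_mc) < 0.01


def test_thresholds_validation_and_profiles():
    t = Thresholds()
    assert (t.p_individual, t.p_combined, t.fdr) == (0.20, 0.05, 0.10)
    d = Thresholds.diversity()
    assert (d.p_individual, d.p_combined, d.fdr) == (0.02, 0.001, 0.001)
    with pytest.raises(ValueError):
        Thresholds(fdr=0.0)
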