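"""k x 2 t-test arithmetic, permutation null, ARI closed testing, FCR bands."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

import trialdecode as td
from trialdecode.crossval import make_split_plan
from trialdecode.inference import (
    TestCurve as PCurve,
    _permute_labels,
    ari_discoveries,
    fcr_adjusted_cis,
    find_clusters_fdp,
    hommel_h,
    kx2_cv_ttest,
    permutation_test,
)


class TestKx2TTest:
    def test_all_chance_gives_zero(self):
        t, p, df = kx2_cv_ttest(np.full((10, 2), 0.5))
        assert t == 0.0 and p == 0.5 and df == 10

    def test_hand_arithmetic(self):
        """d = [[0.1, 0.06], [0.02, 0.1]]: s1^2=0.0008, s2^2=0.0032,
        SE = sqrt(0.002), mean numerator 0.07."""
        auc = 0.5 + np.array([[0.1, 0.06], [0.02, 0.1]])
        t, p, df = kx2_cv_ttest(auc)
        assert t == pytest.approx(0.07 / np.sqrt(0.002), abs=1e-10)
        assert df == 2
        assert p == pytest.approx(stats.t.sf(0.07 / np.sqrt(0.002), 2), abs=1e-12)

    def test_first_numerator_variant(self):
        auc = 0.5 + np.array([[0.1, 0.06], [0.02, 0.1]])
        t, _, _ = kx2_cv_ttest(auc, numerator="first")
        assert t == pytest.approx(0.1 / np.sqrt(0.002), abs=1e-10)

    def test_p_monotone_decreasing_in_t(self, rng):
        results = []
        for _ in range(30):
            auc = 0.5 + rng.normal(0, 0.05, size=(10, 2))
            results.append(kx2_cv_ttest(auc)[:2])
        results.sort()
        ps = [p for _, p in results]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_se_nonzero_numerator(self):
        auc = np.full((5, 2), 0.7)
        with pytest.warns(RuntimeWarning, match="zero"):
            t, p, _ = kx2_cv_ttest(auc)
        assert p == 0.0 and np.isinf(t)

    def test_missing_replication_dropped_pairwise(self):
        auc = 0.5 + np.array([[0.1, 0.06], [np.nan, 0.2], [0.02, 0.1]])
        t, p, df = kx2_cv_ttest(auc)
        t2, p2, df2 = kx2_cv_ttest(0.5 + np.array([[0.1, 0.06], [0.02, 0.1]]))
        assert (t, p, df) == (t2, p2, df2)

    def test_too_many_missing_rejected(self):
        auc = np.full((4, 2), np.nan)
        auc[0] = 0.6
        with pytest.raises(ValueError, match="missing"):
            kx2_cv_ttest(auc)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            kx2_cv_ttest(np.array([[0.6, 0.5]]))


class TestPermutation:
    @pytest.fixture(scope="class")
    def strong_signal(self):
        cfg = td.SimConfig(
            n_subjects=4, n_stimuli=24, n_channels=4, sfreq=5.0, noise_scale=2.0,
            patterns=(td.PatternSpec(np.ones(4), (0.2, 0.6), 8.0, "choice"),), seed=2)
        return td.simulate_dataset(cfg)

    def test_extremes_of_p(self, strong_signal):
        epochs, trials = strong_signal
        plan = make_split_plan(sorted(trials.stimulus_id.unique()), k=2, seed=0)
        idx = np.array([0, 3])  # pre-stimulus and inside the window
        test = permutation_test(epochs, trials, "choice", plan, n_perm=99, seed=1,
                                time_indices=idx)
        assert test.p[1] == pytest.approx(1 / 100)  # observed beats all permutations
        assert test.p[0] > 0.2  # pre-stimulus: nothing to find
        assert np.all(test.p >= 1 / 100)

    def test_market_permutation_preserves_stimulus_constancy(self, tiny_dataset):
        _, _, trials = tiny_dataset
        rng = np.random.default_rng(0)
        perm = _permute_labels(trials, "market", rng)
        assert (perm.groupby("stimulus_id")["market"].nunique() == 1).all()
        assert perm["market"].sum() == trials["market"].sum()

    def test_choice_permutation_stays_within_subject(self, tiny_dataset):
        _, _, trials = tiny_dataset
        rng = np.random.default_rng(0)
        perm = _permute_labels(trials, "choice", rng)
        for sub, g in trials.groupby("subject_id"):
            assert perm[perm.subject_id == sub]["choice"].sum() == g["choice"].sum()

    def test_null_p_values_roughly_uniform(self):
        """Permutation p-values are valid by construction; check the empirical
        CDF over independent null runs is consistent with uniformity."""
        ps = []
        for seed in range(25):
            cfg = td.SimConfig(n_subjects=4, n_stimuli=20, n_channels=3, sfreq=5.0,
                               seed=seed)
            epochs, trials = td.simulate_dataset(cfg)
            plan = make_split_plan(sorted(trials.stimulus_id.unique()), k=2, seed=seed)
            test = permutation_test(epochs, trials, "choice", plan, n_perm=99,
                                    seed=seed, time_indices=np.array([3]))
            ps.append(test.p[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_n_perm_floor(self, tiny_dataset):
        _, epochs, trials = tiny_dataset
        plan = make_split_plan(sorted(trials.stimulus_id.unique()), k=2, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(epochs, trials, "choice", plan, n_perm=10)


# -- exhaustive closed-testing oracle ---------------------------------------


def _simes_rejects(p_sub, alpha):
    p_sub = np.sort(p_sub)
    m = len(p_sub)
    return np.any(p_sub <= (np.arange(1, m + 1) * alpha / m))


def _closed_testing(p, alpha):
    """For every subset I, whether its intersection hypothesis is rejected by
    the closed procedure (all supersets rejected by the local Simes test)."""
    m = len(p)
    idx = np.arange(m)
    local_not = [frozenset(J) for r in range(m + 1)
                 for J in itertools.combinations(idx, r)
                 if r > 0 and not _simes_rejects(p[list(J)], alpha)]
    def closed_rejected(I):
        return not any(I <= J for J in local_not)
    return closed_rejected


class TestARIOracle:
    def test_hommel_trivial_cases(self):
        assert hommel_h(np.array([1.0, 1.0, 1.0]), 0.05) == 3
        assert hommel_h(np.full(5, 1e-10), 0.05) == 0

    def test_hommel_matches_largest_unrejected_simes_subset(self, rng):
        for _ in range(40):
            m = int(rng.integers(3, 9))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            h = hommel_h(p, 0.05)
            brute = max((len(J) for r in range(m + 1)
                         for J in itertools.combinations(range(m), r)
                         if r == 0 or not _simes_rejects(p[list(J)], 0.05)),
                        default=0)
            assert h == brute

    def test_discoveries_match_closed_testing(self, rng):
        for _ in range(15):
            m = int(rng.integers(4, 9))
            p = np.concatenate([rng.random(m // 2) * 0.02, rng.random(m - m // 2)])
            rng.shuffle(p)
            h = hommel_h(p, 0.05)
            rejected = _closed_testing(p, 0.05)
            for r in range(1, m + 1):
                for S in itertools.combinations(range(m), r):
                    S_set = frozenset(S)
                    brute = len(S) - max(
                        (len(I) for rr in range(len(S) + 1)
                         for I in itertools.combinations(S, rr)
                         if rr == 0 or not rejected(frozenset(I))),
                        default=0)
                    assert ari_discoveries(p, np.array(S), h, 0.05) == brute

    def test_hommel_monotone_in_p(self, rng):
        p = rng.random(10)
        h = hommel_h(p, 0.05)
        p2 = p.copy()
        p2[int(rng.integers(10))] *= 0.1
        assert hommel_h(p2, 0.05) <= h

    def test_discoveries_monotone_in_subset(self, rng):
        p = rng.random(12) ** 2
        h = hommel_h(p, 0.05)
        S = np.array([1, 3, 5, 7])
        d_small = ari_discoveries(p, S, h, 0.05)
        d_big = ari_discoveries(p, np.r_[S, 0, 9], h, 0.05)
        assert d_big >= d_small
        assert d_small <= len(S)

    def test_h_zero_convention(self):
        assert ari_discoveries(np.full(4, 1e-9), np.arange(3), 0, 0.05) == 3

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            hommel_h(np.array([]), 0.05)
        with pytest.raises(ValueError):
            ari_discoveries(np.array([0.5]), np.array([]), 1, 0.05)


class TestFindClusters:
    def test_flat_null_curve_gives_no_cluster(self):
        test = PCurve(t=np.zeros(40), p=np.full(40, 0.5), df=10, method="kx2")
        cs = find_clusters_fdp(test)
        assert cs.clusters == []

    def test_single_strong_run_recovered_exactly(self, rng):
        p = 0.3 + 0.4 * rng.random(100)
        p[40:50] = 1e-8
        test = PCurve(t=-stats.norm.ppf(p), p=p, df=10, method="kx2")
        cs = find_clusters_fdp(test)
        assert cs.clusters == [(40, 49)]
        assert cs.tdp_lower[0] == 1.0

    def test_reported_clusters_meet_fdp_bound(self, rng):
        for _ in range(20):
            p = rng.random(60) ** rng.uniform(1, 6)
            test = PCurve(t=np.zeros(60), p=p, df=10, method="kx2")
            cs = find_clusters_fdp(test, target_fdp=0.05)
            for (a, b), tdp in zip(cs.clusters, cs.tdp_lower):
                assert tdp >= 0.95
                assert a <= b
            starts = [a for a, _ in cs.clusters]
            assert starts == sorted(starts)

    def test_tightening_fdp_never_widens_clusters(self, rng):
        p = rng.random(80) ** 4
        test = PCurve(t=np.zeros(80), p=p, df=10, method="kx2")
        loose = find_clusters_fdp(test, target_fdp=0.2)
        tight = find_clusters_fdp(test, target_fdp=0.02)
        covered_loose = set()
        for a, b in loose.clusters:
            covered_loose |= set(range(a, b + 1))
        covered_tight = set()
        for a, b in tight.clusters:
            covered_tight |= set(range(a, b + 1))
        assert covered_tight <= covered_loose


class TestFCR:
    def test_select_all_equals_unadjusted(self, rng):
        auc = 0.5 + rng.normal(0, 0.03, size=(10, 2, 8))
        all_sel = fcr_adjusted_cis(auc, np.arange(8), alpha=0.05)
        none_sel = fcr_adjusted_cis(auc, np.array([], dtype=int), alpha=0.05)
        assert np.allclose(all_sel["ci_lo"], none_sel["ci_lo"])
        assert np.allclose(all_sel["level"], 0.95)

    def test_adjusted_level_closed_form(self, rng):
        auc = 0.5 + rng.normal(0, 0.03, size=(10, 2, 100))
        sel = np.arange(5)
        ci = fcr_adjusted_cis(auc, sel, alpha=0.05)
        assert np.allclose(ci.loc[ci.selected, "level"], 1 - 5 * 0.05 / 100)
        t = 3
        d = auc[:, :, t] - 0.5
        se = np.sqrt((((d - d.mean(axis=1, keepdims=True)) ** 2).sum()) / 10)
        q = stats.t.ppf(1 - (1 - 0.9975) / 2, df=10)
        expected_hi = 0.5 + d.mean() + q * se
        assert ci.loc[t, "ci_hi"] == pytest.approx(expected_hi, abs=1e-12)

    def test_selected_intervals_are_wider(self, rng):
        auc = 0.5 + rng.normal(0, 0.03, size=(10, 2, 50))
        ci = fcr_adjusted_cis(auc, np.array([7]), alpha=0.05)
        width = ci["ci_hi"] - ci["ci_lo"]
        d = auc[:, :, 7] - 0.5
        se = np.sqrt((((d - d.mean(axis=1, keepdims=True)) ** 2).sum()) / 10)
        unadj = 2 * stats.t.ppf(0.975, 10) * se
        assert width[7] > unadj
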