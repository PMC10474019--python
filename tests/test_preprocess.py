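"""Baseline correction, EOG-IC flagging, p2p threshold CV, resampling."""

import math

import numpy as np
import pytest

import trialdecode as td
from trialdecode.preprocess import (
    ICScores,
    baseline_correct,
    drop_trials,
    flag_eog_components,
    peak_to_peak,
    resample_to,
    select_p2p_threshold,
    zscore_correlations,
)
from trialdecode.simulate import EpochSet


def _epochs(data, sfreq=10.0, t_start=-0.2):
    data = np.asarray(data, dtype=float)
    n_t = data.shape[2]
    names = [f"E{i + 1}" for i in range(data.shape[1])]
    return EpochSet(
        subject_id="sub-01", data=data, ch_names=names,
        ch_groups=td.simulate.default_channel_groups(names),
        times=t_start + np.arange(n_t) / sfreq, sfreq=sfreq,
    )


class TestBaselineCorrect:
    def test_constant_trial_whole_epoch_window(self):
        ep = _epochs(np.full((2, 3, 5), 5.0))
        out = baseline_correct(ep, (ep.times[0], ep.times[-1]))
        assert np.allclose(out.data, 0.0)

    def test_shifts_post_stimulus_by_baseline_mean(self):
        data = np.zeros((1, 1, 10))
        data[0, 0, :2] = 2.0  # pre-stimulus samples
        data[0, 0, 2:] = 7.0
        ep = _epochs(data)
        out = baseline_correct(ep, (-0.2, -0.1))
        assert out.data[0, 0, 2:].mean() == pytest.approx(5.0)

    def test_baseline_mean_is_zero_and_idempotent(self, rng):
        ep = _epochs(rng.normal(size=(7, 4, 20)))
        out = baseline_correct(ep)
        mask = (out.times >= -0.2) & (out.times <= 0.0)
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-10
        out2 = baseline_correct(out)
        assert np.allclose(out.data, out2.data)

    def test_empty_window_rejected(self, rng):
        ep = _epochs(rng.normal(size=(2, 2, 10)))
        with pytest.raises(ValueError, match="no samples"):
            baseline_correct(ep, (5.0, 6.0))


class TestFlagEOG:
    def test_component_equal_to_eog_is_flagged(self, rng):
        n = 2000
        eog = rng.normal(size=(2, n))
        ics = rng.normal(size=(15, n))
        ics[4] = eog[0]
        scores = ICScores(ic_sources=ics, eog_channels=eog)
        assert 4 in flag_eog_components(scores)

    def test_identical_correlations_give_empty_set(self):
        corr = np.full((6, 2), 0.4)
        assert flag_eog_components(corr) == set()

    def test_hand_zscore_example(self):
        """r = (0.9, 0.0, 0.1, -0.05, 0.05): only the first exceeds z=1.96."""
        corr = np.array([[0.9], [0.0], [0.1], [-0.05], [0.05]])
        z = zscore_correlations(corr)
        assert z[0, 0] == pytest.approx((0.9 - 0.2) / np.sqrt(0.125), abs=1e-12)
        assert flag_eog_components(np.column_stack([corr, np.zeros(5)])) == {0}

    def test_invariant_to_scaling_and_joint_sign_flip(self, rng):
        n = 500
        eog = rng.normal(size=(2, n))
        ics = rng.normal(size=(8, n))
        ics[2] = 0.7 * eog[1] + 0.3 * rng.normal(size=n)
        base = flag_eog_components(ICScores(ics, eog))
        scaled = ics * rng.uniform(0.1, 10.0, size=(8, 1))
        assert flag_eog_components(ICScores(scaled, eog)) == base
        flipped = ics.copy()
        flipped[2] = -flipped[2]
        eog_flipped = eog.copy()
        eog_flipped[1] = -eog_flipped[1]
        assert flag_eog_components(ICScores(flipped, eog_flipped)) == base

    def test_zero_variance_component_warns_and_counts_zero(self, rng):
        ics = rng.normal(size=(5, 100))
        ics[1] = 3.0
        eog = rng.normal(size=(2, 100))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            scores = ICScores(ics, eog)
        assert np.all(scores.correlations[1] == 0)

    def test_too_few_components_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            flag_eog_components(np.array([[0.5, 0.1], [0.2, 0.3]]))


class TestP2PThreshold:
    def test_spike_trial_dropped(self, rng):
        data = rng.normal(0, 1.0, size=(30, 4, 20))
        data[13, 2, 10] = 500.0
        ep = _epochs(data)
        report = select_p2p_threshold(ep, candidates=np.array([50.0, 1000.0]), seed=0)
        assert report.threshold == 50.0
        assert report.dropped_trial_indices == {13}
        assert report.cv_error_by_candidate[50.0] < report.cv_error_by_candidate[1000.0]

    def test_tie_breaks_to_smallest_harmless_threshold(self):
        ep = _epochs(np.tile(np.linspace(0, 4, 10), (6, 3, 1)))
        p2p = peak_to_peak(ep.data)[0]
        report = select_p2p_threshold(ep, candidates=np.array([p2p / 2, p2p, 2 * p2p]),
                                      seed=0)
        assert report.threshold == pytest.approx(p2p)
        assert report.dropped_trial_indices == set()

    def test_matches_brute_force_oracle(self, rng):
        """Independent naive recomputation of every candidate's CV error."""
        data = rng.normal(size=(17, 3, 8)) * rng.uniform(0.5, 4.0, size=(17, 1, 1))
        ep = _epochs(data)
        candidates = np.percentile(peak_to_peak(data), [40, 60, 80, 100])
        seed = 5
        report = select_p2p_threshold(ep, candidates=candidates, k_folds=5, seed=seed)

        p2p = (data.max(axis=2) - data.min(axis=2)).max(axis=1)
        order = np.random.default_rng(seed).permutation(17)
        folds = np.array_split(order, 5)
        for tau in candidates:
            errs = []
            for fold in folds:
                train = [i for i in range(17) if i not in fold and p2p[i] <= tau]
                if not train:
                    errs.append(math.inf)
                    continue
                tm = data[train].mean(axis=0)
                vm = data[fold].mean(axis=0)
                errs.append(np.mean((tm - vm) ** 2))
            assert report.cv_error_by_candidate[float(tau)] == pytest.approx(
                np.mean(errs), abs=1e-12)

    def test_drop_rule_matches_threshold(self, rng):
        data = rng.normal(size=(20, 2, 10)) * rng.uniform(0.2, 5.0, size=(20, 1, 1))
        ep = _epochs(data)
        report = select_p2p_threshold(ep, seed=1)
        p2p = peak_to_peak(data)
        assert report.dropped_trial_indices == set(np.flatnonzero(p2p > report.threshold))
        assert report.threshold in report.cv_error_by_candidate
        kept = drop_trials(ep, report.dropped_trial_indices)
        assert kept.n_trials == 20 - len(report.dropped_trial_indices)

    def test_too_few_trials_rejected(self, rng):
        ep = _epochs(rng.normal(size=(3, 2, 5)))
        with pytest.raises(ValueError, match="at least"):
            select_p2p_threshold(ep, k_folds=5)


class TestResample:
    def test_1000_to_100(self, rng):
        ep = _epochs(rng.normal(size=(2, 3, 1000)), sfreq=1000.0, t_start=-0.1)
        out = resample_to(ep, 100.0)
        assert out.data.shape == (2, 3, 100)
        assert out.sfreq == 100.0
        assert out.times[0] == pytest.approx(ep.times[0])

    def test_identity(self, rng):
        ep = _epochs(rng.normal(size=(2, 2, 50)))
        out = resample_to(ep, ep.sfreq)
        assert np.array_equal(out.data, ep.data)

    def test_sinusoid_preserved(self):
        sfreq = 1000.0
        t = np.arange(1000) / sfreq
        sig = np.sin(2 * np.pi * 5 * t)
        ep = _epochs(sig[None, None, :] - 0.0, sfreq=sfreq, t_start=-0.1)
        out = resample_to(ep, 100.0)
        t_new = ep.times[0] + np.arange(100) / 100.0
        expected = np.sin(2 * np.pi * 5 * (t_new - ep.times[0]))
        interior = slice(10, 90)
        err = np.abs(out.data[0, 0, interior] - expected[interior]).max()
        assert err < 0.01

    def test_upsampling_rejected(self, rng):
        ep = _epochs(rng.normal(size=(1, 1, 20)))
        with pytest.raises(ValueError, match="upsampling"):
            resample_to(ep, ep.sfreq * 2)
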