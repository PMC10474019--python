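"""Preprocessing computations for epoched EEG.

Only the analysis-relevant steps are implemented here: baseline correction,
the z-scored EOG/IC correlation flagging rule, cross-validated peak-to-peak
rejection-threshold selection, and resampling glue.  Upstream standardised
cleaning (PREP referencing, 0.3-50 Hz filtering, the ICA decomposition
itself, bipolar EOG derivation) is delegated to existing tools; this module
consumes their outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .simulate import EpochSet


def baseline_correct(epochs: EpochSet, window: tuple[float, float] = (-0.2, 0.0)) -> EpochSet:
    """Subtract the per-(trial, channel) mean voltage over ``window``.

    The default window is the 200 ms preceding stimulus onset.  Idempotent:
    correcting twice equals correcting once.
    """
    t0, t1 = window
    mask = (epochs.times >= t0 - 1e-12) & (epochs.times <= t1 + 1e-12)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


@dataclass
class ICScores:
    """Independent-component sources paired with bipolar EOG traces.

    Correlations and z-scores are computed lazily on construction: one
    Pearson r per (component, EOG channel), z-scored across components
    separately per EOG channel.
    """

    ic_sources: np.ndarray  # components x samples
    eog_channels: np.ndarray  # 2 x samples (bipolar pairs)
    correlations: np.ndarray = field(init=False)
    zscores: np.ndarray = field(init=False)

    def __post_init__(self):
        self.ic_sources = np.atleast_2d(np.asarray(self.ic_sources, dtype=float))
        self.eog_channels = np.atleast_2d(np.asarray(self.eog_channels, dtype=float))
        if self.ic_sources.shape[1] != self.eog_channels.shape[1]:
            raise ValueError("IC sources and EOG channels must share the sample axis")
        self.correlations = _safe_correlations(self.ic_sources, self.eog_channels)
        self.zscores = zscore_correlations(self.correlations)

    @property
    def n_components(self) -> int:
        return self.ic_sources.shape[0]


def _safe_correlations(ics: np.ndarray, eog: np.ndarray) -> np.ndarray:
    ic_sd = ics.std(axis=1)
    eog_sd = eog.std(axis=1)
    if (ic_sd == 0).any() or (eog_sd == 0).any():
        warnings.warn(
            "zero-variance IC source or EOG trace; its correlation is treated as 0",
            RuntimeWarning,
        )
    icc = ics - ics.mean(axis=1, keepdims=True)
    eogc = eog - eog.mean(axis=1, keepdims=True)
    denom = np.outer(ic_sd, eog_sd) * ics.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (icc @ eogc.T) / denom
    return np.where(np.isfinite(r), r, 0.0)


def zscore_correlations(correlations: np.ndarray) -> np.ndarray:
    """Z-score signed correlations across components, per EOG channel.

    Population standard deviation (ddof=0); a zero-spread column yields
    all-zero z-scores.
    """
    r = np.atleast_2d(np.asarray(correlations, dtype=float))
    mean = r.mean(axis=0, keepdims=True)
    sd = r.std(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (r - mean) / sd
    return np.where(sd > 0, z, 0.0)


def flag_eog_components(ic: ICScores | np.ndarray, z_crit: float = 1.96) -> set[int]:
    """Indices of components whose z-scored EOG correlation exceeds +-z_crit.

    A component is flagged if |z| > z_crit against *either* eye channel; the
    z-scores are on signed correlations, so a strongly anti-correlated
    component is flagged too.  Accepts a prepared :class:`ICScores` or a raw
    components x EOG-channels correlation matrix.
    """
    z = ic.zscores if isinstance(ic, ICScores) else zscore_correlations(ic)
    if z.shape[0] < 3:
        raise ValueError("need at least 3 components for meaningful z-scores")
    return set(np.flatnonzero((np.abs(z) > z_crit).any(axis=1)).tolist())


@dataclass
class RejectionReport:
    """Outcome of peak-to-peak threshold selection."""

    threshold: float  # uV peak-to-peak
    dropped_trial_indices: set[int]
    cv_error_by_candidate: dict[float, float]


def peak_to_peak(data: np.ndarray) -> np.ndarray:
    """Per-trial max over channels of (max - min over time), in uV."""
    return (data.max(axis=2) - data.min(axis=2)).max(axis=1)


def default_candidate_grid(p2p: np.ndarray, n_candidates: int = 40) -> np.ndarray:
    """Log-spaced thresholds between the median and the maximum observed p2p."""
    lo = np.percentile(p2p, 50)
    hi = p2p.max()
    if lo <= 0:
        lo = max(hi * 1e-6, 1e-12)
    if hi <= lo:
        return np.array([hi])
    return np.geomspace(lo, hi, n_candidates)


def select_p2p_threshold(
    epochs: EpochSet,
    candidates: np.ndarray | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> RejectionReport:
    """Pick the rejection threshold by five-fold cross-validation.

    For each candidate threshold tau, trials are split into ``k_folds`` folds
    (label-blind, seeded); per fold the error is the mean squared difference
    between the mean of surviving (p2p <= tau) training trials and the mean
    of all validation trials.  The tau minimising the fold-averaged error
    wins; ties break toward the smallest tau.  A candidate that rejects every
    training trial in some fold scores +inf.
    """
    n_trials = epochs.n_trials
    if n_trials < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} trials, got {n_trials}")
    p2p = peak_to_peak(epochs.data)
    if candidates is None:
        candidates = default_candidate_grid(p2p)
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size == 0:
        raise ValueError("candidate grid is empty")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    folds = np.array_split(order, k_folds)

    cv_error: dict[float, float] = {}
    for tau in candidates:
        errors = []
        for fold in folds:
            val_mask = np.zeros(n_trials, dtype=bool)
            val_mask[fold] = True
            train_keep = (~val_mask) & (p2p <= tau)
            if not train_keep.any():
                errors.append(math.inf)
                continue
            train_mean = epochs.data[train_keep].mean(axis=0)
            val_mean = epochs.data[val_mask].mean(axis=0)
            errors.append(float(np.mean((train_mean - val_mean) ** 2)))
        cv_error[float(tau)] = float(np.mean(errors))

    # ties break toward the smallest threshold: candidates are sorted ascending
    best = min(cv_error, key=lambda tau: (cv_error[tau], tau))
    dropped = set(np.flatnonzero(p2p > best).tolist())
    return RejectionReport(threshold=best, dropped_trial_indices=dropped,
                           cv_error_by_candidate=cv_error)


def drop_trials(epochs: EpochSet, indices: set[int]) -> EpochSet:
    """Remove the given trial indices (e.g. a RejectionReport's drops)."""
    keep = np.setdiff1d(np.arange(epochs.n_trials), np.asarray(sorted(indices), dtype=int))
    out = epochs.copy()
    out.data = out.data[keep]
    return out


def resample_to(epochs: EpochSet, target_sfreq: float) -> EpochSet:
    """Downsample the epoch to ``target_sfreq`` (polyphase, anti-aliased).

    Upsampling is rejected: the pipeline's contract is that the signal was
    already low-pass filtered below target/2 upstream, which cannot hold for
    an upsampling request.
    """
    current = epochs.sfreq
    if target_sfreq > current + 1e-9:
        raise ValueError(f"upsampling {current} -> {target_sfreq} Hz not supported")
    if abs(target_sfreq - current) < 1e-9:
        return epochs.copy()
    from fractions import Fraction

    frac = Fraction(target_sfreq / current).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    n_in = epochs.data.shape[2]
    data = sp_signal.resample_poly(epochs.data, up, down, axis=2)
    n_out = int(round(n_in * target_sfreq / current))
    data = data[:, :, :n_out]
    out = epochs.copy()
    out.data = data
    out.sfreq = target_sfreq
    out.times = epochs.times[0] + np.arange(n_out) / target_sfreq
    return out
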