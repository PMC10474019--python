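"""Stimulus-disjoint k x 2 cross-validation and ROC-AUC scoring.

Generalisation is assessed over *novel stimuli*: each of k replications
randomly partitions the stimulus set into two halves, the classifier is
trained on all trials (all subjects) of one half's stimuli and scored on the
other half, in both orientations.  Because stimuli never overlap between
halves, a market-level label (constant per stimulus) cannot leak from train
to test.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .gee import fit_gee_logistic, predict_scores
from .simulate import EpochSet, validate_trial_table


@dataclass(frozen=True)
class SplitPlan:
    """k replications of a random half/half partition of the stimulus set."""

    halves: tuple[tuple[frozenset, frozenset], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.halves)

    def __post_init__(self):
        for a, b in self.halves:
            if a & b:
                raise ValueError("halves of a replication must be disjoint")

    def digest(self) -> str:
        """Stable content hash, used to assert two analyses share the plan."""
        payload = json.dumps(
            [[sorted(a), sorted(b)] for a, b in self.halves], sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def make_split_plan(stimulus_ids, k: int = 10, seed: int = 0) -> SplitPlan:
    """k independent random partitions into halves of size floor/ceil(n/2)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = sorted(stimulus_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 stimuli to split")
    rng = np.random.default_rng(seed)
    halves = []
    half = len(ids) // 2
    for _ in range(k):
        perm = rng.permutation(len(ids))
        a = frozenset(ids[i] for i in perm[:half])
        b = frozenset(ids[i] for i in perm[half:])
        halves.append((a, b))
    return SplitPlan(halves=tuple(halves), seed=seed)


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals U / (n1 * n0) with midrank handling of ties: the probability that
    a random positive is scored above a random negative, ties counting 1/2.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y).ravel()
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class StackedData:
    """All subjects' trials stacked into one design: n_obs x channels x times."""

    X: np.ndarray
    y: np.ndarray
    clusters: np.ndarray  # subject id per observation
    stimulus: np.ndarray  # stimulus id per observation
    times: np.ndarray
    ch_names: list[str]
    ch_groups: dict[str, str]


def stack_trials(epochs: list[EpochSet], trials: pd.DataFrame, target: str) -> StackedData:
    """Align the trial table with the epoch tensors and stack across subjects."""
    if target not in ("choice", "market"):
        raise ValueError(f"target must be 'choice' or 'market', got {target!r}")
    validate_trial_table(trials)
    ref = epochs[0]
    blocks, ys, subs, stims = [], [], [], []
    for ep in epochs:
        if ep.ch_names != ref.ch_names or not np.allclose(ep.times, ref.times):
            raise ValueError("all subjects must share channels and time grid")
        rows = trials[trials["subject_id"] == ep.subject_id].sort_values("trial_index")
        if len(rows) != ep.n_trials:
            raise ValueError(
                f"trial table has {len(rows)} rows for {ep.subject_id}, "
                f"but the EpochSet has {ep.n_trials} trials"
            )
        blocks.append(ep.data)
        ys.append(rows[target].to_numpy())
        subs.append(np.repeat(ep.subject_id, ep.n_trials))
        stims.append(rows["stimulus_id"].to_numpy())
    return StackedData(
        X=np.concatenate(blocks, axis=0),
        y=np.concatenate(ys).astype(int),
        clusters=np.concatenate(subs),
        stimulus=np.concatenate(stims),
        times=ref.times,
        ch_names=list(ref.ch_names),
        ch_groups=dict(ref.ch_groups),
    )


@dataclass
class DecodingCurve:
    """Out-of-sample AUC per (replication, orientation, timepoint)."""

    auc: np.ndarray  # k x 2 x T, NaN where a fold could not be scored
    times: np.ndarray
    target: str
    split_plan: SplitPlan

    def mean_auc(self) -> np.ndarray:
        """Grand-mean AUC over splits, per timepoint (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.auc, axis=(0, 1))


def sliding_decode(
    epochs: list[EpochSet],
    trials: pd.DataFrame,
    target: str,
    plan: SplitPlan,
    scaling: str = "none",
    time_indices: np.ndarray | None = None,
    working_corr: str = "independence",
    ridge: float = 0.0,
    return_fits: bool = False,
):
    """Run the per-timepoint GEE decoder over the full split plan.

    For every timepoint and every (replication, orientation): fit on all
    trials of the training-half stimuli using the channel voltages at that
    timepoint, then score the held-out half's trials by AUC.  Scaling
    statistics (``scaling="train_zscore"``) come from training trials only.
    A test half missing a class records NaN with a warning.
    """
    if scaling not in ("none", "train_zscore"):
        raise ValueError(f"scaling must be 'none' or 'train_zscore', got {scaling!r}")
    data = stack_trials(epochs, trials, target)
    present = set(np.unique(data.stimulus))
    covered = set().union(*[a | b for a, b in plan.halves])
    if not present <= covered:
        raise ValueError("split plan does not cover all stimuli present in the data")

    t_idx = (np.arange(len(data.times)) if time_indices is None
             else np.asarray(time_indices, dtype=int))
    k = plan.k
    auc = np.full((k, 2, len(t_idx)), np.nan)
    fits = [[[None] * len(t_idx) for _ in range(2)] for _ in range(k)] if return_fits else None
    n_missing = 0

    for i, (half_a, half_b) in enumerate(plan.halves):
        if half_a & half_b:
            raise AssertionError("leakage: split halves intersect")
        in_a = np.isin(data.stimulus, sorted(half_a))
        in_b = np.isin(data.stimulus, sorted(half_b))
        for j, (train_mask, test_mask) in enumerate([(in_a, in_b), (in_b, in_a)]):
            y_tr, y_te = data.y[train_mask], data.y[test_mask]
            if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
                n_missing += len(t_idx)
                continue
            cl_tr = data.clusters[train_mask]
            for ti, t in enumerate(t_idx):
                X_tr = data.X[train_mask, :, t]
                X_te = data.X[test_mask, :, t]
                if scaling == "train_zscore":
                    mu = X_tr.mean(axis=0)
                    sd = X_tr.std(axis=0)
                    sd[sd == 0] = 1.0
                    X_tr = (X_tr - mu) / sd
                    X_te = (X_te - mu) / sd
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # separation warnings handled via flag
                    fit = fit_gee_logistic(X_tr, y_tr, cl_tr,
                                           working_corr=working_corr, ridge=ridge)
                auc[i, j, ti] = roc_auc(predict_scores(fit, X_te), y_te)
                if return_fits:
                    fits[i][j][ti] = fit

    if n_missing:
        warnings.warn(
            f"{n_missing} fold/timepoint AUCs missing (a test half lacked a class)",
            RuntimeWarning,
        )
    curve = DecodingCurve(auc=auc, times=data.times[t_idx], target=target, split_plan=plan)
    return (curve, fits) if return_fits else curve


def fit_full_sample(
    epochs: list[EpochSet],
    trials: pd.DataFrame,
    target: str,
    time_indices: np.ndarray | None = None,
    working_corr: str = "independence",
    ridge: float = 0.0,
) -> list:
    """One GEE fit per timepoint on *all* trials (for interpretation)."""
    data = stack_trials(epochs, trials, target)
    t_idx = (np.arange(len(data.times)) if time_indices is None
             else np.asarray(time_indices, dtype=int))
    fits = []
    for t in t_idx:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits.append(fit_gee_logistic(data.X[:, :, t], data.y, data.clusters,
                                         working_corr=working_corr, ridge=ridge))
    return fits
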