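"""Calibrated inference on cross-validated decoding curves.

Implements the modified k x 2 cross-validated t-test (the variance formula
does not shrink with the number of splits, avoiding the optimistic bias of a
naive t-test over CV folds), a stimulus-level permutation alternative,
All-Resolutions Inference (closed testing with Simes local tests) for
temporal clusters with true-discovery-proportion lower bounds, and
false-coverage-rate adjusted confidence bands for selected timepoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossval import DecodingCurve, SplitPlan, sliding_decode
from .simulate import validate_trial_table


# ---------------------------------------------------------------------------
# k x 2 cross-validated t-test


def kx2_cv_ttest(
    auc: np.ndarray,
    chance: float = 0.5,
    numerator: str = "mean",
    df: int | None = None,
    max_missing_frac: float = 0.5,
) -> tuple[float, float, int]:
    """One-sided test of mean CV AUC against chance.

    ``auc`` is k x 2 (replications x orientations).  With differences
    d_i^(j) = auc[i, j] - chance, the per-replication variance is
    s_i^2 = (d_i^(1) - dbar_i)^2 + (d_i^(2) - dbar_i)^2 and the standard
    error sqrt(sum_i s_i^2 / k) — independent of how many replications are
    averaged, unlike a naive t-test over folds.  The numerator is the mean of
    all 2k differences by default (``numerator="mean"``, df = k) or the first
    difference d_1^(1) (``numerator="first"``, the classic variant).
    Replications with a missing orientation are dropped pairwise.
    """
    auc = np.asarray(auc, dtype=float)
    if auc.ndim != 2 or auc.shape[1] != 2:
        raise ValueError("auc must be k x 2")
    if auc.shape[0] < 2:
        raise ValueError("need k >= 2 replications")
    if numerator not in ("mean", "first"):
        raise ValueError("numerator must be 'mean' or 'first'")
    keep = ~np.isnan(auc).any(axis=1)
    if keep.mean() < 1 - max_missing_frac:
        raise ValueError(
            f"{(~keep).sum()} of {len(keep)} replications missing exceeds "
            f"max_missing_frac={max_missing_frac}"
        )
    d = auc[keep] - chance
    k = d.shape[0]
    if k < 2:
        raise ValueError("fewer than 2 complete replications")
    dbar = d.mean(axis=1, keepdims=True)
    s2 = ((d - dbar) ** 2).sum(axis=1)
    se = np.sqrt(s2.sum() / k)
    num = d.mean() if numerator == "mean" else d[0, 0]
    dof = k if df is None else df
    if se == 0:
        if num == 0:
            return 0.0, 0.5, dof
        warnings.warn("zero k x 2 standard error with nonzero numerator; p set to 0",
                      RuntimeWarning)
        return float(np.sign(num) * np.inf), 0.0 if num > 0 else 1.0, dof
    t = float(num / se)
    p = float(stats.t.sf(t, dof))
    return t, p, dof


@dataclass
class TestCurve:
    """Per-timepoint test statistics and one-sided p-values."""

    t: np.ndarray
    p: np.ndarray
    df: int
    method: str  # "kx2" or "permutation"
    times: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != self.p.shape:
            raise ValueError("t and p must have the same shape")


def kx2_test_curve(curve: DecodingCurve, chance: float = 0.5,
                   numerator: str = "mean", df: int | None = None) -> TestCurve:
    """Apply the k x 2 test at every timepoint of a decoding curve."""
    T = curve.auc.shape[2]
    ts = np.empty(T)
    ps = np.empty(T)
    dof = curve.auc.shape[0]
    for i in range(T):
        ts[i], ps[i], dof = kx2_cv_ttest(curve.auc[:, :, i], chance=chance,
                                         numerator=numerator, df=df)
    return TestCurve(t=ts, p=ps, df=dof, method="kx2", times=curve.times)


# ---------------------------------------------------------------------------
# Permutation alternative


def _permute_labels(trials: pd.DataFrame, target: str, rng: np.random.Generator) -> pd.DataFrame:
    """Permute labels under the null while preserving the design structure.

    Market labels are permuted across *stimuli* (remaining constant per
    stimulus across subjects); choice labels are permuted within each subject
    across that subject's trials.
    """
    out = trials.copy()
    if target == "market":
        stims = np.sort(trials["stimulus_id"].unique())
        labels = (trials.drop_duplicates("stimulus_id")
                  .set_index("stimulus_id")["market"].loc[stims].to_numpy())
        mapping = dict(zip(stims, labels[rng.permutation(len(stims))]))
        out["market"] = out["stimulus_id"].map(mapping)
    elif target == "choice":
        for sub, idx in trials.groupby("subject_id").groups.items():
            vals = out.loc[idx, "choice"].to_numpy()
            out.loc[idx, "choice"] = vals[rng.permutation(len(vals))]
    else:
        raise ValueError(f"target must be 'choice' or 'market', got {target!r}")
    validate_trial_table(out)
    return out


def permutation_test(
    epochs,
    trials: pd.DataFrame,
    target: str,
    plan: SplitPlan,
    n_perm: int = 199,
    seed: int = 0,
    time_indices: np.ndarray | None = None,
) -> TestCurve:
    """Permutation null for the mean CV AUC curve on a fixed split plan.

    p_t = (1 + #{permuted mean AUC_t >= observed_t}) / (n_perm + 1); never
    smaller than 1/(n_perm+1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a usable resolution")
    observed = sliding_decode(epochs, trials, target, plan,
                              time_indices=time_indices).mean_auc()
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_perm):
            perm_trials = _permute_labels(trials, target, rng)
            perm_auc = sliding_decode(epochs, perm_trials, target, plan,
                                      time_indices=time_indices).mean_auc()
            exceed += (perm_auc >= observed).astype(float)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return TestCurve(t=observed - 0.5, p=p, df=n_perm, method="permutation")


# ---------------------------------------------------------------------------
# All-Resolutions Inference (closed testing with Simes local tests)


def hommel_h(p: np.ndarray, alpha: float = 0.05) -> int:
    """Hommel's h: the size of the largest subset whose intersection
    hypothesis survives all Simes tests in the closure.

    h = max{ i in 0..m : p_(m-i+j) > j*alpha/i for all j = 1..i } on the
    sorted p-values; h calibrates every ARI discovery bound.
    """
    p = np.sort(np.asarray(p, dtype=float))
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value vector")
    for i in range(m, 0, -1):
        j = np.arange(1, i + 1)
        if np.all(p[m - i + j - 1] > j * alpha / i):
            return i
    return 0


def ari_discoveries(p: np.ndarray, S: np.ndarray, h: int, alpha: float = 0.05) -> int:
    """Lower bound d(S) on the number of true discoveries inside subset S.

    With h = 0 every hypothesis is rejected, so d(S) = |S|; otherwise
    d(S) = max_u (1 - u + #{ i in S : h * p_i <= u * alpha }).  Simultaneous
    over all S at confidence 1 - alpha.
    """
    p = np.asarray(p, dtype=float)
    S = np.asarray(S, dtype=int)
    if S.size == 0:
        raise ValueError("subset S must be nonempty")
    if h == 0:
        return int(S.size)
    ps = np.sort(p[S])
    u = np.arange(1, S.size + 1)
    counts = np.searchsorted(ps, u * alpha / h, side="right")
    return int(np.max(1 - u + counts))


@dataclass
class ClusterSet:
    """Temporal clusters with ARI true-discovery-proportion lower bounds."""

    clusters: list[tuple[int, int]]  # inclusive [start, end] index intervals
    tdp_lower: list[float]
    threshold: float  # p-value cutoff used for cluster formation (NaN if none worked)
    h: int
    alpha: float = 0.05
    times: np.ndarray | None = None  # time axis, for reporting in seconds

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_times(self) -> list[tuple[float, float]]:
        if self.times is None:
            raise ValueError("no time axis attached")
        return [(float(self.times[a]), float(self.times[b])) for a, b in self.clusters]


def _contiguous_runs(indices: np.ndarray) -> list[tuple[int, int]]:
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.r_[indices[0], indices[breaks + 1]]
    ends = np.r_[indices[breaks], indices[-1]]
    return list(zip(starts.tolist(), ends.tolist()))


def find_clusters_fdp(
    test: TestCurve,
    alpha: float = 0.05,
    target_fdp: float = 0.05,
    family_indices: np.ndarray | None = None,
) -> ClusterSet:
    """Most permissive p-threshold whose clusters all meet the FDP bound.

    Candidate thresholds are the distinct observed p-values, descending.  At
    each, maximal contiguous runs with p <= threshold form the clusters and
    each run's TDP lower bound is d(run)/|run| via ARI (h computed once on
    the whole family).  The first threshold at which every cluster satisfies
    1 - TDP <= target_fdp is returned; if none does, the ClusterSet is empty.
    """
    p = test.p
    family = (np.arange(len(p)) if family_indices is None
              else np.asarray(family_indices, dtype=int))
    h = hommel_h(p[family], alpha)
    in_family = np.zeros(len(p), dtype=bool)
    in_family[family] = True
    for thr in np.unique(p[family])[::-1]:
        idx = np.flatnonzero((p <= thr) & in_family)
        runs = _contiguous_runs(idx)
        if not runs:
            continue
        tdps = []
        ok = True
        for a, b in runs:
            S = np.arange(a, b + 1)
            tdp = ari_discoveries(p, S, h, alpha) / len(S)
            tdps.append(tdp)
            if 1.0 - tdp > target_fdp:
                ok = False
                break
        if ok:
            return ClusterSet(clusters=runs, tdp_lower=tdps, threshold=float(thr),
                              h=h, alpha=alpha, times=test.times)
    return ClusterSet(clusters=[], tdp_lower=[], threshold=float("nan"),
                      h=h, alpha=alpha, times=test.times)


# ---------------------------------------------------------------------------
# FCR-adjusted confidence bands


def fcr_adjusted_cis(
    auc: np.ndarray,
    selected: np.ndarray,
    alpha: float = 0.05,
    chance: float = 0.5,
) -> pd.DataFrame:
    """Marginal t-intervals for mean AUC, FCR-adjusted on selected timepoints.

    Selected timepoints get level 1 - |S|*alpha/T (the selective-inference
    analogue of a Benjamini-Yekutieli adjustment), all others the standard
    1 - alpha.  Width uses the k x 2 standard error with df = k.
    """
    auc = np.asarray(auc, dtype=float)
    if auc.ndim != 3 or auc.shape[1] != 2:
        raise ValueError("auc must be k x 2 x T")
    k, _, T = auc.shape
    selected = np.asarray(selected, dtype=int)
    if selected.size and (selected.min() < 0 or selected.max() >= T):
        raise ValueError("selected indices out of range")
    level_sel = 1 - selected.size * alpha / T if selected.size else 1 - alpha
    rows = []
    is_sel = np.zeros(T, dtype=bool)
    is_sel[selected] = True
    for t in range(T):
        cell = auc[:, :, t]
        keep = ~np.isnan(cell).any(axis=1)
        d = cell[keep] - chance
        mean = chance + d.mean()
        s2 = ((d - d.mean(axis=1, keepdims=True)) ** 2).sum()
        se = np.sqrt(s2 / keep.sum())
        level = level_sel if is_sel[t] else 1 - alpha
        q = stats.t.ppf(1 - (1 - level) / 2, df=k)
        rows.append((t, mean, mean - q * se, mean + q * se, level, bool(is_sel[t])))
    return pd.DataFrame(rows, columns=["timepoint", "mean_auc", "ci_lo", "ci_hi",
                                       "level", "selected"])
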