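"""From decoder weights to interpretable quantities.

Raw linear-classifier weights are not interpretable as scalp activity: a
channel can get a large weight purely for suppressing noise.  The forward
(activation) pattern a = Sigma_x w — decoder weights multiplied by the
feature covariance — is, and can be read like a difference wave between the
two classes.  The module also provides Wald tests of nested models that drop
a 10-20 electrode family from the full fit; these are exploratory (they are
run on timepoints already selected for significance, so their p-values are
circular) and are surfaced with an explicit warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossval import stack_trials
from .gee import GEEFit

EXPLORATORY_BANNER = (
    "EXPLORATORY: these Wald tests are computed on models already selected "
    "for above-chance decoding; the analysis is circular, p-values do not "
    "carry their conventional meaning, and no multiplicity correction is "
    "applied. Use for hypothesis generation only."
)


def haufe_pattern(weights: np.ndarray, feature_cov: np.ndarray) -> np.ndarray:
    """Forward activation pattern a = feature_cov @ w, unit-normalised.

    The sign is chosen so that corr(a, w) >= 0.  For a single-output linear
    model this equals the Haufe transformation up to positive scale.
    """
    w = np.asarray(weights, dtype=float).ravel()
    cov = np.asarray(feature_cov, dtype=float)
    if cov.shape != (w.size, w.size):
        raise ValueError(f"feature_cov must be {w.size} x {w.size}, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("feature_cov must be symmetric")
    a = cov @ w
    norm = np.linalg.norm(a)
    if norm == 0:
        return a
    a = a / norm
    wc = w - w.mean()
    ac = a - a.mean()
    if wc @ ac < 0:
        a = -a
    return a


@dataclass
class PatternMap:
    """Reconstructed activation patterns, channels x timepoints."""

    A: np.ndarray
    times: np.ndarray
    target: str
    ch_names: list[str]


def pattern_curve(epochs, trials, target: str, fits: list[GEEFit | None],
                  time_indices: np.ndarray | None = None) -> PatternMap:
    """Haufe reconstruction at every timepoint.

    Uses the empirical channel covariance over *all* trials at each
    timepoint (train-only covariance is a config choice upstream).  A
    missing fit leaves a NaN column with a warning.
    """
    data = stack_trials(epochs, trials, target)
    t_idx = (np.arange(len(data.times)) if time_indices is None
             else np.asarray(time_indices, dtype=int))
    if len(fits) != len(t_idx):
        raise ValueError(f"need one fit per timepoint ({len(t_idx)}), got {len(fits)}")
    A = np.full((data.X.shape[1], len(t_idx)), np.nan)
    for ti, (t, fit) in enumerate(zip(t_idx, fits)):
        if fit is None:
            warnings.warn(f"missing fit at timepoint index {t}; pattern column is NaN",
                          RuntimeWarning)
            continue
        cov = np.cov(data.X[:, :, t], rowvar=False)
        A[:, ti] = haufe_pattern(fit.beta[1:], cov)
    return PatternMap(A=A, times=data.times[t_idx], target=target,
                      ch_names=data.ch_names)


def window_pattern(pm: PatternMap, window: tuple[float, float]) -> np.ndarray:
    """One spatial map for a latency window: sign-aligned average of the
    per-timepoint patterns inside it, re-normalised to unit norm.

    Per-timepoint patterns are unit-norm with arbitrary overall sign;
    aligning signs to the first window column before averaging keeps the
    estimate from cancelling.
    """
    t0, t1 = window
    cols = np.flatnonzero((pm.times >= t0 - 1e-12) & (pm.times <= t1 + 1e-12))
    if cols.size == 0:
        raise ValueError(f"window {window} contains no pattern timepoints")
    A = pm.A[:, cols]
    if np.isnan(A).all():
        raise ValueError("no finite pattern columns inside the window")
    ref = A[:, 0]
    signs = np.where(np.nansum(A * ref[:, None], axis=0) < 0, -1.0, 1.0)
    mean = np.nanmean(A * signs[None, :], axis=1)
    norm = np.linalg.norm(mean)
    return mean / norm if norm > 0 else mean


@dataclass
class WaldResult:
    """Wald test of dropping one electrode family from the full model."""

    group: str
    timepoint: float  # seconds
    W_stat: float
    df: int
    p: float


def wald_exclusion_test(fit: GEEFit, group_channels: np.ndarray,
                        group: str = "", timepoint: float = float("nan")) -> WaldResult:
    """W = beta_S' V_SS^{-1} beta_S with the robust covariance block.

    ``group_channels`` indexes channels (0-based, excluding the intercept);
    p comes from chi-square with df = |S| (rank-adjusted under a singular
    block, with a warning).
    """
    idx = np.asarray(group_channels, dtype=int)
    if idx.size == 0:
        raise ValueError("group_channels must be nonempty")
    coef_idx = idx + 1  # skip intercept
    b = fit.beta[coef_idx]
    V = fit.robust_cov[np.ix_(coef_idx, coef_idx)]
    try:
        W = float(b @ np.linalg.solve(V, b))
        df = idx.size
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance block; using pseudo-inverse with "
                      "rank-adjusted df", RuntimeWarning)
        Vp = np.linalg.pinv(V)
        W = float(b @ Vp @ b)
        df = int(np.linalg.matrix_rank(V))
    W = max(W, 0.0)
    p = float(stats.chi2.sf(W, df)) if df > 0 else 1.0
    return WaldResult(group=group, timepoint=timepoint, W_stat=W, df=df, p=p)


def wald_exclusion_tests(fit: GEEFit, group_indices: dict[str, np.ndarray],
                         timepoint: float = float("nan"),
                         exploratory_warning: bool = True) -> pd.DataFrame:
    """Run the exclusion test for every 10-20 electrode family."""
    if exploratory_warning:
        warnings.warn(EXPLORATORY_BANNER, UserWarning)
    rows = []
    for group, idx in group_indices.items():
        r = wald_exclusion_test(fit, idx, group=group, timepoint=timepoint)
        rows.append((r.group, r.timepoint, r.W_stat, r.df, r.p))
    return pd.DataFrame(rows, columns=["group", "timepoint", "W_stat", "df", "p"])
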