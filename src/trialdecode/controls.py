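"""Control analyses under the identical cross-validation machinery.

Two confound checks accompany the EEG decoder: (1) can market outcomes be
predicted from the subjects' own yes/no choices, and (2) can they be
predicted from stimulus feature vectors (e.g. CNN penultimate-layer
activations supplied externally) with a linear discriminant?  Both reuse the
*same* stimulus-disjoint split plan as the EEG run — a fairness constraint
asserted by hash equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .crossval import SplitPlan, roc_auc
from .gee import fit_gee_logistic, predict_scores
from .inference import kx2_cv_ttest
from .simulate import validate_trial_table


def assert_same_plan(plan: SplitPlan, reference: SplitPlan) -> None:
    """Fail loudly if a control analysis is not using the EEG run's plan."""
    if plan.digest() != reference.digest():
        raise ValueError("control analysis must reuse the EEG run's split plan "
                         "(plan hashes differ)")


@dataclass
class BehavioralControlResult:
    """Choice -> market GEE control: CV AUCs plus the in-sample fit."""

    auc: np.ndarray  # k x 2
    insample_coef: float
    insample_ci: tuple[float, float]
    z: float
    p: float
    t_stat: float
    t_p: float
    df: int


def behavioral_control(trials: pd.DataFrame, plan: SplitPlan,
                       reference_plan: SplitPlan | None = None) -> BehavioralControlResult:
    """Predict market outcomes from individual choices alone.

    GEE logistic market ~ choice with subject clusters, scored out-of-sample
    on the same stimulus-disjoint halves as the EEG decoder, plus a
    full-sample fit reporting the coefficient with robust 95% CI, z and p.
    """
    validate_trial_table(trials)
    if reference_plan is not None:
        assert_same_plan(plan, reference_plan)
    stim = trials["stimulus_id"].to_numpy()
    X = trials[["choice"]].to_numpy(dtype=float)
    y = trials["market"].to_numpy(dtype=int)
    clusters = trials["subject_id"].to_numpy()

    auc = np.full((plan.k, 2), np.nan)
    for i, (half_a, half_b) in enumerate(plan.halves):
        in_a = np.isin(stim, sorted(half_a))
        in_b = np.isin(stim, sorted(half_b))
        for j, (tr, te) in enumerate([(in_a, in_b), (in_b, in_a)]):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                warnings.warn("control fold missing a class; AUC recorded as NaN",
                              RuntimeWarning)
                continue
            fit = fit_gee_logistic(X[tr], y[tr], clusters[tr])
            auc[i, j] = roc_auc(predict_scores(fit, X[te]), y[te])

    full = fit_gee_logistic(X, y, clusters)
    coef = float(full.beta[1])
    se = float(np.sqrt(full.robust_cov[1, 1]))
    z = coef / se if se > 0 else np.inf * np.sign(coef)
    p = float(2 * stats.norm.sf(abs(z)))
    ci = (coef - 1.96 * se, coef + 1.96 * se)
    t_stat, t_p, df = kx2_cv_ttest(auc)
    return BehavioralControlResult(auc=auc, insample_coef=coef, insample_ci=ci,
                                   z=float(z), p=p, t_stat=t_stat, t_p=t_p, df=df)


def load_feature_table(path) -> pd.DataFrame:
    """Read a stimulus feature table (TSV: stimulus_id + numeric columns)."""
    features = pd.read_csv(path, sep="\t")
    if "stimulus_id" not in features.columns:
        raise ValueError("feature table must have a stimulus_id column")
    return features.set_index("stimulus_id")


@dataclass
class FeatureControlResult:
    """Stimulus-feature LDA control."""

    auc: np.ndarray  # k x 2
    t_stat: float
    p: float
    df: int


def lda_feature_control(features: pd.DataFrame, market: pd.Series,
                        plan: SplitPlan,
                        reference_plan: SplitPlan | None = None) -> FeatureControlResult:
    """Predict market outcomes from per-stimulus feature vectors via LDA.

    One observation per stimulus; the single discriminant dimension of a
    binary LDA is fitted on training-half stimuli only and scores the
    held-out half; the k x 2 t-test summarises the AUCs.  A singular
    within-class scatter falls back to shrinkage with a warning.
    """
    if isinstance(features, pd.DataFrame) and features.index.name != "stimulus_id":
        if "stimulus_id" in features.columns:
            features = features.set_index("stimulus_id")
    if reference_plan is not None:
        assert_same_plan(plan, reference_plan)
    market = pd.Series(market)
    stim_ids = features.index.to_numpy()
    X = features.to_numpy(dtype=float)
    y = market.loc[stim_ids].to_numpy(dtype=int)

    auc = np.full((plan.k, 2), np.nan)
    for i, (half_a, half_b) in enumerate(plan.halves):
        in_a = np.isin(stim_ids, sorted(half_a))
        in_b = np.isin(stim_ids, sorted(half_b))
        for j, (tr, te) in enumerate([(in_a, in_b), (in_b, in_a)]):
            assert not (set(stim_ids[tr]) & set(stim_ids[te]))
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                warnings.warn("LDA fold missing a class; AUC recorded as NaN",
                              RuntimeWarning)
                continue
            scores = _lda_scores(X[tr], y[tr], X[te])
            auc[i, j] = roc_auc(scores, y[te])
    t_stat, p, df = kx2_cv_ttest(auc)
    return FeatureControlResult(auc=auc, t_stat=t_stat, p=p, df=df)


def _lda_scores(X_train, y_train, X_test) -> np.ndarray:
    n, p = X_train.shape
    shrinkage = None
    if n - 2 < p:  # pooled within-class scatter cannot be full rank
        warnings.warn("singular within-class scatter; falling back to "
                      "shrinkage LDA", RuntimeWarning)
        shrinkage = "auto"
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(X_train, y_train)
    return lda.decision_function(X_test)
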