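"""Model / Results front end for the decoding pipeline.

`TrialDecodingModel` is constructed from data (epochs + trial table, or a
simulation config, or an on-disk dataset) and `fit()` returns a
`TrialDecodingResults` carrying the cross-validated AUC curve together with
its inference (k x 2 t-curve, ARI clusters, FCR bands), the full-sample
per-timepoint fits, Haufe patterns and exploratory Wald tables, plus a
text `summary()` and a `plot()`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crossval, inference, interpret
from .crossval import DecodingCurve, SplitPlan, make_split_plan, sliding_decode
from .simulate import EpochSet, SimConfig, simulate_dataset


class TrialDecodingModel:
    """Per-timepoint GEE-logistic decoding of trial outcomes from voltages.

    Parameters
    ----------
    epochs : list of EpochSet
        One per subject; shared channel set and time grid.
    trials : DataFrame
        Columns subject_id, stimulus_id, trial_index, choice, market.
    target : {"choice", "market"}
        Which label the decoder predicts.
    working_corr : {"independence", "exchangeable"}
        GEE working correlation; subjects are the clusters either way.
    scaling : {"none", "train_zscore"}
        Optional train-fold feature standardisation.
    """

    def __init__(self, epochs: list[EpochSet], trials: pd.DataFrame,
                 target: str = "choice", working_corr: str = "independence",
                 scaling: str = "none", ridge: float = 0.0):
        self.epochs = epochs
        self.trials = trials
        self.target = target
        self.working_corr = working_corr
        self.scaling = scaling
        self.ridge = ridge
        # stack once to validate alignment early
        self._stacked = crossval.stack_trials(epochs, trials, target)

    @classmethod
    def from_simulation(cls, config: SimConfig, target: str = "choice", **kw):
        epochs, trials = simulate_dataset(config)
        model = cls(epochs, trials, target=target, **kw)
        model.sim_config = config
        return model

    @classmethod
    def from_dataset(cls, path, target: str = "choice", **kw):
        from .pipeline import load_bids_epochs

        epochs, trials = load_bids_epochs(path)
        return cls(epochs, trials, target=target, **kw)

    @property
    def stimulus_ids(self):
        return sorted(set(self._stacked.stimulus))

    def fit(self, k: int = 10, seed: int = 0, plan: SplitPlan | None = None,
            time_indices: np.ndarray | None = None) -> "TrialDecodingResults":
        """Run the stimulus-disjoint k x 2 CV decoder over all timepoints."""
        if plan is None:
            plan = make_split_plan(self.stimulus_ids, k=k, seed=seed)
        curve = sliding_decode(self.epochs, self.trials, self.target, plan,
                               scaling=self.scaling, time_indices=time_indices,
                               working_corr=self.working_corr, ridge=self.ridge)
        return TrialDecodingResults(model=self, curve=curve,
                                    time_indices=time_indices)


@dataclass
class TrialDecodingResults:
    """Fitted decoding curve plus everything derived from it."""

    model: TrialDecodingModel
    curve: DecodingCurve
    time_indices: np.ndarray | None = None
    alpha: float = 0.05
    target_fdp: float = 0.05
    _test: inference.TestCurve | None = field(default=None, repr=False)
    _clusters: inference.ClusterSet | None = field(default=None, repr=False)
    _full_fits: list | None = field(default=None, repr=False)

    # -- inference ---------------------------------------------------------
    def test_curve(self, numerator: str = "mean") -> inference.TestCurve:
        if self._test is None:
            self._test = inference.kx2_test_curve(self.curve, numerator=numerator)
        return self._test

    def permutation_curve(self, n_perm: int = 199, seed: int = 0) -> inference.TestCurve:
        return inference.permutation_test(
            self.model.epochs, self.model.trials, self.model.target,
            self.curve.split_plan, n_perm=n_perm, seed=seed,
            time_indices=self.time_indices,
        )

    def clusters(self, family_indices: np.ndarray | None = None) -> inference.ClusterSet:
        if self._clusters is None:
            self._clusters = inference.find_clusters_fdp(
                self.test_curve(), alpha=self.alpha, target_fdp=self.target_fdp,
                family_indices=family_indices,
            )
        return self._clusters

    def fcr_intervals(self) -> pd.DataFrame:
        cs = self.clusters()
        selected = np.concatenate(
            [np.arange(a, b + 1) for a, b in cs.clusters]
        ) if cs.clusters else np.array([], dtype=int)
        return inference.fcr_adjusted_cis(self.curve.auc, selected, alpha=self.alpha)

    # -- interpretation ----------------------------------------------------
    def full_sample_fits(self) -> list:
        if self._full_fits is None:
            self._full_fits = crossval.fit_full_sample(
                self.model.epochs, self.model.trials, self.model.target,
                time_indices=self.time_indices,
                working_corr=self.model.working_corr, ridge=self.model.ridge,
            )
        return self._full_fits

    def patterns(self) -> interpret.PatternMap:
        return interpret.pattern_curve(
            self.model.epochs, self.model.trials, self.model.target,
            self.full_sample_fits(), time_indices=self.time_indices,
        )

    def wald_table(self, timepoint_index: int,
                   exploratory_warning: bool = True) -> pd.DataFrame:
        """Exploratory nested-model tests for one timepoint's full fit."""
        fit = self.full_sample_fits()[timepoint_index]
        groups = self.model.epochs[0].group_channel_indices()
        return interpret.wald_exclusion_tests(
            fit, groups, timepoint=float(self.curve.times[timepoint_index]),
            exploratory_warning=exploratory_warning,
        )

    # -- reporting ---------------------------------------------------------
    def peak(self) -> tuple[float, float]:
        """(peak mean AUC, its time in seconds)."""
        mean = self.curve.mean_auc()
        i = int(np.nanargmax(mean))
        return float(mean[i]), float(self.curve.times[i])

    def summary(self) -> str:
        st = self.model._stacked
        peak_auc, peak_t = self.peak()
        cs = self.clusters()
        lines = []
        width = 64
        lines.append("Single-trial decoding: GEE logistic, stimulus-disjoint k x 2 CV".center(width))
        lines.append("=" * width)
        lines.append(f"{'Target:':<16}{self.model.target:<16}"
                     f"{'Subjects:':<14}{len(self.model.epochs)}")
        lines.append(f"{'Trials:':<16}{len(st.y):<16}"
                     f"{'Channels:':<14}{len(st.ch_names)}")
        lines.append(f"{'Timepoints:':<16}{self.curve.auc.shape[2]:<16}"
                     f"{'Replications:':<14}{self.curve.auc.shape[0]}")
        lines.append(f"{'Working corr:':<16}{self.model.working_corr:<16}"
                     f"{'alpha:':<14}{self.alpha}")
        lines.append("-" * width)
        lines.append(f"Peak mean AUC: {peak_auc:.3f} at {peak_t * 1000:+.0f} ms")
        if cs.clusters:
            lines.append(f"Temporal clusters with FDP < {self.target_fdp:.0%} "
                         f"(ARI, Hommel h = {cs.h}):")
            lines.append(f"{'':>2}{'start_ms':>10}{'end_ms':>10}{'peak_AUC':>10}{'TDP>=':>8}")
            mean = self.curve.mean_auc()
            for n, ((a, b), tdp) in enumerate(zip(cs.clusters, cs.tdp_lower), 1):
                lines.append(f"{n:>2}{self.curve.times[a] * 1000:>10.0f}"
                             f"{self.curve.times[b] * 1000:>10.0f}"
                             f"{np.nanmax(mean[a:b + 1]):>10.3f}{tdp:>8.2f}")
        else:
            lines.append(f"No temporal cluster reaches FDP < {self.target_fdp:.0%}.")
        lines.append("=" * width)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Mean AUC curve with FCR-adjusted bands and cluster shading."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mean = self.curve.mean_auc()
        times = self.curve.times
        ci = self.fcr_intervals()
        ax.fill_between(times, ci["ci_lo"], ci["ci_hi"], alpha=0.25,
                        label="FCR-adjusted CI")
        ax.plot(times, mean, lw=1.5, label="mean CV AUC")
        for a, b in self.clusters().clusters:
            ax.axvspan(times[a], times[b], color="gold", alpha=0.3)
        ax.axhline(0.5, ls="--", c="k", lw=0.8)
        ax.axvline(0.0, ls=":", c="k", lw=0.8)
        ax.set_xlabel("time from stimulus onset (s)")
        ax.set_ylabel("ROC-AUC")
        ax.set_title(f"{self.model.target} decoding")
        ax.legend(loc="upper left", fontsize=8)
        return ax
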