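# Methods

`trialdecode` implements a time-resolved multivariate decoding analysis for
multi-subject epoched EEG: at every timepoint of the epoch, a single
logistic classifier is fitted over *all* subjects' trials at once and asked
to predict either the subject's own yes/no choice about the stimulus or a
market-level outcome attached to the stimulus (funded / unfunded), from the
vector of channel voltages at that timepoint. This note records the model,
the inferential machinery, the synthetic-data generator, and the numerical
and design choices that were genuinely open.

## The decoding model

For trial $i$ of subject $s$ with channel voltages $x_{si} \in \mathbb{R}^C$
(µV) at one timepoint,

$$\operatorname{logit} P(y_{si} = 1) = \beta_0 + x_{si}^\top \beta ,$$

estimated by generalized estimating equations with subjects as clusters.
Under the default **independence** working correlation the point estimate
equals the pooled logistic MLE, so the package solves it directly by
Newton–IRLS and attaches the cluster-robust (sandwich) covariance
$\widehat V = A^{-1} \left( \sum_s g_s g_s^\top \right) A^{-1}$ with
$A = X^\top W X$ and per-cluster score $g_s = X_s^\top (y_s - \mu_s)$. The
**exchangeable** working correlation is delegated to statsmodels' GEE. The
fit is unpenalised — unlike the regularised classifiers common in MVPA —
precisely so that the coefficients support ordinary multiple-regression
inference (nested-model Wald tests, robust CIs). Perfect separation is
detected (divergence or iteration cap) and reported through an honest
`converged=False` flag and warning, never silently; a small optional ridge
on the score equations exists for degenerate designs and is off by default.

## Cross-validation and scoring

Generalisation is defined over *novel stimuli*: each of $k = 10$
replications partitions the stimulus set at random into halves of size
$\lfloor n/2 \rfloor$ / $\lceil n/2 \rceil$; the model is trained on all
trials (all subjects) of one half's stimuli and scored on the other half,
in both orientations. Because market labels are constant per stimulus, the
stimulus-disjoint split is what prevents label leakage, and the split plan
carries a content hash so the control analyses can prove they reused the
identical splits. Performance is the ROC-AUC, computed as the Mann–Whitney
statistic with midrank tie handling. Optional train-fold z-scoring is
available; it is off by default since the unpenalised logistic fit is
equivariant to affine feature maps.

## The k × 2 CV t-test and its calibration

With differences from chance $d_i^{(j)} = \mathrm{AUC}_{ij} - 0.5$, the test
uses the per-replication variance
$s_i^2 = (d_i^{(1)} - \bar d_i)^2 + (d_i^{(2)} - \bar d_i)^2$ and
$t = \bar d \big/ \sqrt{\tfrac1k \sum_i s_i^2}$, one-sided against Student
$t$ with $\mathrm{df} = k$ (the classic single-difference numerator is
available by flag). The denominator deliberately does not shrink with the
number of replications, avoiding the false-positive inflation of a naive
t-test over CV folds.

**Known limitation.** This variance formula assumes the two
fold-orientations of a replication are nearly independent. That holds when
*comparing two algorithms* (the shared component cancels in the
difference), but not against a fixed chance level: both orientations'
AUC deviations reduce to nearly the same symmetric cross-half alignment
statistic, and we measure their null correlation at ≈ 0.8 at the desk
scale (reproduced independently with scikit-learn logistic regression on
iid Gaussian features). Consequently $\sum_i s_i^2 / k$ underestimates the
variance of $\bar d$ by a factor ≈ 2.5–3 and the test is anti-conservative:
its measured size at nominal α = 0.05 is ≈ 0.13 under the desk-scale null,
and ARI clusters built on these p-values inherit the inflation (≈ 1/3 of
pure-null desk-scale runs report some cluster). The package therefore also
provides a **permutation test** of the same hypotheses — market labels
permuted across stimuli (preserving per-stimulus constancy), choice labels
permuted within subject, the identical split plan re-scored — whose
p-values $p = (1 + \#\{\text{perm} \ge \text{obs}\})/(n_{\text{perm}}+1)$
are exactly valid; the two approaches agree on strong signals and diverge
exactly where the parametric test's optimism matters.

## All-Resolutions Inference

Per-timepoint p-values are corrected by closed testing with Simes local
tests. Hommel's $h$ — the size of the largest subset whose intersection
survives every Simes test in the closure — is computed once on the whole
family (all $T$ timepoints by default; a sub-family can be configured);
for any index subset $S$ the number of true discoveries is bounded below by
$d(S) = \max_{u} \left( 1 - u + \#\{ i \in S : h\, p_i \le u \alpha \}
\right)$, simultaneously over all $S$ at confidence $1-\alpha$. Cluster
formation scans the distinct observed p-values from the most permissive
threshold downward, forms maximal contiguous runs with $p \le$ threshold,
and stops at the first threshold where every run's false-discovery
proportion bound $1 - d(S)/|S|$ is below the 5% target. Both $h$ and $d(S)$
are verified in the test suite against exhaustive enumeration of the full
closed-testing lattice at $m \le 10$.

Confidence bands for the mean AUC curve use the k × 2 standard error;
timepoints selected by the cluster step get false-coverage-rate adjusted
marginal levels $1 - |S|\alpha/T$ (the selective-inference analogue of a
Benjamini–Yekutieli adjustment), all others the standard $1-\alpha$. The
exact interval construction for selective coverage is not uniquely
determined by its name; this construction is declared, not inferred.

## Weights, patterns, and nested models

Linear-decoder weights are not interpretable as scalp activity (a channel
can earn a large weight purely for cancelling shared noise), so maps are
reported as forward activation patterns $a \propto \Sigma_x w$ — the Haufe
transformation, exact up to positive scale for a single-output linear model
— using the empirical channel covariance over all trials at the evaluated
timepoint (a train-only covariance is a configuration choice). Patterns are
unit-norm with sign aligned to the weights; for a latency window the
per-timepoint patterns are sign-aligned and averaged into one map
(`interpret.window_pattern`), which is also what the recovery tests score
against the generator's ground truth.

Nested-model Wald tests drop one 10–20 electrode family at a time from the
full fit: $W = \beta_S^\top V_{SS}^{-1} \beta_S$ on the robust covariance
block, $\chi^2_{|S|}$ reference (pseudo-inverse with rank-adjusted df if the
block is singular). Because these tests are run at timepoints already
selected for above-chance decoding, they are circular; the package surfaces
them only behind an `--exploratory` acknowledgment with a warning banner and
applies no multiplicity correction, and their p-values must be read as
hypothesis-generating only.

## Control analyses

Two confound checks reuse the identical split plan (hash-asserted):
market-from-choice (GEE logistic `market ~ choice`, subject clusters,
out-of-sample AUC per half, plus a full-sample coefficient with robust 95%
CI, z and p) and market-from-stimulus-features (binary LDA on externally
supplied per-stimulus feature vectors, e.g. CNN penultimate-layer
activations; the package defines the contract over any feature table and
does not extract CNN features itself). A pooled within-class scatter that
cannot be full rank falls back to shrinkage LDA with a warning.

## Synthetic data generator

The generator emulates the structure of the motivating study design — about
16 usable subjects, 91 stimuli viewed once each, 128 scalp channels in six
anterior-to-posterior 10–20 families, epochs −200…800 ms at 100 Hz after
resampling, market label split near 43 funded / 48 unfunded — while keeping
every ground truth known:

* **Evoked background**: a common ERP waveform (N1 dip at 110 ms, P2 peak
  at 220 ms, late positivity, ≈ 8 µV peak) times a smooth posterior-weighted
  topography, identical for all trials. Classes are coded ±½ around it, so
  the grand-average evoked response carries no label information and all
  decodable signal lives in the configured patterns.
* **Patterns**: unit-norm spatial forward patterns confined to latency
  windows, with amplitude in µV and a target label (choice or market).
* **Noise**: Gaussian, white in time, spatially correlated with an
  exponential falloff in channel-index distance (length scale 5 channels)
  scaled by a per-channel sd (default 10 µV — the order of single-trial EEG
  background at a posterior channel). Spatial correlation is what makes the
  weight/pattern distinction non-trivial.
* **Subject effects**: a lognormal per-subject gain (sd 0.25) on pattern
  amplitude, inducing the within-subject correlation that GEE clustering is
  meant to absorb.
* **Labels**: market labels per stimulus, by default exactly
  round(n · p_funded) funded (the study-count analogue); choices Bernoulli
  with base rate 0.5 and a configurable correlation ρ to the market label,
  implemented as a conditional-Bernoulli mixing that achieves
  corr(choice, market) = ρ exactly in expectation (a doubly-thresholded
  shared Gaussian would attenuate the binary correlation by the arcsine
  law). ρ defaults to 0: at the default the two label streams are
  independent, and the behavioral control is a true null. The balanced
  choice base rate keeps the ±½ coding symmetric; real subjects funded
  fewer than half the appeals, and the rate is configurable.
* A `drop_fraction` knob stands in for artifact rejection attrition, since
  per-subject retention is otherwise unconstrained.

What the generator does **not** emulate: realistic head-model forward
physics, eye artifacts, non-stationary or temporally correlated noise,
continuous (non-epoched) recordings, and any real relationship between
image content and market outcomes. Passing tests therefore demonstrate the
statistical machinery's behaviour under a known, well-specified data model
— not performance on real EEG.

## Desk scale and test problem sizes

The default simulated study is 8 subjects × 60 stimuli × 32 channels × 51
timepoints (50 Hz over [−0.2, 0.8] s); an acquisition-matched
16 × 91 × 128 @ 100 Hz configuration is available
(`full_scale_config`) but is not needed by any test. The test suite runs
the null-calibration study at 500 replicates on a single timepoint, cluster
recovery and null specificity at 50 seeds each on the 51-timepoint scale,
Haufe recovery at 20 seeds, and permutation uniformity at 25 runs × 99
permutations; `scripts/acceptance.py` reports one decoding run plus a
100-replicate calibration estimate. These sizes are the package's own
desk-scale choices; all generator parameters are fixed defaults, not
per-test adjustments.

## Preprocessing scope

Only the computations that shape the analysis are implemented: baseline
correction over [−200, 0] ms; flagging of independent components whose
Pearson correlations with the two bipolar EOG channels, z-scored across
components (population sd, signed r, two-sided at ±1.96), mark them as
oculomotor; selection of the peak-to-peak trial-rejection threshold by
five-fold cross-validation (minimising the mean squared difference between
the surviving-trial average and the validation-fold average, ties toward
the smaller threshold, label-blind seeded folds, default grid of 40
log-spaced candidates between the median and the maximum observed p2p); and
polyphase downsampling. Standardised cleaning (PREP referencing, 0.3–50 Hz
filtering, the ICA decomposition itself, channel repair) is upstream of
this package and is consumed, not reimplemented.

## Numerical choices and edge cases

* IRLS: Newton steps, tolerance 1e−8 on the max coefficient change, 100
  iterations, linear predictor clipped at ±30 for stable sigmoids;
  divergence (‖β‖∞ > 1e6) or a singular Hessian ends the fit with
  `converged=False`.
* k × 2 test: SE = 0 with zero numerator gives t = 0, p = 0.5; SE = 0 with
  nonzero numerator gives p = 0 with a warning. Replications with a missing
  orientation are dropped pairwise; more than half missing is an error.
* Folds whose test half lacks a class record NaN AUCs with a warning and
  propagate as missing into inference.
* Cluster formation ties: thresholds are the distinct observed p-values,
  scanned descending; clusters are maximal contiguous runs, so they are
  disjoint by construction.
* Epoch convention: times relative to image onset, [−0.2 s, 0.8 s] closed
  at both endpoints on the sampling grid; µV and seconds everywhere.
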