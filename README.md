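# trialdecode

Time-resolved single-trial EEG decoding with GEE classifiers,
stimulus-disjoint k × 2 cross-validation, and All-Resolutions Inference.

## What this is for

Given multi-subject epoched EEG (trials × channels × timepoints) and a
per-trial label table, `trialdecode` asks, at every timepoint of the epoch,
whether the scalp voltages can predict (a) the subject's own binary choice
about the stimulus and (b) an aggregate, stimulus-level outcome shared by
all subjects — the motivating case being crowdfunding appeals whose market
fate (funded / unfunded) is a property of the stimulus, not of the viewer.
It is written for cognitive neuroscientists and biostatisticians who want
the full inferential stack of that analysis as reusable, tested code, plus
a synthetic-data generator with known ground truth so every stage can be
validated without any data download.

The core pieces:

* **Decoder** — one logistic model per timepoint fitted over *all*
  subjects' trials by generalized estimating equations (subjects as
  clusters, independence working correlation by default, cluster-robust
  sandwich covariance, no regularisation):
  `logit P(y = 1) = β₀ + xᵀβ` with `x` the channel voltages (µV).
* **Cross-validation** — k = 10 random half/half partitions of the
  *stimulus set*; train on all trials of one half's stimuli, score the
  held-out half by ROC-AUC (Mann–Whitney with midrank ties), both
  orientations. Stimulus-disjoint halves are what make stimulus-level
  labels leakage-proof.
* **Inference** — the k × 2 CV t-test
  `t = d̄ / √(Σᵢ sᵢ² / k)`, `sᵢ² = (dᵢ⁽¹⁾ − d̄ᵢ)² + (dᵢ⁽²⁾ − d̄ᵢ)²`,
  whose standard error does not shrink with the number of splits; a
  permutation alternative with exactly valid p-values; All-Resolutions
  Inference (closed testing with Simes local tests, Hommel's h) giving
  each temporal cluster a simultaneous lower bound on its true-discovery
  proportion, with the cluster threshold relaxed until FDP < 5%; and
  false-coverage-rate adjusted confidence bands for selected timepoints.
* **Interpretation** — Haufe forward patterns `a ∝ Σₓ w` (readable like a
  difference wave, unlike raw weights) and exploratory nested-model Wald
  tests over the six anterior-to-posterior 10–20 electrode families.
* **Controls** — market-from-behavior (GEE) and market-from-stimulus-
  features (LDA) under the *identical* split plan, enforced by hash.
* **Simulator** — configurable ERP background, class-conditional
  spatiotemporal patterns in latency windows, spatially correlated noise,
  subject random gains, market-label imbalance, and a dial for the
  choice–market coupling (default 0).

See `docs/methods.md` for the model details, the generator's scope, and a
known calibration limitation of the parametric k × 2 test against a fixed
chance level (its permutation counterpart does not share it).

## Worked example

```python
import trialdecode as td

# desk-scale study: 8 subjects x 60 stimuli x 32 channels @ 50 Hz,
# a choice pattern injected at 200-300 ms with amplitude/noise = 1
cfg = td.demo_config(seed=1)
epochs, trials = td.simulate_dataset(cfg)

model = td.TrialDecodingModel(epochs, trials, target="choice")
res = model.fit(k=10, seed=1)
print(res.summary())
```

```
Single-trial decoding: GEE logistic, stimulus-disjoint k x 2 CV 
================================================================
Target:         choice          Subjects:     8
Trials:         480             Channels:     32
Timepoints:     51              Replications: 10
Working corr:   independence    alpha:        0.05
----------------------------------------------------------------
Peak mean AUC: 0.590 at +200 ms
Temporal clusters with FDP < 5% (ARI, Hommel h = 47):
    start_ms    end_ms  peak_AUC   TDP>=
 1       200       200     0.590    1.00
 2       240       280     0.573    1.00
================================================================
```

The decoder finds above-chance decoding only inside the window where the
generator injected signal: peak cross-validated AUC 0.590 at 200 ms, and
the ARI clusters (200 ms; 240–280 ms) carry a true-discovery-proportion
lower bound of 1.00, i.e. every timepoint inside them is guaranteed (at
95% confidence) to be a true discovery. Pre-stimulus AUC stays at chance.
From the same results object, `res.patterns()` reconstructs the forward
activation map (which correlates ≈ 0.97 with the generating pattern when
averaged over the window), `res.fcr_intervals()` gives the adjusted
confidence bands, `res.permutation_curve()` the permutation p-values, and
`res.plot()` the AUC curve with cluster shading.

The same pipeline is scriptable from the shell:

```bash
trialdecode simulate --out ds --seed 1
trialdecode decode --in ds --target choice --k 10 --seed 1 --out dec.json
trialdecode infer --decoding dec.json --out clusters.json
trialdecode run-all --out run --seed 1     # full pipeline + manifest
```

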