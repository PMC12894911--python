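# pmikit

Post-mortem interval (PMI) prediction from untargeted metabolomics
feature tables.

When a body is found, the time since death is a central question for
forensic investigators, yet classical indicators (rectal temperature,
vitreous potassium) are only reliable for the first 1–3 days. The
post-mortem metabolome keeps changing for weeks — lipids degrade, amino
acids accumulate as proteolysis proceeds — so LC-MS data already
collected during routine toxicological screening carry a PMI signal.
`pmikit` is a library for building and interrogating PMI regression
models from such data: forensic toxicology groups with feature tables
of their own, and methodologists who want a fully synthetic, ground-
truthed test bed for the approach.

## What it does

Given an intensity matrix *X* (samples × features) with per-feature
(m/z, RT) coordinates and per-sample PMI in days:

1. **Preprocessing** — zero-impute missing peaks, transform
   *x*ₙₒᵣₘ = ln(*x* + 1), z-score each feature
   ((*x* − μ)/σ, sample SD), split 80/10/10 by independent
   probabilistic assignment.
2. **Attention-gated FFNN** — the core model. A per-feature gate
   *aᵢ* = ReLU(*wᵢxᵢ* + *bᵢ*) (no cross-feature mixing) acts as
   data-driven feature selection, followed by 1–4 dense ReLU layers
   with dropout and a single linear output node (days). Training uses
   minibatch Adam, MSE loss, and early stopping with patience 25 on the
   validation loss, restoring the best weights. A seeded random search
   explores layer counts (1–4), widths (32–512), dropout (0.05–0.5) and
   learning rate (10⁻⁴–10⁻², log-uniform), with and without the gate.
3. **Model compendium** — ridge, LASSO, SVR, random forest, gradient
   boosting and k-NN baselines; MAE / median AE / R² reporting,
   Wilcoxon signed-rank model comparisons, Mann–Whitney subgroup tests,
   day-1 bias and empirical 95% prediction intervals.
4. **Harmonization** — map a second platform's features onto the
   reference space by m/z (5 ppm) + RT (30 s) windows, choosing the
   candidate minimizing *d* = (Δmz/s_mz)² + (Δrt/s_rt)²; unmatched
   reference features are zero-filled before normalization.
5. **Pseudo-time trends** — screen features whose gate activations
   correlate with PMI (Spearman + Benjamini–Hochberg), average
   standardized abundance per PMI day, Ward-cluster the trajectories
   into decreasing / increasing / fluctuating groups.
6. **Learning curves** — repeatedly subsample *n* = 16…1024 training
   profiles, fit 5-fold cross-validated LASSO, track held-out MAE.
7. **Synthetic cohorts** — a seeded generator with planted ground truth
   (PMI distribution with median 5 days and 97% of cases within 1–13,
   trend archetypes, below-LOD zero censoring, jittered platform pairs)
   so every stage is testable without any data download.

## Worked example

```bash
python examples/02_train_attention_net.py
```

```
early stopping: best epoch 5, stopped after epoch 30
test MAE 1.40 / median AE 0.93 days, R^2 0.65  (n=160)
constant-median baseline MAE 2.58 days -> the network explains most of the predictable signal
```

On the default synthetic cohort (1500 samples × 300 features, planted
trends) the attention network predicts held-out PMI with a mean error
of 1.4 days versus 2.6 days for always guessing the median — i.e. it
recovers most of the signal the generator planted. The other examples
cover simulation (`01`), cross-platform harmonization (`03`, recovering
the planted feature correspondence exactly), the six-model compendium
(`04`), trend clustering (`05`, 121 features selected, three clusters
matching the planted decreasing/increasing/fluctuating classes), and
learning curves (`06`, MAE falling from 2.6 days at n=16 to 1.5 days at
n=1024).

The same stages are scriptable end to end:

```bash
pmikit all --seed 1 --out my_run        # or: pmikit simulate / train / ...
```

which writes the cohort CSVs, normalization parameters, model archive,
evaluation report, trend clusters and a manifest recording every
resolved parameter into `my_run/`.

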