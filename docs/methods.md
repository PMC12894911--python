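# Methods

This note documents the models and procedures implemented in `pmikit`,
the conventions chosen where several were defensible, and what the
synthetic test bed does and does not establish about real data.

## Data model and preprocessing

A cohort is a `FeatureTable`: a non-negative intensity matrix (samples
× features), per-sample metadata (PMI in integer days, sex, platform)
and per-feature coordinates (median m/z in Da/charge, median RT in
seconds). PMI is a whole-day count between the date of death and the
date of autopsy (`compute_pmi`); registries code the death date as
*certain* or *probable* (last seen alive the day before being found),
the latter carrying up to 48 h of uncertainty, so sub-day resolution is
deliberately out of scope.

Preprocessing is fixed in this order: missing peaks are imputed to 0
(below limit of detection), intensities are transformed elementwise as
ln(x + 1), and each feature is z-scored. Conventions:

* **SD denominator** — sample SD (ddof = 1), recorded inside
  `NormalizationParams` so projected data always uses the convention it
  was fitted with. `fit_standardizer(..., ddof=0)` switches to the
  population convention.
* **Constant features** — flagged, kept, and mapped to all-zero columns
  after standardization, preserving column alignment for harmonization.
* **Split** — samples are assigned independently to
  train/validation/test with probabilities (0.8, 0.1, 0.1); realized
  counts therefore fluctuate binomially. By default normalization is
  fitted on the full table before splitting, as large-cohort studies
  commonly do; `leakage_safe=True` fits it on
  the training split only. At cohort scale the difference is
  negligible, and the null-cohort tests confirm neither mode leaks
  label information.

## The attention-gated network

The regressor is a dense feed-forward network implemented directly in
numpy (forward pass, backpropagation, Adam); at this problem size
(≈10²–10³ features, ≈10³ samples) CPU matrix products train the model
in seconds and the implementation stays transparent enough to verify
the gradient against central finite differences, which the test suite
does.

* **Attention gate** — feature *i* passes through its own single node,
  aᵢ = ReLU(wᵢxᵢ + bᵢ), initialized at w = 1, b = 0 (a plain ReLU
  pass-through). There is no cross-feature mixing, so a feature's gate
  weight and activations are directly interpretable as its usage by the
  model; driving wᵢ to 0 switches the feature off. The gate is the
  minimal per-feature construction in which every feature feeds its own
  single ReLU node; the bias is toggleable.
* **Body** — 1–4 dense ReLU layers (32–512 nodes, dropout 0.05–0.5 per
  layer, inverted dropout disabled at inference) and a single linear
  output node in days. A ReLU output is available but clips gradients
  at zero, so linear is the default.
* **Loss and optimizer** — MSE (MAE available), Adam with the
  configured learning rate, batch size 64: the standard recipe for
  regression reported by MAE.
* **Early stopping** — patience 25 on the validation loss, maximum 500
  epochs by default, best weights restored. The contract (returned
  validation loss equals the recorded minimum; stop exactly
  `best_epoch + patience` when no improvement follows) is unit-tested
  on constructed loss sequences.
* **Hyperparameter search** — seeded random draw: layers and widths
  uniform on their integer ranges, dropout uniform, learning rate
  log-uniform. The attention flag alternates deterministically across
  configurations so both arms are always represented, even in reduced
  searches; each configuration trains `repeats` times with fresh seeds
  and is scored by its best repeat's validation MAE.
* **Determinism** — all randomness (init, shuffling, dropout) flows
  from one `numpy` generator seeded by `HyperParams.seed`; training is
  bitwise reproducible on one machine.

## Baselines, metrics and statistics

Ridge and LASSO penalties are selected by cross-validation over
documented logarithmic grids (ridge 10⁻³–10³, 13 points, efficient GCV;
LASSO 10⁻³–10¹, 25 points, 5-fold). Forest and boosting use 100
estimators; SVR uses the RBF kernel with C = 1, ε = 0.1; k-NN uses
k = 5. R² is computed as 1 − SS_res/SS_tot about the evaluated truth's
mean; the PMI 1–13 display filter is an evaluation option only, never a
training filter. Model pairs are compared on paired absolute errors
with a two-sided Wilcoxon signed-rank test (zero differences dropped;
all-zero vectors give p = 1 by convention, with a warning); subgroups
with a tie-corrected Mann–Whitney U. Both tests are validated against
exhaustive enumeration at small n and for null calibration by
simulation. Prediction intervals are empirical 2.5/97.5 percentiles of
the predictions at one actual PMI day, with linear interpolation
between order statistics and a minimum-sample floor (default 20).

The learning curve subsamples n profiles without replacement, fits the
5-fold CV-tuned LASSO per draw, and reports the held-out MAE mean and
2.5–97.5% band per size.

## Harmonization

Each reference feature (median m/z, median RT) collects new-platform
candidates inside a ±5 ppm m/z window and a ±30 s RT window (both
configurable; the m/z window can be absolute Daltons). Among
candidates, the match minimizes d = (Δmz/s_mz)² + (Δrt/s_rt)², where
the scales default to the window half-widths so both terms are
dimensionless and reach 1 at the window edge — an unweighted squared
distance across Da and seconds would be dimensionally meaningless. Ties
resolve by smaller |Δmz|, then lexicographic feature id, making the map
bitwise reproducible. Two reference features may share a best match by
default (collisions are reported); a strict one-to-one mode assigns
greedily by ascending distance. Unmatched reference features are
zero-filled as *raw* intensity 0 and then log-transformed and
standardized with the reference parameters — the same semantics as a
missing peak — rather than being zeroed on the z-scale; this reading of
"set to 0" is an interpretation and is isolated in one code path.
Matching is verified against an exhaustive all-pairs oracle and against
planted correspondences from the generator.

## Pseudo-time trends

Feature importance is read from the attention gate: per-feature
Spearman rank correlation (tie-corrected, two-sided t-approximation
p-values) between gate activations and PMI, with Benjamini–Hochberg
step-up selection at the conventional α = 0.05. Screening on
standardized abundances instead of activations is one argument away:
both are defensible readings of feature importance, and which one
drives selection is an explicit parameter.
Constant columns have undefined correlation
and are flagged and excluded rather than failing.

Selected features are averaged over individuals sharing the same PMI
day, restricted to days with at least 5 samples (means over fewer
individuals are too noisy to cluster; `min_count=1` restores the full
grid) and optionally to a PMI range (default 1–13, where ~97% of the
cohort lies). Trajectories are row-z-scored (shape, not amplitude) and
clustered by Ward linkage on Euclidean distance, cut at k = 3; the
dendrogram is exportable as newick so other cuts remain possible.
Clusters are named by the Spearman correlation of their mean trajectory
with the PMI grid: ρ ≤ −0.6 decreasing, ρ ≥ 0.6 increasing, otherwise
fluctuating (τ = 0.6 separates monotone trends from oscillations
cleanly on the synthetic archetypes and is configurable).

## The synthetic cohort generator

The generator is first-class, tested code; its defaults define the
study conditions used throughout the test suite (1500 samples × 300
features, seeds fixed in the tests).

* **PMI sampler** — a log-normal rounded to integer days and clipped to
  [1, 67], with μ = ln 5 (median 5 days) and σ derived so that
  P(PMI ≤ 13) = 0.97 with half-integer continuity correction
  (σ ≈ 0.528). These three facts — median, 97% mass within 1–13, range
  1–67 — are the distribution summaries the sampler encodes; the full
  histogram of a real cohort is not claimed.
* **Trajectories** — on the ln-intensity scale, feature baselines are
  uniform on [4, 8]; decreasing/increasing features add
  ∓effect_size · ln t/ln 67 (decay processes move fastest early, hence
  the log time axis); fluctuating features add a two-harmonic cosine
  whose full period spans the densely observed 1–13 day range on the
  ln-time axis, with two phases drawn once per cohort (a co-regulated
  degradation process — per-feature phases would make the class
  internally incoherent and unrecoverable by any clustering) and
  per-feature amplitude mixes. Default class fractions: 15% decreasing,
  15% increasing, 10% fluctuating, 60% uninformative noise; effect size
  1.0 ln-units, residual noise SD 0.5 ln-units.
* **Zero inflation** — exactly `round(rate · n_entries)` entries
  (default 15%) are censored to raw 0 via a soft detection threshold: a
  Gumbel bottom-k on realized ln-abundance with sharpness 4 per
  ln-unit, so zeros concentrate in the genuinely lowest peaks, as a
  limit of detection does. Low-baseline features can lose half their
  entries while intense features lose none.
* **Platform pairs** — the second platform keeps 1 − frac_exclusive of
  the reference features with bounded uniform jitter (ppm in m/z,
  seconds in RT), drops the rest and gains the same number of novel
  features; coordinates are generated with a minimum-separation rule
  (two features closer than 25 ppm in m/z must differ by more than
  120 s in RT) so that matching is unambiguous whenever jitter stays
  below half the tolerance windows. The planted correspondence is
  returned as the oracle.
* **Death records** — death dates uniform over a ~1.5-year intake
  window, PMI from the cohort sampler, ~18.9% of records coded
  *probable*.

What the generator does **not** emulate: raw spectra and peak shapes,
within-platform batch drift, retention-time warping, adducts and
isotopologues, cause-of-death structure, and any real relationship
between sex and the metabolome (sex is decoration). Consequently,
passing tests demonstrate that the pipeline recovers *planted* signal
faithfully and does not manufacture signal from noise (null-cohort
guards); they do not establish accuracy figures for real forensic
cohorts, which depend on acquisition noise the generator does not
model.

## Scale of the bundled experiments

The default test-suite conditions — 1500 × 300 cohorts, 20-seed null
replicates, a 10-configuration × 2-repeat search, 25-repetition
learning curves — are desk-scale choices: large enough for the
statistical assertions they support (rank-sum separation, FDR
calibration, learning-curve monotonicity within one standard error),
small enough to run routinely. All sizes are arguments, so the full
protocol (e.g. 30 configurations × 3 repeats, 150 learning-curve
repetitions) runs unchanged on larger budgets.

## Known limitations

* The network is CPU-bound numpy; it is deliberately sized for
  feature-table regression, not for architectures beyond dense
  feed-forward nets.
* Prediction intervals are empirical percentiles per PMI day and need
  enough samples at that day; no parametric uncertainty model is
  fitted.
* Harmonization assumes static (m/z, RT) coordinates; systematic RT
  drift beyond the window defeats it by design and would need alignment
  upstream.
* The probabilistic split can, at small n, produce empty validation or
  test sets; the pipeline raises rather than silently refitting.
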