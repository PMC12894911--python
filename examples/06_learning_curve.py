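"""How many profiles does a forensic institute need?

Subsample n training profiles (n = 16 ... 1024), fit a 5-fold
cross-validated LASSO on each subset, and score the held-out test MAE.
The mean error shrinks monotonically with n; a few hundred samples
already support useful PMI predictions.
"""

from pmikit import SynthConfig, generate_cohort, run_learning_curve, split_dataset
from pmikit.preprocessing import preprocess_table

table, _ = generate_cohort(SynthConfig(seed=1))
std, _, _ = preprocess_table(table)
split = split_dataset(std, seed=1)
parts = {k: std.subset_samples(split.mask(k)) for k in ("train", "test")}

result = run_learning_curve(
    parts["train"].values(), parts["train"].pmi.astype(float),
    parts["test"].values(), parts["test"].pmi.astype(float),
    sizes=[16, 32, 64, 128, 256, 512, 1024], reps=10, seed=1,
)
print(f"{'n':>6} {'mean MAE':>9}  95% band (days)")
lo, hi = result.band
for i, n in enumerate(result.sizes):
    print(f"{n:>6} {result.mean[i]:>9.2f}  [{lo[i]:.2f}, {hi[i]:.2f}]")
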