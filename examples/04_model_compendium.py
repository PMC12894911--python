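"""Fit the six-model regression compendium and compare the models.

Ridge and LASSO penalties are tuned by cross-validation; forest and
boosting use 100 estimators; SVR and k-NN use library defaults. Paired
absolute errors are compared with a two-sided Wilcoxon signed-rank
test, as when ranking PMI models on a shared test set.
"""

import numpy as np

from pmikit import (
    SynthConfig, compare_models, evaluate, fit_compendium, generate_cohort,
    split_dataset,
)
from pmikit.preprocessing import preprocess_table

table, _ = generate_cohort(SynthConfig(n_samples=800, n_features=150, seed=2))
std, _, _ = preprocess_table(table)
split = split_dataset(std, seed=2)
parts = {k: std.subset_samples(split.mask(k)) for k in ("train", "test")}
y_train = parts["train"].pmi.astype(float)
y_test = parts["test"].pmi.astype(float)

models = fit_compendium(parts["train"].values(), y_train, seed=2)
errors = {}
print(f"{'model':<18} {'MAE':>6} {'medAE':>6} {'R2':>6}")
for kind, model in models.items():
    preds = model.predict(parts["test"].values())
    rep = evaluate(preds, y_test)
    errors[kind] = np.abs(preds - y_test)
    print(f"{kind:<18} {rep.mae:>6.2f} {rep.median_ae:>6.2f} {rep.r2:>6.2f}")

best = min(errors, key=lambda k: errors[k].mean())
print(f"\nbest model: {best}; Wilcoxon signed-rank p-values vs the rest:")
for kind in errors:
    if kind != best:
        p = compare_models(errors[best], errors[kind])
        print(f"  {best} vs {kind}: p = {p:.2g}")
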