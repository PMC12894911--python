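"""Baseline regression compendium, evaluation metrics, model comparison
statistics and the sample-size learning curve.

Six off-the-shelf regressors (ridge, LASSO, SVR, random forest,
gradient boosting, k-NN) are fitted to the same standardized training
matrix as the neural network. Models are compared on paired absolute
errors with a two-sided Wilcoxon signed-rank test; subgroup error
distributions (e.g. by sex) with a Mann-Whitney U test. The learning
curve repeatedly subsamples n training profiles, fits a 5-fold
cross-validated LASSO, and records the held-out MAE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LassoCV, RidgeCV
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

BASELINE_KINDS = ("ridge", "lasso", "svr", "random_forest", "gradient_boosting", "knn")

# documented logarithmic penalty grids for the CV-tuned linear models
RIDGE_ALPHAS = np.logspace(-3, 3, 13)
LASSO_ALPHAS = np.logspace(-3, 1, 25)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to fit and with what hyperparameter policy.

    Ridge/LASSO penalties are selected by cross-validation over the
    module-level logarithmic grids; forest and boosting use 100
    estimators; SVR (RBF, C=1, eps=0.1) and k-NN (k=5) use library
    defaults. All policies are recorded here so a run manifest can
    serialize them.
    """

    kind: str
    seed: int = 0
    cv_folds: int = 5
    n_estimators: int = 100
    knn_k: int = 5
    ridge_alphas: tuple[float, ...] = tuple(RIDGE_ALPHAS)
    lasso_alphas: tuple[float, ...] = tuple(LASSO_ALPHAS)

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise EvaluationError(
                f"unknown baseline kind {self.kind!r}; choose from {BASELINE_KINDS}"
            )
        if not self.ridge_alphas or not self.lasso_alphas:
            raise EvaluationError("penalty grids must be non-empty")


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y: np.ndarray):
    """Fit one baseline regressor on standardized features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.kind == "ridge":
        model = RidgeCV(alphas=np.asarray(spec.ridge_alphas))
    elif spec.kind == "lasso":
        model = LassoCV(
            alphas=np.asarray(spec.lasso_alphas),
            cv=spec.cv_folds,
            random_state=spec.seed,
            max_iter=5000,
        )
    elif spec.kind == "svr":
        model = SVR()  # RBF kernel, C=1, epsilon=0.1
    elif spec.kind == "random_forest":
        model = RandomForestRegressor(
            n_estimators=spec.n_estimators, random_state=spec.seed
        )
    elif spec.kind == "gradient_boosting":
        model = GradientBoostingRegressor(
            n_estimators=spec.n_estimators, random_state=spec.seed
        )
    else:  # knn
        model = KNeighborsRegressor(n_neighbors=spec.knn_k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def fit_compendium(
    X: np.ndarray, y: np.ndarray, seed: int = 0, kinds=BASELINE_KINDS
) -> dict[str, object]:
    """All six baselines, keyed by kind."""
    return {k: fit_baseline(BaselineSpec(kind=k, seed=seed), X, y) for k in kinds}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """MAE / median AE / R-squared plus per-actual-PMI prediction quantiles."""

    mae: float
    median_ae: float
    r2: float
    n: int
    per_pmi_quantiles: pd.DataFrame = field(repr=False)
    quantile_levels: tuple[float, ...] = (2.5, 25.0, 50.0, 75.0, 97.5)

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "median_ae": self.median_ae,
            "r2": self.r2,
            "n": self.n,
            "quantile_levels": list(self.quantile_levels),
        }


def evaluate(
    predictions: np.ndarray,
    truth: np.ndarray,
    pmi_range: tuple[int, int] | None = None,
) -> EvaluationReport:
    """Error metrics, optionally restricted to an actual-PMI range.

    ``pmi_range`` filters by *actual* PMI (inclusive bounds); it is a
    display/evaluation filter, not a training filter. R-squared is
    ``1 - SS_res / SS_tot`` about the evaluated truth's mean.
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise EvaluationError("predictions and truth differ in length")
    if pmi_range is not None:
        keep = (truth >= pmi_range[0]) & (truth <= pmi_range[1])
        predictions, truth = predictions[keep], truth[keep]
    if len(truth) == 0:
        raise EvaluationError("no samples left after the PMI filter")
    err = np.abs(predictions - truth)
    ss_res = float(np.sum((predictions - truth) ** 2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    levels = (2.5, 25.0, 50.0, 75.0, 97.5)
    rows = {}
    for day in np.unique(truth):
        preds_at = predictions[truth == day]
        rows[int(day)] = np.percentile(preds_at, levels)
    qdf = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"p{q}" for q in levels]
    ).rename_axis("actual_pmi")
    return EvaluationReport(
        mae=float(err.mean()),
        median_ae=float(np.median(err)),
        r2=r2,
        n=int(len(truth)),
        per_pmi_quantiles=qdf,
        quantile_levels=levels,
    )


def compare_models(abs_err_a: np.ndarray, abs_err_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired absolute errors.

    Zero differences are dropped (classical Wilcoxon convention); if all
    differences are zero there is no signal and p = 1 by convention.
    """
    a = np.asarray(abs_err_a, dtype=float)
    b = np.asarray(abs_err_b, dtype=float)
    if a.shape != b.shape:
        raise EvaluationError("paired error vectors differ in length")
    if np.all(a == b):
        logger.warning("all paired differences are zero; p = 1 by convention")
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def subgroup_test(err_group1: np.ndarray, err_group2: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value for independent error groups."""
    g1 = np.asarray(err_group1, dtype=float)
    g2 = np.asarray(err_group2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise EvaluationError("both groups must be non-empty")
    return float(stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue)


def day_one_bias(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Signed mean (prediction - actual) among samples with actual PMI 1."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    at_one = truth == 1
    if not at_one.any():
        raise EvaluationError("no samples with actual PMI = 1")
    return float(np.mean(predictions[at_one] - 1.0))


def prediction_interval(
    predictions: np.ndarray,
    truth: np.ndarray,
    actual_pmi: int,
    level: float = 95.0,
    min_n: int = 20,
) -> tuple[float, float]:
    """Empirical central prediction interval at one actual PMI.

    Linear interpolation between order statistics (numpy's default
    percentile rule).
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    preds_at = predictions[truth == actual_pmi]
    if len(preds_at) < min_n:
        raise EvaluationError(
            f"only {len(preds_at)} samples at PMI {actual_pmi}; "
            f"need at least {min_n}"
        )
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(preds_at, [half, 100.0 - half])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Learning curve
# ---------------------------------------------------------------------------

@dataclass
class LearningCurveResult:
    """Held-out MAE of CV-tuned LASSO as a function of training size."""

    sizes: list[int]
    mae: np.ndarray  # (len(sizes), reps)
    seed: int

    @property
    def mean(self) -> np.ndarray:
        return self.mae.mean(axis=1)

    @property
    def band(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical 2.5/97.5 percentile band per size."""
        return (
            np.percentile(self.mae, 2.5, axis=1),
            np.percentile(self.mae, 97.5, axis=1),
        )

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.band
        return pd.DataFrame(
            {"n": self.sizes, "mean_mae": self.mean, "p2.5": lo, "p97.5": hi}
        ).set_index("n")


def run_learning_curve(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    sizes=(16, 32, 64, 128, 256, 512, 1024),
    reps: int = 150,
    cv_folds: int = 5,
    seed: int = 0,
) -> LearningCurveResult:
    """Subsample n profiles, fit CV-tuned LASSO, score on the test set.

    For each size n, ``reps`` random subsets are drawn without
    replacement from the training pool; the LASSO penalty is chosen to
    minimize ``cv_folds``-fold cross-validated prediction error within
    each subset.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    sizes = [int(s) for s in sizes]
    if max(sizes) > len(y_train):
        raise EvaluationError(
            f"size {max(sizes)} exceeds the training pool ({len(y_train)})"
        )
    rng = np.random.default_rng(seed)
    mae = np.empty((len(sizes), reps))
    for i, n in enumerate(sizes):
        for rep in range(reps):
            idx = rng.choice(len(y_train), size=n, replace=False)
            folds = min(cv_folds, n)
            model = LassoCV(
                alphas=np.asarray(LASSO_ALPHAS),
                cv=folds,
                random_state=int(rng.integers(2**31)),
                max_iter=3000,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_train[idx], y_train[idx])
            mae[i, rep] = float(
                np.mean(np.abs(model.predict(X_test) - y_test))
            )
    return LearningCurveResult(sizes=sizes, mae=mae, seed=seed)
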