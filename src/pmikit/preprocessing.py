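"""Raw-table preprocessing: PMI computation, zero imputation, log
transform, z-standardization and the train/validation/test split.

The pipeline order is fixed: impute missing peaks to zero, apply the
``ln(x + 1)`` transform, z-standardize each feature, then split samples.
Standardization parameters fitted on one dataset can be re-applied to
project new data into the same space (see :mod:`pmikit.harmonization`).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .tables import FeatureTable, NormalizationParams

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "unknown")
SPLIT_LABELS = ("train", "validation", "test")


class PreprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PMI from death records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeathRecord:
    """A death/autopsy date pair with the registry's certainty code.

    ``certain`` means the date of death is documented; ``probable`` means
    a probable date was ascribed (the deceased last seen alive the day
    before being found), carrying up to 48 h of uncertainty.
    """

    death_date: _dt.date
    autopsy_date: _dt.date
    certainty: str = "certain"
    last_seen_date: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if self.certainty not in ("certain", "probable"):
            raise PreprocessingError(
                f"unknown certainty code {self.certainty!r}"
            )
        if self.autopsy_date < self.death_date:
            raise PreprocessingError(
                f"autopsy date {self.autopsy_date} precedes death date "
                f"{self.death_date}"
            )


def compute_pmi(record: DeathRecord) -> int:
    """Whole-day post-mortem interval: autopsy date minus death date."""
    return (record.autopsy_date - record.death_date).days


# ---------------------------------------------------------------------------
# Imputation and transforms
# ---------------------------------------------------------------------------

def impute_missing_zero(table: FeatureTable) -> tuple[FeatureTable, int]:
    """Replace missing peak intensities by zero.

    Missing values arise when a peak was not detected in a sample; zero
    encodes abundance below the limit of detection. Returns the imputed
    table and the number of cells replaced.
    """
    mask = table.intensities.isna()
    n = int(mask.to_numpy().sum())
    out = table.copy()
    out.intensities = out.intensities.fillna(0.0)
    if n:
        logger.info("imputed %d missing intensities to zero", n)
    return out, n


def log_transform(x):
    """Elementwise ``ln(x + 1)`` of a non-negative intensity matrix.

    Accepts an ndarray or DataFrame and preserves the input type. Zeros
    map to zeros, so below-LOD peaks stay at the origin of the log scale.
    """
    values = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    if np.isnan(values).any():
        raise PreprocessingError(
            "matrix contains missing values; impute before log transform"
        )
    if (values < 0).any():
        raise PreprocessingError("negative intensity in log transform")
    out = np.log1p(values)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def fit_standardizer(log_matrix, feature_order=None, ddof: int = 1) -> NormalizationParams:
    """Per-feature mean/SD of a log-intensity matrix.

    ``ddof=1`` (sample SD) is the default convention and is recorded in
    the returned parameters. Constant features get ``sd = 0`` and are
    flagged rather than rejected.
    """
    if isinstance(log_matrix, pd.DataFrame):
        feature_order = [str(c) for c in log_matrix.columns]
        values = log_matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(log_matrix, dtype=float)
        if feature_order is None:
            feature_order = [f"F{i}" for i in range(values.shape[1])]
    if values.shape[0] < 2:
        raise PreprocessingError("need at least 2 samples to fit a standardizer")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    return NormalizationParams(mean=mean, sd=sd, feature_order=list(feature_order), ddof=ddof)


def apply_standardizer(log_matrix, params: NormalizationParams):
    """Standardize ``(x - mean) / sd`` per feature using fitted params.

    The column order must match ``params.feature_order`` exactly; a
    mismatch raises naming the first offending feature. Columns flagged
    constant map to all-zeros by convention.
    """
    if isinstance(log_matrix, pd.DataFrame):
        cols = [str(c) for c in log_matrix.columns]
        for got, expected in zip(cols, params.feature_order):
            if got != expected:
                raise PreprocessingError(
                    f"feature order mismatch: got {got!r} where "
                    f"{expected!r} was expected"
                )
        if len(cols) != len(params.feature_order):
            raise PreprocessingError(
                "feature count differs from fitted parameters"
            )
        values = log_matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(log_matrix, dtype=float)
        if values.shape[1] != len(params.feature_order):
            raise PreprocessingError(
                "feature count differs from fitted parameters"
            )
    sd = np.where(params.constant, 1.0, params.sd)
    out = (values - params.mean) / sd
    out[:, params.constant] = 0.0
    if isinstance(log_matrix, pd.DataFrame):
        return pd.DataFrame(out, index=log_matrix.index, columns=log_matrix.columns)
    return out


def preprocess_table(
    table: FeatureTable,
    params: NormalizationParams | None = None,
    ddof: int = 1,
) -> tuple[FeatureTable, NormalizationParams, int]:
    """Impute -> log -> standardize; returns the standardized table.

    If ``params`` is given it is applied as-is (projection of new data);
    otherwise parameters are fitted on this table. The returned table's
    ``intensities`` hold z-scores, no longer raw intensities.
    """
    imputed, n_imputed = impute_missing_zero(table)
    logged = log_transform(imputed.intensities)
    if params is None:
        params = fit_standardizer(logged, ddof=ddof)
    z = apply_standardizer(logged, params)
    out = FeatureTable(
        z, imputed.sample_meta, imputed.feature_meta, standardized=True
    )
    return out, params, n_imputed


# ---------------------------------------------------------------------------
# Train / validation / test split
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Per-sample split label with the proportions and seed that made it."""

    labels: pd.Series  # index sample_id, values in SPLIT_LABELS
    proportions: tuple[float, float, float]
    seed: int

    def mask(self, which: str) -> pd.Series:
        if which not in SPLIT_LABELS:
            raise PreprocessingError(f"unknown split label {which!r}")
        return self.labels == which

    def counts(self) -> dict[str, int]:
        return {k: int((self.labels == k).sum()) for k in SPLIT_LABELS}


def split_dataset(
    table: FeatureTable,
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Probabilistic 80/10/10 assignment of samples to train/val/test.

    Each sample is assigned independently with the given probabilities,
    so realized counts fluctuate binomially around the proportions.
    """
    p = np.asarray(proportions, dtype=float)
    if len(p) != 3 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise PreprocessingError(
            f"proportions must be three non-negatives summing to 1, got {proportions}"
        )
    rng = np.random.default_rng(seed)
    draws = rng.choice(3, size=table.n_samples, p=p)
    labels = pd.Series(
        np.asarray(SPLIT_LABELS, dtype=object)[draws],
        index=table.intensities.index,
        name="split",
    )
    return SplitAssignment(labels=labels, proportions=tuple(p), seed=seed)
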