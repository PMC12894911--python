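"""Feature-table containers and the three-CSV on-disk format.

The universal currency of the pipeline is a :class:`FeatureTable`: an
intensity matrix (samples x features) with linked per-sample metadata
(post-mortem interval in days, sex, platform) and per-feature metadata
(median m/z, median retention time). On disk a table is three CSV files:

* ``intensities.csv`` — first column ``sample_id``, remaining columns are
  feature ids; empty cells encode missing (undetected) peaks.
* ``samples.csv``     — ``sample_id, pmi_days, sex, platform``.
* ``features.csv``    — ``feature_id, mz_median, rt_median``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_META_COLUMNS = ("pmi_days", "sex", "platform")
FEATURE_META_COLUMNS = ("mz_median", "rt_median")


class TableValidationError(ValueError):
    """A feature table violated one of its structural invariants."""


@dataclass
class FeatureTable:
    """Intensity matrix with aligned sample and feature metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by ``sample_id`` with one column per
        ``feature_id``. Non-negative; NaN marks a missing (undetected)
        peak prior to zero imputation.
    sample_meta
        DataFrame indexed by ``sample_id`` carrying at least ``pmi_days``
        (integer days, >= 0), ``sex`` and ``platform``.
    feature_meta
        DataFrame indexed by ``feature_id`` carrying ``mz_median``
        (Da/charge) and ``rt_median`` (seconds).
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    #: True once the values are z-scores rather than raw intensities;
    #: lifts the non-negativity invariant.
    standardized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        ix, sm, fm = self.intensities, self.sample_meta, self.feature_meta
        if not ix.index.is_unique:
            raise TableValidationError("sample ids are not unique")
        if not ix.columns.is_unique:
            raise TableValidationError("feature ids are not unique")
        if not ix.index.equals(sm.index):
            raise TableValidationError(
                "intensity rows and sample_meta are not aligned"
            )
        if not ix.columns.equals(fm.index):
            raise TableValidationError(
                "intensity columns and feature_meta are not aligned"
            )
        missing = [c for c in SAMPLE_META_COLUMNS if c not in sm.columns]
        if missing:
            raise TableValidationError(f"sample_meta lacks columns {missing}")
        missing = [c for c in FEATURE_META_COLUMNS if c not in fm.columns]
        if missing:
            raise TableValidationError(f"feature_meta lacks columns {missing}")
        if not self.standardized:
            vals = ix.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise TableValidationError("negative intensity encountered")
        if (sm["pmi_days"].to_numpy() < 0).any():
            raise TableValidationError("negative PMI encountered")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def pmi(self) -> np.ndarray:
        """Per-sample PMI in integer days, aligned with intensity rows."""
        return self.sample_meta["pmi_days"].to_numpy()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.sample_meta.copy(),
            self.feature_meta.copy(),
            standardized=self.standardized,
        )

    def subset_samples(self, mask) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[mask].copy(),
            self.sample_meta.loc[mask].copy(),
            self.feature_meta.copy(),
            standardized=self.standardized,
        )

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    # -- three-CSV round trip -------------------------------------------
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.intensities.rename_axis("sample_id").to_csv(
            directory / "intensities.csv"
        )
        self.sample_meta.rename_axis("sample_id").to_csv(
            directory / "samples.csv"
        )
        self.feature_meta.rename_axis("feature_id").to_csv(
            directory / "features.csv"
        )
        (directory / "table_meta.json").write_text(
            json.dumps({"standardized": self.standardized})
        )

    @classmethod
    def read(cls, directory: str | Path) -> "FeatureTable":
        directory = Path(directory)
        ix = pd.read_csv(directory / "intensities.csv", index_col="sample_id")
        sm = pd.read_csv(directory / "samples.csv", index_col="sample_id")
        fm = pd.read_csv(directory / "features.csv", index_col="feature_id")
        ix.index = ix.index.astype(str)
        sm.index = sm.index.astype(str)
        ix.columns = ix.columns.astype(str)
        fm.index = fm.index.astype(str)
        meta_path = directory / "table_meta.json"
        standardized = (
            json.loads(meta_path.read_text()).get("standardized", False)
            if meta_path.exists()
            else False
        )
        return cls(ix, sm.loc[ix.index], fm.loc[ix.columns], standardized=standardized)


@dataclass
class NormalizationParams:
    """Per-feature mean/SD of log intensities, with the feature order.

    Required to project any new data into the space a model was trained
    in. ``ddof`` records the SD denominator convention (1 = sample SD).
    Constant features carry ``sd == 0`` and a flag; standardizing maps
    them to all-zero columns rather than dropping them.
    """

    mean: np.ndarray
    sd: np.ndarray
    feature_order: list[str]
    ddof: int = 1
    constant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.constant is None:
            self.constant = self.sd == 0
        self.constant = np.asarray(self.constant, dtype=bool)
        n = len(self.feature_order)
        if not (len(self.mean) == len(self.sd) == len(self.constant) == n):
            raise TableValidationError(
                "NormalizationParams fields have inconsistent lengths"
            )
        if (self.sd < 0).any():
            raise TableValidationError("negative standard deviation")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_order": list(self.feature_order),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "ddof": self.ddof,
            "constant": self.constant.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        doc = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(doc["mean"], dtype=float),
            sd=np.asarray(doc["sd"], dtype=float),
            feature_order=[str(f) for f in doc["feature_order"]],
            ddof=int(doc["ddof"]),
            constant=np.asarray(doc["constant"], dtype=bool),
        )
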