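"""Cross-platform feature harmonization by m/z and retention time.

A feature measured on a new instrument is identified with a reference
feature when it falls inside an m/z window (ppm or Daltons) *and* an RT
window (seconds); among such candidates the one with the minimal
weighted squared distance

    d = (dmz / mz_scale)^2 + (drt / rt_scale)^2

is selected. Scales default to the window half-widths so both terms are
dimensionless and equal 1 at the window edge. Reference features with
no candidate are zero-filled (raw intensity 0, i.e. below LOD) before
the reference normalization is applied, so a harmonized table can be
fed straight into a model trained on the reference platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import apply_standardizer, impute_missing_zero, log_transform
from .tables import FeatureTable, NormalizationParams


class HarmonizationError(ValueError):
    pass


@dataclass(frozen=True)
class MatchTolerance:
    """Matching windows and distance scales.

    ``mz_window`` is in ppm of the reference m/z when ``mz_mode='ppm'``
    (default, 5 ppm) or absolute Daltons when ``mz_mode='da'``;
    ``rt_window`` is in seconds. ``mz_scale``/``rt_scale`` weight the
    squared distance and default to the window widths.
    """

    mz_window: float = 5.0
    rt_window: float = 30.0
    mz_mode: str = "ppm"
    mz_scale: float | None = None
    rt_scale: float | None = None

    def __post_init__(self) -> None:
        if self.mz_window <= 0 or self.rt_window <= 0:
            raise HarmonizationError("tolerance windows must be positive")
        if self.mz_mode not in ("ppm", "da"):
            raise HarmonizationError(f"unknown mz_mode {self.mz_mode!r}")
        if (self.mz_scale is not None and self.mz_scale <= 0) or (
            self.rt_scale is not None and self.rt_scale <= 0
        ):
            raise HarmonizationError("distance scales must be positive")

    def mz_window_da(self, ref_mz: np.ndarray) -> np.ndarray:
        """Window half-width in Daltons, per reference feature."""
        if self.mz_mode == "ppm":
            return np.asarray(ref_mz) * self.mz_window * 1e-6
        return np.full_like(np.asarray(ref_mz, dtype=float), self.mz_window)

    def mz_scale_da(self, ref_mz: np.ndarray) -> np.ndarray:
        if self.mz_scale is not None:
            return np.full_like(np.asarray(ref_mz, dtype=float), self.mz_scale)
        return self.mz_window_da(ref_mz)

    @property
    def rt_scale_value(self) -> float:
        return self.rt_scale if self.rt_scale is not None else self.rt_window


@dataclass
class FeatureCatalog:
    """Per-feature (median m/z, median RT) coordinates."""

    entries: pd.DataFrame  # index feature_id; columns mz_median, rt_median

    def __post_init__(self) -> None:
        if not self.entries.index.is_unique:
            raise HarmonizationError("catalog feature ids are not unique")
        if (self.entries["mz_median"] <= 0).any():
            raise HarmonizationError("m/z must be positive")
        if (self.entries["rt_median"] < 0).any():
            raise HarmonizationError("RT must be non-negative")

    @classmethod
    def from_table(cls, table: FeatureTable) -> "FeatureCatalog":
        return cls(table.feature_meta[["mz_median", "rt_median"]].copy())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class HarmonizationMap:
    """Per-reference-feature best match on the new platform, or None.

    ``pairs`` has one row per reference feature (in reference order)
    with columns ``new_feature_id`` (NaN when unmatched), ``sq_distance``
    and ``status`` in {matched, unmatched}.
    """

    pairs: pd.DataFrame

    def matched(self) -> pd.DataFrame:
        return self.pairs[self.pairs["status"] == "matched"]

    def collisions(self) -> pd.Series:
        """New features claimed by more than one reference feature."""
        hits = self.matched()["new_feature_id"].value_counts()
        return hits[hits > 1]

    def to_csv(self, path) -> None:
        self.pairs.rename_axis("ref_feature_id").to_csv(path)


def _best_candidate(
    dmz: np.ndarray,
    drt: np.ndarray,
    ids: np.ndarray,
    mz_win: float,
    rt_win: float,
    mz_scale: float,
    rt_scale: float,
) -> tuple[str | None, float]:
    """Minimal weighted squared distance inside both windows.

    Ties broken by smaller |dmz|, then lexicographic new feature id.
    """
    inside = (np.abs(dmz) <= mz_win) & (np.abs(drt) <= rt_win)
    if not inside.any():
        return None, np.nan
    d = (dmz[inside] / mz_scale) ** 2 + (drt[inside] / rt_scale) ** 2
    cand_ids = ids[inside]
    cand_admz = np.abs(dmz[inside])
    order = np.lexsort((cand_ids, cand_admz, d))
    best = order[0]
    return str(cand_ids[best]), float(d[best])


def match_features(
    ref: FeatureCatalog,
    new: FeatureCatalog,
    tol: MatchTolerance = MatchTolerance(),
    one_to_one: bool = False,
) -> HarmonizationMap:
    """Match every reference feature to its nearest new-platform feature.

    By default two reference features may select the same new feature
    (collisions are queryable on the result); ``one_to_one=True``
    resolves collisions greedily by ascending distance.
    """
    if len(ref) == 0 or len(new) == 0:
        raise HarmonizationError("catalogs must be non-empty")
    ref_mz = ref.entries["mz_median"].to_numpy(dtype=float)
    ref_rt = ref.entries["rt_median"].to_numpy(dtype=float)
    new_mz = new.entries["mz_median"].to_numpy(dtype=float)
    new_rt = new.entries["rt_median"].to_numpy(dtype=float)
    new_ids = new.entries.index.to_numpy(dtype=object)
    mz_wins = tol.mz_window_da(ref_mz)
    mz_scales = tol.mz_scale_da(ref_mz)

    rows = []
    for i in range(len(ref_mz)):
        nid, d = _best_candidate(
            new_mz - ref_mz[i],
            new_rt - ref_rt[i],
            new_ids,
            mz_wins[i],
            tol.rt_window,
            mz_scales[i],
            tol.rt_scale_value,
        )
        rows.append((nid, d))
    pairs = pd.DataFrame(
        rows, index=ref.entries.index, columns=["new_feature_id", "sq_distance"]
    )
    pairs["status"] = np.where(
        pairs["new_feature_id"].notna(), "matched", "unmatched"
    )

    if one_to_one:
        taken: set[str] = set()
        matched = pairs[pairs["status"] == "matched"]
        order = matched.sort_values(
            ["sq_distance", "new_feature_id"], kind="mergesort"
        ).index
        for rid in order:
            nid = pairs.at[rid, "new_feature_id"]
            if nid in taken:
                pairs.at[rid, "new_feature_id"] = None
                pairs.at[rid, "sq_distance"] = np.nan
                pairs.at[rid, "status"] = "unmatched"
            else:
                taken.add(nid)
    return HarmonizationMap(pairs)


def project_table(
    new_table: FeatureTable,
    hmap: HarmonizationMap,
    ref_params: NormalizationParams,
    ref_catalog: FeatureCatalog | None = None,
) -> FeatureTable:
    """Reorder a new-platform table into the reference feature space.

    Matched reference columns carry the new platform's raw intensities;
    unmatched columns are zero-filled (below-LOD semantics). The result
    is log-transformed and standardized with the *reference* parameters,
    so it is directly consumable by a reference-trained model.
    """
    ref_order = list(ref_params.feature_order)
    missing_in_map = [r for r in ref_order if r not in hmap.pairs.index]
    if missing_in_map:
        raise HarmonizationError(
            f"harmonization map lacks reference feature {missing_in_map[0]!r}"
        )
    imputed, _ = impute_missing_zero(new_table)
    n = imputed.n_samples
    raw = np.zeros((n, len(ref_order)))
    for j, rid in enumerate(ref_order):
        nid = hmap.pairs.at[rid, "new_feature_id"]
        if pd.isna(nid):
            continue
        if nid not in imputed.intensities.columns:
            raise HarmonizationError(
                f"mapped feature {nid!r} absent from the new table"
            )
        raw[:, j] = imputed.intensities[nid].to_numpy(dtype=float)
    z = apply_standardizer(log_transform(raw), ref_params)
    if ref_catalog is not None:
        fmeta = ref_catalog.entries.loc[ref_order].copy()
    else:
        fmeta = pd.DataFrame(
            {"mz_median": np.nan, "rt_median": np.nan},
            index=pd.Index(ref_order, name="feature_id"),
        )
    return FeatureTable(
        pd.DataFrame(z, index=imputed.intensities.index, columns=pd.Index(ref_order, name="feature_id")),
        imputed.sample_meta.copy(),
        fmeta,
        standardized=True,
    )


def overlap_report(hmap: HarmonizationMap, new: FeatureCatalog) -> dict[str, int]:
    """Counts of matched / unmatched reference and exclusive new features."""
    matched_ids = set(hmap.matched()["new_feature_id"])
    n_matched = int((hmap.pairs["status"] == "matched").sum())
    report = {
        "n_matched": n_matched,
        "n_unmatched_ref": int(len(hmap.pairs) - n_matched),
        "n_exclusive_new": int(len(new) - len(matched_ids)),
        "n_collisions": int(len(hmap.collisions())),
    }
    assert report["n_matched"] + report["n_unmatched_ref"] == len(hmap.pairs)
    return report
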