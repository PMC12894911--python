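"""Feature screening and pseudo-time trend clustering.

Features whose attention-gate activations (or standardized abundances)
correlate with PMI — Spearman rank correlation, Benjamini-Hochberg
controlled at ``alpha`` — are retained. For the retained features a
pseudo-time series is built by averaging the standardized abundance
over all individuals sharing the same PMI day, and the resulting
trajectories are grouped by agglomerative (Ward) clustering into trend
classes: decreasing, increasing, or fluctuating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .tables import FeatureTable

TREND_LABELS = ("decreasing", "increasing", "fluctuating")


class PseudoTimeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class FeatureScreenResult:
    """Per-feature Spearman rho, p-values and BH selection at alpha."""

    table: pd.DataFrame  # index feature_id: rho, p_value, p_adjusted, selected, constant
    alpha: float

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def to_csv(self, path) -> None:
        self.table.rename_axis("feature_id").to_csv(path)


def benjamini_hochberg(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-up false-discovery-rate control; returns the rejection mask.

    The largest i with p_(i) <= i * alpha / m defines the rejections.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise PseudoTimeError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="mergesort")
    thresholds = (np.arange(1, m + 1) / m) * alpha
    passing = np.nonzero(p[order] <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def bh_adjusted(p_values: np.ndarray) -> np.ndarray:
    """Monotone step-up adjusted p-values (min over j>=i of m p_(j)/j)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def spearman_screen(
    activations: np.ndarray,
    pmi: np.ndarray,
    alpha: float = 0.05,
    feature_ids=None,
) -> FeatureScreenResult:
    """Tie-corrected Spearman correlation of every feature with PMI.

    Two-sided p-values come from the t approximation on ranks; the
    selection set is the BH rejection set at ``alpha``. Constant columns
    have undefined rho and are flagged and excluded from selection.
    """
    A = np.asarray(activations, dtype=float)
    pmi = np.asarray(pmi, dtype=float)
    if A.shape[0] != len(pmi):
        raise PseudoTimeError("activation rows do not align with PMI vector")
    n, m = A.shape
    if feature_ids is None:
        feature_ids = [f"F{i}" for i in range(m)]
    constant = np.ptp(A, axis=0) == 0
    ranks = stats.rankdata(A, axis=0)
    r_pmi = stats.rankdata(pmi)
    rz = (ranks - ranks.mean(axis=0)) / np.where(
        ranks.std(axis=0) > 0, ranks.std(axis=0), 1.0
    )
    pz = (r_pmi - r_pmi.mean()) / r_pmi.std()
    rho = (rz * pz[:, None]).mean(axis=0)
    rho[constant] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p[constant] = np.nan

    valid = ~constant
    p_adj = np.full(m, np.nan)
    selected = np.zeros(m, dtype=bool)
    if valid.any():
        p_adj[valid] = bh_adjusted(p[valid])
        selected[valid] = benjamini_hochberg(p[valid], alpha)
    table = pd.DataFrame(
        {
            "rho": rho,
            "p_value": p,
            "p_adjusted": p_adj,
            "selected": selected,
            "constant": constant,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return FeatureScreenResult(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# Pseudo-time series
# ---------------------------------------------------------------------------

@dataclass
class PseudoTimeSeries:
    """Feature x PMI-day matrix of mean standardized abundance."""

    values: pd.DataFrame  # index feature_id, columns integer PMI days
    counts: pd.Series  # samples per retained PMI day

    @property
    def pmi_grid(self) -> np.ndarray:
        return self.values.columns.to_numpy()

    def to_csv(self, path) -> None:
        self.values.rename_axis("feature_id").to_csv(path)


def build_pseudotime(
    table: FeatureTable,
    selected_features,
    pmi_filter: tuple[int, int] | None = None,
    min_count: int = 5,
) -> PseudoTimeSeries:
    """Average each feature over individuals sharing the same PMI day.

    ``pmi_filter`` restricts the grid to an inclusive day range;
    independently, days with fewer than ``min_count`` samples are
    dropped to stabilize the means (set ``min_count=1`` for the full
    grid).
    """
    selected = [str(f) for f in selected_features]
    missing = [f for f in selected if f not in table.intensities.columns]
    if missing:
        raise PseudoTimeError(f"feature {missing[0]!r} absent from table")
    sub = table.intensities[selected]
    pmi = pd.Series(table.pmi, index=sub.index, name="pmi")
    grouped = sub.groupby(pmi).mean()
    counts = sub.groupby(pmi).size()
    keep = counts >= min_count
    if pmi_filter is not None:
        keep &= (counts.index >= pmi_filter[0]) & (counts.index <= pmi_filter[1])
    grid = counts.index[keep]
    if len(grid) == 0:
        raise PseudoTimeError("empty PMI grid after filtering")
    return PseudoTimeSeries(values=grouped.loc[grid].T, counts=counts[keep])


# ---------------------------------------------------------------------------
# Trend clustering
# ---------------------------------------------------------------------------

@dataclass
class TrendClusters:
    """Cluster assignment of pseudo-time trajectories, cut at k."""

    k: int
    assignments: pd.Series  # index feature_id, cluster id in 1..k
    linkage_matrix: np.ndarray
    method: str = "ward"
    metric: str = "euclidean"
    labels: pd.Series | None = None  # cluster id -> trend label

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def feature_labels(self) -> pd.Series:
        """Per-feature trend label (requires label_trends)."""
        if self.labels is None:
            raise PseudoTimeError("clusters are unlabelled; run label_trends")
        return self.assignments.map(self.labels)

    def to_newick(self) -> str:
        """Dendrogram as a newick string (leaf names = feature ids)."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        names = list(self.assignments.index)

        def walk(node) -> str:
            if node.is_leaf():
                return f"{names[node.id]}:{node.dist:.6g}"
            return (
                f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"
            )

        return f"({walk(tree.left)},{walk(tree.right)});"


def _row_zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def cluster_trajectories(
    pts: PseudoTimeSeries,
    k: int = 3,
    method: str = "ward",
    metric: str = "euclidean",
    zscore_rows: bool = True,
) -> TrendClusters:
    """Agglomerative clustering of feature trajectories, tree cut at k.

    Rows are z-scored first (default) so clusters group by *shape*
    rather than amplitude. Deterministic for a given linkage/metric.
    """
    X = pts.values.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise PseudoTimeError(f"k={k} exceeds {X.shape[0]} features")
    if zscore_rows:
        X = _row_zscore(X)
    Z = hierarchy.linkage(X, method=method, metric=metric)
    ids = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(ids, index=pts.values.index, name="cluster")
    return TrendClusters(
        k=k, assignments=assignments, linkage_matrix=Z, method=method, metric=metric
    )


def label_trends(
    clusters: TrendClusters, pts: PseudoTimeSeries, tau: float = 0.6
) -> TrendClusters:
    """Name each cluster by the monotonicity of its mean trajectory.

    Spearman rho of the cluster-mean trajectory against the PMI grid:
    rho <= -tau -> decreasing, rho >= tau -> increasing, otherwise
    fluctuating.
    """
    grid = pts.pmi_grid.astype(float)
    labels = {}
    for cid in sorted(clusters.assignments.unique()):
        members = clusters.assignments.index[clusters.assignments == cid]
        mean_traj = pts.values.loc[members].mean(axis=0).to_numpy()
        rho = stats.spearmanr(mean_traj, grid).statistic
        if rho <= -tau:
            labels[cid] = "decreasing"
        elif rho >= tau:
            labels[cid] = "increasing"
        else:
            labels[cid] = "fluctuating"
    clusters.labels = pd.Series(labels, name="trend")
    return clusters
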