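"""Standardized PCA on the nine map metrics and Ward clustering on scores.

The nine active variables mix counts (components, links) with proportions,
so the PCA is run on the correlation matrix (variables centered and scaled
to unit variance); the total inertia then equals the number of active
variables.  The respondent's stakeholder group takes no part in axis
construction — it is projected afterwards as supplementary-category
centroids in score space.

Clustering is hierarchical (Ward linkage, Euclidean distances) in the
space of the retained principal-component scores, with an automatic choice
of the number of clusters by the inertia-gain ratio, and an optional
k-means consolidation step (off by default so results stay reproducible
from the linkage alone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

from .metrics import METRIC_COLUMNS
from .model import ValidationError

ACTIVE_COLUMNS = METRIC_COLUMNS


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    scores: pd.DataFrame  # respondents x Dim1..Dimp (principal coordinates)
    loadings: pd.DataFrame  # variables x axes (correlations with axes)
    supplementary_coords: pd.DataFrame | None = None

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    @property
    def percent_variance(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    @property
    def cumulative_percent(self) -> np.ndarray:
        return np.cumsum(self.percent_variance)

    def n_axes_for(self, retain) -> int:
        """Number of axes: an int is taken as-is, a fraction as the smallest
        axis count whose cumulative explained variance reaches it."""
        if isinstance(retain, (int, np.integer)) and not isinstance(retain, bool):
            if not 1 <= retain <= self.n_axes:
                raise ValidationError(f"retained axis count {retain} out of range")
            return int(retain)
        target = 100.0 * float(retain)
        return int(np.searchsorted(self.cumulative_percent, target - 1e-9) + 1)


def run_pca(
    table: pd.DataFrame,
    supplementary: pd.Series | str | None = "respondent_group",
    active_columns=ACTIVE_COLUMNS,
) -> PcaResult:
    """Correlation PCA of the active metrics.

    Axis signs are fixed deterministically: on each axis, the variable
    with the largest absolute loading loads positively.  A zero-variance
    column cannot be standardized and raises an error naming it.
    """
    active = list(active_columns)
    missing = [c for c in active if c not in table.columns]
    if missing:
        raise ValidationError(f"metrics table missing columns {missing}")
    X = table[active].to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValidationError("PCA requires at least 3 rows")
    if np.isnan(X).any():
        raise ValidationError("metrics table contains missing values")
    std = X.std(axis=0, ddof=0)
    constant = [active[j] for j in range(p) if std[j] == 0]
    if constant:
        raise ValidationError(f"constant (zero-variance) column(s): {constant}")
    Z = (X - X.mean(axis=0)) / std
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / n  # eigenvalues of the correlation matrix
    scores = U * s
    loadings = Vt.T * np.sqrt(eig)
    for j in range(len(eig)):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    axes = [f"Dim{j + 1}" for j in range(len(eig))]
    scores_df = pd.DataFrame(scores, index=table.index.copy(), columns=axes)
    loadings_df = pd.DataFrame(loadings, index=pd.Index(active, name="variable"), columns=axes)
    sup_df = None
    if supplementary is not None:
        if isinstance(supplementary, str):
            if supplementary not in table.columns:
                raise ValidationError(f"supplementary column {supplementary!r} not in table")
            sup = table[supplementary]
        else:
            sup = pd.Series(supplementary).reindex(table.index)
        sup_df = scores_df.groupby(sup.to_numpy()).mean()
        sup_df.index.name = "category"
    return PcaResult(
        eigenvalues=eig, scores=scores_df, loadings=loadings_df, supplementary_coords=sup_df
    )


@dataclass
class ClusterResult:
    labels: pd.Series  # respondent -> cluster label (1..k)
    linkage_matrix: np.ndarray
    k: int
    n_axes: int
    within_inertia: float
    between_inertia: float
    total_inertia: float

    def members(self, label) -> list:
        return list(self.labels.index[self.labels == label])


def _within_inertia(points: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        cluster = points[labels == lab]
        total += ((cluster - cluster.mean(axis=0)) ** 2).sum()
    return float(total)


def hcpc(
    pca: PcaResult,
    retain=0.8,
    k="auto",
    kmax: int | None = None,
    consolidate: bool = False,
    seed: int = 0,
) -> ClusterResult:
    """Hierarchical clustering on retained principal-component scores.

    ``k="auto"`` scans k in [2, kmax] and picks the k with the largest
    relative gain of between-inertia, i.e. minimizing W(k)/W(k-1) (the
    within-inertia kept after the cut relative to before it) — the rule
    the reference HCPC implementation uses to suggest a partition.
    ``consolidate`` reassigns points by k-means started from the
    hierarchical cluster centroids (seeded, so the pipeline stays
    deterministic).
    """
    ncp = pca.n_axes_for(retain)
    S = pca.scores.iloc[:, :ncp].to_numpy()
    R = S.shape[0]
    Z = linkage(S, method="ward")
    kmax = min(10, R - 1) if kmax is None else min(kmax, R - 1)
    if k == "auto":
        if kmax < 2:
            raise ValidationError("too few respondents for automatic k")
        within = {
            kk: _within_inertia(S, fcluster(Z, kk, criterion="maxclust"))
            for kk in range(1, kmax + 1)
        }
        best, best_ratio = 2, np.inf
        for kk in range(2, kmax + 1):
            ratio = within[kk] / max(within[kk - 1], 1e-12)
            if ratio < best_ratio:
                best, best_ratio = kk, ratio
        k = best
    k = int(k)
    if not 1 <= k <= R:
        raise ValidationError(f"k={k} outside [1, {R}]")
    flat = fcluster(Z, k, criterion="maxclust")
    if consolidate and k >= 2:
        from sklearn.cluster import KMeans

        centroids = np.vstack([S[flat == lab].mean(axis=0) for lab in np.unique(flat)])
        km = KMeans(n_clusters=k, init=centroids, n_init=1, random_state=seed).fit(S)
        flat = km.labels_ + 1
    labels = pd.Series(flat, index=pca.scores.index.copy(), name="cluster")
    total = float(((S - S.mean(axis=0)) ** 2).sum())
    within = _within_inertia(S, flat)
    return ClusterResult(
        labels=labels,
        linkage_matrix=Z,
        k=k,
        n_axes=ncp,
        within_inertia=within,
        between_inertia=total - within,
        total_inertia=total,
    )


@dataclass
class ClusterComparison:
    """Per-metric cluster means +/- SD with two-sample t tests, plus the
    composition of each cluster by stakeholder group."""

    stats: pd.DataFrame
    composition: pd.DataFrame


def compare_clusters(
    table: pd.DataFrame,
    clusters,
    test: str = "student",
    active_columns=ACTIVE_COLUMNS,
    holm: bool = False,
) -> ClusterComparison:
    """Compare clusters metric by metric.

    Means and SDs (n-1 denominator) are reported for any number of
    clusters; the two-sided t test (pooled variance for ``"student"``,
    Welch for ``"welch"``) requires exactly two clusters of size >= 2.
    ``holm`` applies a Holm step-down correction across the metrics
    (off by default).
    """
    if test not in ("student", "welch"):
        raise ValidationError(f"unknown test {test!r}")
    labels = clusters.labels if isinstance(clusters, ClusterResult) else pd.Series(clusters)
    labels = labels.reindex(table.index)
    if labels.isna().any():
        raise ValidationError("every respondent needs a cluster label")
    groups = sorted(labels.unique())
    do_test = len(groups) == 2
    if do_test:
        sizes = [int((labels == g).sum()) for g in groups]
        if min(sizes) < 2:
            raise ValidationError("t test requires both clusters to have size >= 2")
    rows = []
    for col in active_columns:
        row: dict = {"metric": col}
        samples = []
        for g in groups:
            values = table.loc[labels == g, col].to_numpy(dtype=float)
            samples.append(values)
            row[f"mean_{g}"] = values.mean()
            row[f"sd_{g}"] = values.std(ddof=1) if len(values) > 1 else np.nan
        if do_test:
            t, p = ttest_ind(samples[0], samples[1], equal_var=(test == "student"))
            row["t"] = float(t)
            row["p_value"] = float(p)
        rows.append(row)
    stats = pd.DataFrame(rows).set_index("metric")
    if do_test and holm:
        from statsmodels.stats.multitest import multipletests

        stats["p_holm"] = multipletests(stats["p_value"].to_numpy(), method="holm")[1]
    if "respondent_group" in table.columns:
        composition = pd.crosstab(labels, table["respondent_group"])
        composition.index.name = "cluster"
    else:
        composition = pd.DataFrame(index=pd.Index(groups, name="cluster"))
    return ClusterComparison(stats=stats, composition=composition)
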