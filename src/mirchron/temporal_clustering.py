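"""Temporal pattern discovery: correlation-based hierarchical clustering.

Dynamic features are grouped by the *shape* of their time-course profile:
per-time-point mean profiles are row-standardized (mean 0, sd 1) and
clustered agglomeratively with distance 1 − Pearson r and average linkage,
then the tree is cut to k clusters (defaults: 6 for mRNA, 5 for miRNA,
the numbers of temporal patterns seen in lung development).  Cluster ids
are renumbered by descending size.  Centroids for human-readable pattern
labels use relative-to-adult profiles (log2 ratio against the Adult time
point) so "peak at E18" means a peak in actual relative expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core_model import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Reserved cluster id for zero-variance (flat) profiles.
FLAT_CLUSTER = 0


def relative_to_adult(x: ExpressionMatrix, reference: str = "Adult") -> pd.DataFrame:
    """Per-time-point mean profiles re-expressed as log2 ratios to Adult.

    On the log2 scale this subtracts each feature's Adult mean, so the
    Adult column is exactly 0; on the linear scale it is the ratio to the
    adult group.  Shift-invariant: adding a constant to a profile does not
    change its relative profile.
    """
    means = x.timepoint_means()
    if reference not in means.columns:
        raise ValueError(f"reference time point {reference!r} missing from the design")
    return means.sub(means[reference], axis=0)


def standardize_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-standardize to mean 0, sd 1; returns (z-profiles, flat ids)."""
    mu = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=0)
    flat = list(profiles.index[sd == 0.0])
    ok = profiles.loc[sd > 0.0]
    z = ok.sub(mu[ok.index], axis=0).div(sd[ok.index], axis=0)
    return z, flat


@dataclass
class ClusteringResult:
    """Assignments (feature → cluster id), centroids, and pattern labels."""

    assignments: pd.Series
    centroids: pd.DataFrame  # cluster × time point, relative-to-adult scale
    labels: dict[int, str]
    linkage_matrix: np.ndarray | None = None

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def cluster_temporal(
    x: ExpressionMatrix, k: int, pattern_eps: float = 0.1
) -> ClusteringResult:
    """Cut an average-linkage, 1 − Pearson dendrogram into k shape clusters.

    Features are sorted by id before clustering so the result is invariant
    to input order.  Zero-variance profiles cannot be standardized and go
    to the reserved flat cluster (id 0) with a warning.  Remaining clusters
    are renumbered 1..k by descending size (ties broken by the smallest
    dendrogram label).
    """
    profiles = x.timepoint_means().sort_index()
    z, flat = standardize_profiles(profiles)
    if flat:
        logger.warning("%d zero-variance profiles assigned to the flat cluster", len(flat))
    if len(z) < k:
        raise ValueError(f"need at least k={k} clusterable features, have {len(z)}")

    if len(z) == 1:
        raw = np.array([1])
        lm = None
    else:
        dists = pdist(z.to_numpy(), metric="correlation")
        lm = linkage(dists, method="average")
        raw = fcluster(lm, t=k, criterion="maxclust")

    # renumber by descending size, ties by smallest original label
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    assigned = pd.Series([relabel[c] for c in raw], index=z.index, name="cluster")
    if flat:
        assigned = pd.concat(
            [assigned, pd.Series(FLAT_CLUSTER, index=flat, name="cluster")]
        )
    assigned = assigned.sort_index()

    rel = relative_to_adult(x).sort_index()
    centroids = rel.groupby(assigned).mean()
    labels = {
        int(c): ("flat" if c == FLAT_CLUSTER else label_temporal_pattern(
            centroids.loc[c].to_numpy(), list(rel.columns), eps=pattern_eps))
        for c in centroids.index
    }
    return ClusteringResult(
        assignments=assigned, centroids=centroids, labels=labels, linkage_matrix=lm
    )


def label_temporal_pattern(
    centroid: Sequence[float], timepoints: Sequence[str], eps: float = 0.1
) -> str:
    """Verbal shape label for a time-course centroid.

    monotone_up / monotone_down when the profile is non-decreasing /
    non-increasing within tolerance ``eps`` and moves overall by more than
    ``eps``; otherwise peak_at:<tp> (interior maximum above both endpoints
    by ≥ eps), then trough_at:<tp>, else "other".
    """
    c = np.asarray(centroid, dtype=float)
    if len(c) != len(timepoints):
        raise ValueError("centroid and time point axis lengths differ")
    d = np.diff(c)
    if np.all(d >= -eps) and (c[-1] - c[0]) > eps:
        return "monotone_up"
    if np.all(d <= eps) and (c[0] - c[-1]) > eps:
        return "monotone_down"
    i = int(np.argmax(c))
    if 0 < i < len(c) - 1 and c[i] - c[0] >= eps and c[i] - c[-1] >= eps:
        return f"peak_at:{timepoints[i]}"
    j = int(np.argmin(c))
    if 0 < j < len(c) - 1 and c[0] - c[j] >= eps and c[-1] - c[j] >= eps:
        return f"trough_at:{timepoints[j]}"
    return "other"
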