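"""Autonomous two-class labeling of band-flux features by k-means.

k-means (k=2, squared Euclidean, k-means++ initialization) partitions the
targets without histology; a phenomenological rule then names the clusters:
the cluster whose centroid has lost high-wavenumber C-H signal is tumor,
and for fingerprint-only features the cluster whose 796/828 centroid flux
ratio favors the DNA|RNA band is tumor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import ValidationError
from .features import BandSet, FeatureMatrix, default_band_set

HEALTHY = "healthy"
TUMOR = "tumor"


@dataclass
class ClusterModel:
    """A fitted 2-cluster k-means model over one feature matrix."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    seed: int
    feature_set: str
    label_map: dict[int, str] | None = None

    def labels(self) -> list[str]:
        """Per-target healthy/tumor labels (requires a label_map)."""
        if self.label_map is None:
            raise ValidationError("cluster semantics not mapped yet")
        return [self.label_map[int(a)] for a in self.assignments]


def fit_kmeans(
    features: FeatureMatrix, seed: int = 0, n_restarts: int = 10
) -> ClusterModel:
    """k-means with k=2; best of ``n_restarts`` k-means++ runs.

    Restart r uses random state seed+r; the run with minimal within-cluster
    squared Euclidean inertia wins, so repeated calls with the same seed
    are identical.
    """
    X = features.values
    if len(np.unique(X, axis=0)) < 2:
        raise ValidationError("k-means undefined: all feature rows identical")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    best = None
    for r in range(n_restarts):
        km = KMeans(
            n_clusters=2,
            init="k-means++",
            n_init=1,
            max_iter=300,
            algorithm="lloyd",
            random_state=seed + r,
        ).fit(X)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    return ClusterModel(
        k=2,
        centroids=best.cluster_centers_.copy(),
        assignments=best.labels_.copy(),
        inertia=float(best.inertia_),
        seed=seed,
        feature_set=features.feature_set,
    )


def map_cluster_labels(
    model: ClusterModel,
    bands: BandSet | None = None,
    feature_set: str | None = None,
) -> ClusterModel:
    """Attach healthy/tumor semantics to the anonymous clusters.

    For feature sets containing HW bands the centroid with the smaller
    mean HW flux is tumor (high-wavenumber collapse). For FP-only
    features the centroid with the larger flux(796)/flux(828) ratio is
    tumor (relative DNA|RNA rise). An exact tie labels cluster 0 tumor,
    with a warning.
    """
    bands = bands or default_band_set()
    feature_set = feature_set or model.feature_set
    group = bands.group_indices(feature_set)
    centers = [bands.bands[i][0] for i in group]
    hw_cols = [
        j for j, c in enumerate(centers) if 2800.0 <= c <= 3000.0
    ]
    if model.centroids.shape[1] != len(centers):
        raise ValidationError(
            f"centroid width {model.centroids.shape[1]} does not match "
            f"feature set {feature_set} ({len(centers)} bands)"
        )
    if hw_cols:
        score = model.centroids[:, hw_cols].mean(axis=1)
        # smaller mean HW flux => tumor
        tumor_cluster = int(np.argmin(score))
        tie = score[0] == score[1]
    else:
        try:
            i796 = centers.index(796.0)
            i828 = centers.index(828.0)
        except ValueError as exc:
            raise ValidationError(
                "FP-only labeling needs the 796 and 828 cm^-1 bands"
            ) from exc
        ratio = model.centroids[:, i796] / model.centroids[:, i828]
        tumor_cluster = int(np.argmax(ratio))
        tie = ratio[0] == ratio[1]
    if tie:
        warnings.warn(
            "cluster-labeling criterion tied exactly; labeling cluster 0 tumor",
            stacklevel=2,
        )
        tumor_cluster = 0
    label_map = {
        tumor_cluster: TUMOR,
        1 - tumor_cluster: HEALTHY,
    }
    return replace(model, label_map=label_map)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with tumor as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int


def compare_partitions(
    predicted: Sequence[str], reference: Sequence[str]
) -> ConfusionCounts:
    """Confusion counts of a predicted labeling against a reference."""
    if len(predicted) != len(reference):
        raise ValidationError("predicted and reference labelings differ in length")
    for lab in list(predicted) + list(reference):
        if lab not in (HEALTHY, TUMOR):
            raise ValidationError(f"label {lab!r} not in {{healthy, tumor}}")
    tp = fn = tn = fp = 0
    for p, r in zip(predicted, reference):
        if r == TUMOR:
            if p == TUMOR:
                tp += 1
            else:
                fn += 1
        else:
            if p == HEALTHY:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp, fn, tn, fp)
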