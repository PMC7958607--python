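"""Rhythm profiling: feature standardization, k-means clustering, diagnostics
and deterministic semantic labeling of the four canonical profiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

from .cosine import CosineFitResult
from .errors import ConfigError, DataError, DegenerateFeatureError

logger = logging.getLogger(__name__)

#: the eight per-participant rhythm features used for profiling
DEFAULT_FEATURES = (
    "alpha",
    "beta",
    "acrophase",
    "amplitude",
    "mesor",
    "up_mesor",
    "down_mesor",
    "pseudo_f",
)

TIMING_FEATURES = ("up_mesor", "acrophase", "down_mesor")
ACTIVITY_FEATURES = ("amplitude", "mesor", "pseudo_f")

LABEL_LESS_ACTIVE = "Less Active/Robust"
LABEL_EARLIER = "Earlier Risers"
LABEL_MORE_ACTIVE = "More Active/Robust"
LABEL_LATER = "Later RAR"


@dataclass(frozen=True)
class FeatureMatrix:
    ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # n x p
    standardized: bool = False
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.ids), len(self.feature_names)):
            raise DataError("feature matrix shape does not match ids/names")
        if np.isnan(values).any():
            raise DataError("feature matrix contains missing values")
        object.__setattr__(self, "values", values)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


@dataclass(frozen=True)
class ClusterModel:
    k: int
    centroids: np.ndarray  # k x p, standardized units
    assignments: dict[str, int]
    within_ss: float
    seed: int
    feature_names: tuple[str, ...]
    labels: dict[int, str] = field(default_factory=dict)


def features_from_fits(
    fits: dict[str, CosineFitResult], log_beta: bool = False
) -> FeatureMatrix:
    """Build the profiling feature matrix from converged fits.

    Participants with non-converged fits are excluded (logged). ``mesor``
    enters on the log-count scale; ``beta`` raw by default with an ln-scale
    switch.
    """
    rows, ids = [], []
    for pid in sorted(fits):
        r = fits[pid]
        if not r.converged:
            logger.info("excluding %s from profiling: fit not converged", pid)
            continue
        ids.append(pid)
        rows.append(
            [
                r.params.alpha,
                np.log(r.params.beta) if log_beta else r.params.beta,
                r.params.phi,
                r.params.amp,
                r.mesor_log,
                r.up_mesor,
                r.down_mesor,
                r.pseudo_f,
            ]
        )
    return FeatureMatrix(
        ids=tuple(ids), feature_names=DEFAULT_FEATURES, values=np.array(rows)
    )


def standardize_features(raw: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-scores with sample SD (n-1 denominator)."""
    if len(raw.ids) < 2:
        raise DataError("need at least 2 participants to standardize")
    center = raw.values.mean(axis=0)
    scale = raw.values.std(axis=0, ddof=1)
    dead = np.flatnonzero(scale == 0)
    if dead.size:
        names = ", ".join(raw.feature_names[i] for i in dead)
        raise DegenerateFeatureError(f"zero-variance feature column(s): {names}")
    return replace(
        raw,
        values=(raw.values - center) / scale,
        standardized=True,
        center=center,
        scale=scale,
    )


def kmeans_fit(
    features: FeatureMatrix,
    k: int = 4,
    n_restarts: int = 100,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-restarts Lloyd k-means on standardized features.

    Deterministic given ``seed``; keeps the restart with the lowest within-
    cluster sum of squares.
    """
    n = len(features.ids)
    if not 1 <= k <= n:
        raise ConfigError(f"k={k} incompatible with n={n} participants")
    if not features.standardized:
        raise DataError("features must be standardized before clustering")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=seed,
        init="k-means++",
        algorithm="lloyd",
    ).fit(features.values)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments={pid: int(c) for pid, c in zip(features.ids, km.labels_)},
        within_ss=float(km.inertia_),
        seed=seed,
        feature_names=features.feature_names,
    )


def cluster_diagnostics(
    features: FeatureMatrix,
    k_range: range = range(1, 11),
    seed: int = 0,
    n_restarts: int = 20,
) -> dict:
    """Cluster-count diagnostics: elbow curve, PCA spectrum, Ward heights,
    and participant coordinates on the first two principal components."""
    if not features.standardized:
        raise DataError("features must be standardized")
    X = features.values
    n = X.shape[0]
    within = []
    for k in k_range:
        if k > n:
            break
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        within.append(float(km.inertia_))
    Xc = X - X.mean(axis=0)
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = svals**2 / (n - 1)
    cumvar = np.cumsum(eigvals) / eigvals.sum()
    pc_coords = Xc @ vt[:2].T
    ward = linkage(X, method="ward") if n >= 2 else np.empty((0, 4))
    return {
        "k_range": list(k_range)[: len(within)],
        "within_ss": within,
        "pca_eigenvalues": eigvals.tolist(),
        "pca_cumulative_variance": cumvar.tolist(),
        "ward_heights": ward[:, 2].tolist(),
        "pc_coordinates": {
            pid: [float(a), float(b)] for pid, (a, b) in zip(features.ids, pc_coords)
        },
    }


def label_clusters(model: ClusterModel) -> ClusterModel:
    """Assign the four semantic profile names by centroid signature.

    Rule (fixed order, ties broken by lowest cluster id): the cluster with
    the largest mean timing z-score (up mesor, acrophase, down mesor) is
    "Later RAR"; among the rest, the largest mean activity/rhythmicity
    z-score (amplitude, mesor, pseudo-F) is "More Active/Robust" and the
    smallest is "Less Active/Robust"; the remaining cluster is
    "Earlier Risers".
    """
    if model.k != 4:
        logger.warning("label_clusters requires k=4; got k=%d, leaving labels empty",
                       model.k)
        return model
    names = model.feature_names
    timing_ix = [names.index(f) for f in TIMING_FEATURES]
    activity_ix = [names.index(f) for f in ACTIVITY_FEATURES]
    timing = model.centroids[:, timing_ix].mean(axis=1)
    activity = model.centroids[:, activity_ix].mean(axis=1)

    remaining = list(range(model.k))
    later = min(remaining, key=lambda c: (-timing[c], c))
    remaining.remove(later)
    more = min(remaining, key=lambda c: (-activity[c], c))
    remaining.remove(more)
    less = min(remaining, key=lambda c: (activity[c], c))
    remaining.remove(less)
    (earlier,) = remaining
    labels = {
        later: LABEL_LATER,
        more: LABEL_MORE_ACTIVE,
        less: LABEL_LESS_ACTIVE,
        earlier: LABEL_EARLIER,
    }
    return replace(model, labels=labels)


def cluster_assignments_frame(model: ClusterModel) -> pd.DataFrame:
    rows = [
        {
            "participant_id": pid,
            "cluster_id": cid,
            "label": model.labels.get(cid, ""),
        }
        for pid, cid in sorted(model.assignments.items())
    ]
    return pd.DataFrame(rows, columns=["participant_id", "cluster_id", "label"])
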