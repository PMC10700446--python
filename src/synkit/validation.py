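"""Automated validity classification of consistency-test response data.

Consistency scores are only interpretable when a participant actually
engaged with the test: gave enough complete responses and used more than
one or two colors. This module classifies each participant's data as valid
or invalid by clustering their response colors with DBSCAN (Euclidean
neighborhoods in the working color space) and summarizing within-cluster
spread with a total within-cluster variance (TWCV) statistic

    TWCV = sum over non-noise clusters c of (1/n_c) * sum_{x in c} ||x - mu_c||^2,

i.e., the sum over clusters of the mean squared distance to the cluster
centroid (0 when no cluster forms). Points too isolated to join any
cluster are collected in a noise "cluster" labelled -1.

The decision procedure, applied in order:

1. too few complete graphemes → invalid (``too_few_complete_graphemes``);
2. cluster the responses; if one cluster holds at least
   ``max_prop_single_cluster`` of all responses (noise included in the
   denominator) → invalid (``dominant_color_cluster``);
3. if fewer than ``min_num_clusters`` clusters formed AND TWCV is below
   ``safe_twcv`` → invalid (``too_few_distinct_colors``);
4. otherwise valid.

The TWCV escape hatch in step 3 covers participants whose colors are so
scattered that no cluster forms (all noise, TWCV computed over clusters is
0 would wrongly flag them — hence the threshold is only consulted together
with the cluster count, and ``safe_twcv`` should be calibrated for the
working space; the defaults below are calibrated for CIELUV).

Determinism: points are processed in input order, the eps-neighborhood is
inclusive (d <= eps), border points join the first cluster that reaches
them, and cluster ids follow discovery order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .colorspace import ColorPoint, srgb_to
from .errors import ConfigError
from .model_io import Participant, ParticipantGroup, complete_symbol_count

__all__ = [
    "NOISE",
    "ClusterLabeling",
    "ValidationSpec",
    "ValidationResult",
    "preset",
    "dbscan_labels",
    "twcv",
    "validate_participant",
    "validate_group",
]

#: Label assigned to noise points.
NOISE = -1

REASONS = (
    "ok",
    "too_few_complete_graphemes",
    "dominant_color_cluster",
    "too_few_distinct_colors",
)


@dataclass(frozen=True)
class ClusterLabeling:
    """Cluster labels aligned to the input points (-1 = noise)."""

    labels: np.ndarray

    @property
    def num_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def noise_count(self) -> int:
        return int(np.sum(self.labels == NOISE))

    def cluster_sizes(self) -> np.ndarray:
        k = self.num_clusters
        return np.bincount(self.labels[self.labels >= 0], minlength=k)

    @property
    def largest_cluster_size(self) -> int:
        sizes = self.cluster_sizes()
        return int(sizes.max()) if sizes.size else 0


@dataclass(frozen=True)
class ValidationSpec:
    """Criteria bundle for validity classification.

    Defaults mirror commonly used manual criteria — at least 4 fully
    answered inducers, at least 3 clearly different colors, no single
    color covering 80% or more of all responses — with the numeric
    clustering parameters (eps, min_pts, safe_twcv) expressed in CIELUV
    units and calibrated on synthetic archetypes.
    """

    min_complete_graphemes: int = 4
    eps: float = 20.0
    min_pts: int = 4
    min_num_clusters: int = 3
    max_prop_single_cluster: float = 0.8
    safe_twcv: float = 250.0
    complete_graphemes_only: bool = True
    symbol_filter: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ConfigError("eps must be > 0")
        if self.min_pts < 2:
            raise ConfigError("min_pts must be >= 2")
        if not (0 < self.max_prop_single_cluster <= 1):
            raise ConfigError("max_prop_single_cluster must be in (0, 1]")
        if self.safe_twcv < 0:
            raise ConfigError("safe_twcv must be >= 0")
        if self.symbol_filter is not None:
            object.__setattr__(self, "symbol_filter", frozenset(self.symbol_filter))


#: Named criteria presets. "rater_strict" mirrors manual rating schemes in
#: which using one color for 60% or more of all responses invalidates data.
_PRESETS = {
    "default": ValidationSpec(),
    "rater_strict": ValidationSpec(max_prop_single_cluster=0.6),
}


def preset(name: str) -> ValidationSpec:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown validation preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class ValidationResult:
    """Per-participant verdict with diagnostics; reason is 'ok' iff valid."""

    valid: bool
    reason: str
    num_clusters: int
    twcv: Optional[float]
    prop_largest_cluster: Optional[float]
    num_complete_graphemes: int


def _as_point_array(points: Union[np.ndarray, Sequence[ColorPoint]]) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return points.reshape(-1, 3).astype(float)
    pts = list(points)
    if pts and isinstance(pts[0], ColorPoint):
        spaces = {p.space for p in pts}
        if len(spaces) > 1:
            raise ConfigError(f"points span multiple color spaces: {sorted(spaces)}")
        return np.array([p.to_array() for p in pts])
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def dbscan_labels(
    points: Union[np.ndarray, Sequence[ColorPoint]], eps: float, min_pts: int
) -> ClusterLabeling:
    """DBSCAN cluster labels for a point cloud (Euclidean neighborhoods).

    A point is core iff its closed eps-ball contains at least ``min_pts``
    points (itself included); clusters are maximal density-connected sets
    of core points plus the border points they reach; everything else is
    noise (label -1). An empty input yields an empty labeling.
    """
    arr = _as_point_array(points)
    if arr.shape[0] == 0:
        return ClusterLabeling(np.empty(0, dtype=int))
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(arr).labels_
    return ClusterLabeling(labels.astype(int))


def twcv(
    points: Union[np.ndarray, Sequence[ColorPoint]],
    labeling: Union[ClusterLabeling, np.ndarray],
) -> float:
    """Total within-cluster variance of a labelled point cloud.

    Sum over non-noise clusters of the mean squared Euclidean distance to
    the cluster centroid; 0 when no cluster exists.
    """
    arr = _as_point_array(points)
    labels = labeling.labels if isinstance(labeling, ClusterLabeling) else np.asarray(labeling)
    total = 0.0
    for c in np.unique(labels):
        if c == NOISE:
            continue
        members = arr[labels == c]
        centroid = members.mean(axis=0)
        total += float(np.mean(np.sum((members - centroid) ** 2, axis=1)))
    return total


def _participant_points(
    p: Participant, spec: ValidationSpec, space: str
) -> np.ndarray:
    graphemes = p.filtered_graphemes(spec.symbol_filter)
    if spec.complete_graphemes_only:
        graphemes = tuple(g for g in graphemes if g.is_complete)
    arrays = [g.response_array() for g in graphemes]
    stacked = np.concatenate(arrays, axis=0) if arrays else np.empty((0, 3))
    return srgb_to(stacked, space)


def validate_participant(
    p: Participant, spec: ValidationSpec = ValidationSpec(), space: str = "Luv"
) -> ValidationResult:
    """Apply the ordered decision procedure to one participant."""
    n_cg = complete_symbol_count(p, spec.symbol_filter)
    if n_cg < spec.min_complete_graphemes:
        return ValidationResult(
            valid=False,
            reason="too_few_complete_graphemes",
            num_clusters=0,
            twcv=None,
            prop_largest_cluster=None,
            num_complete_graphemes=n_cg,
        )

    points = _participant_points(p, spec, space)
    labeling = dbscan_labels(points, spec.eps, spec.min_pts)
    k = labeling.num_clusters
    n_points = points.shape[0]
    prop_largest = labeling.largest_cluster_size / n_points if n_points and k else 0.0
    t = twcv(points, labeling)

    if k >= 1 and prop_largest >= spec.max_prop_single_cluster:
        valid, reason = False, "dominant_color_cluster"
    elif k < spec.min_num_clusters and t < spec.safe_twcv:
        valid, reason = False, "too_few_distinct_colors"
    else:
        valid, reason = True, "ok"
    return ValidationResult(
        valid=valid,
        reason=reason,
        num_clusters=k,
        twcv=t,
        prop_largest_cluster=prop_largest,
        num_complete_graphemes=n_cg,
    )


def validate_group(
    grp: ParticipantGroup, spec: ValidationSpec = ValidationSpec()
) -> pd.DataFrame:
    """Validity table with one row per participant, in group order."""
    rows = []
    for p in grp.participants:
        res = validate_participant(p, spec, grp.color_space)
        rows.append(
            {
                "participant_id": p.id,
                "valid": res.valid,
                "reason": res.reason,
                "num_complete_graphemes": res.num_complete_graphemes,
                "num_clusters": res.num_clusters,
                "twcv": np.nan if res.twcv is None else res.twcv,
                "prop_largest_cluster": (
                    np.nan
                    if res.prop_largest_cluster is None
                    else res.prop_largest_cluster
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "valid",
            "reason",
            "num_complete_graphemes",
            "num_clusters",
            "twcv",
            "prop_largest_cluster",
        ],
    )
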