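"""DBSCAN nanocluster detection and per-nucleus morphometrics.

Defaults follow the analysis regime of the pipeline: neighborhood radius
200 nm and a minimum of 30 signals per cluster.  Neighbor counting
includes the point itself; border points reachable from several clusters
are assigned to the cluster discovered first under an ascending-row-index
scan, which makes the labeling fully deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .io_masks import BinaryMask, OrteMatrix, apply_mask, mask_area

NOISE = -1


@dataclass
class ClusterParams:
    radius_nm: float = 200.0
    min_count: int = 30

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be > 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class Cluster:
    """One DBSCAN cluster with convex-hull morphometrics.

    ``area_um2`` is 0 and ``density_per_um2`` is None for degenerate
    (collinear or < 3 member) clusters.
    """

    members: np.ndarray
    hull_vertices_nm: np.ndarray | None = None
    area_um2: float = 0.0
    density_per_um2: float | None = None

    @property
    def n(self) -> int:
        return len(self.members)


def dbscan_labels(points: np.ndarray, params: ClusterParams) -> np.ndarray:
    """Deterministic DBSCAN labeling; noise points get -1.

    Core points have >= min_count neighbors within radius (self included).
    Clusters are grown in ascending index order with a FIFO frontier, so
    border-point ties resolve to the earliest-discovered cluster.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, params.radius_nm)
    core = np.array([len(nb) >= params.min_count for nb in neighbors])

    cluster_id = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cluster_id
        frontier = deque([i])
        while frontier:
            j = frontier.popleft()
            for k in sorted(neighbors[j]):
                if labels[k] == NOISE:
                    labels[k] = cluster_id
                    if core[k]:
                        frontier.append(k)
        cluster_id += 1
    return labels


def cluster_properties(members: np.ndarray, points: np.ndarray) -> Cluster:
    """Complete a cluster with its convex hull, area (µm²) and tag density.

    Area uses the shoelace formula on the hull vertices; degenerate
    clusters report area 0 and a missing density.
    """
    members = np.asarray(members, dtype=int)
    pts = np.asarray(points, dtype=float)[members]
    if len(pts) < 3:
        return Cluster(members=members)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return Cluster(members=members)  # collinear
    verts = pts[hull.vertices]
    x, y = verts[:, 0], verts[:, 1]
    area_nm2 = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    area_um2 = area_nm2 / 1e6
    density = len(members) / area_um2 if area_um2 > 0 else None
    return Cluster(members=members, hull_vertices_nm=verts, area_um2=area_um2,
                   density_per_um2=density)


def dbscan(points: np.ndarray, params: ClusterParams | None = None):
    """Run DBSCAN and complete every cluster's morphometrics.

    Returns ``(clusters, noise_indices)`` where clusters are ordered by
    discovery (ascending first-core index).
    """
    params = params or ClusterParams()
    points = np.asarray(points, dtype=float)
    labels = dbscan_labels(points, params)
    clusters = [
        cluster_properties(np.flatnonzero(labels == cid), points)
        for cid in range(labels.max() + 1 if len(labels) else 0)
    ]
    return clusters, np.flatnonzero(labels == NOISE)


def summarize_nucleus(
    ortes: dict[str, OrteMatrix],
    masks: dict[str, BinaryMask],
    params: ClusterParams | None = None,
) -> pd.DataFrame:
    """Per-label, per-mask event and cluster summary (one row each).

    Columns: n_events, event_density_per_um2, n_clusters,
    n_tags_in_clusters, mean_cluster_area_um2, mean_cluster_density_per_um2.
    Densities are missing (NaN) for empty masks; the mean in-cluster
    density is an unweighted mean over non-degenerate clusters.
    """
    params = params or ClusterParams()
    rows = []
    for label, orte in ortes.items():
        for mask_name, mask in masks.items():
            masked = apply_mask(orte, mask)
            area = mask_area(mask)
            clusters, _ = dbscan(masked.xy, params)
            n_in = int(sum(c.n for c in clusters))
            areas = [c.area_um2 for c in clusters]
            densities = [c.density_per_um2 for c in clusters if c.density_per_um2 is not None]
            rows.append(
                {
                    "label": label,
                    "mask": mask_name,
                    "n_events": len(masked),
                    "event_density_per_um2": len(masked) / area if area > 0 else np.nan,
                    "n_clusters": len(clusters),
                    "n_tags_in_clusters": n_in,
                    "mean_cluster_area_um2": float(np.mean(areas)) if areas else np.nan,
                    "mean_cluster_density_per_um2": (
                        float(np.mean(densities)) if densities else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Per-cluster table (id, n, area, density, hull vertex list)."""
    rows = []
    for cid, c in enumerate(clusters):
        hull = (
            ";".join(f"{x:.2f} {y:.2f}" for x, y in c.hull_vertices_nm)
            if c.hull_vertices_nm is not None
            else ""
        )
        rows.append(
            {
                "cluster_id": cid,
                "n": c.n,
                "area_um2": c.area_um2,
                "density_per_um2": c.density_per_um2 if c.density_per_um2 is not None else np.nan,
                "hull_nm": hull,
            }
        )
    return pd.DataFrame(rows)
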