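"""Two-channel co-localization by nearest-neighbor distance thresholding.

A channel-A event co-localizes when its nearest channel-B event lies
within the distance threshold (analysis set: 95, 50 and 20 nm).  Cluster
overlap percentages and second-channel densities inside first-channel
cluster hulls complete the cross-channel readout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .clustering import Cluster
from .io_masks import OrteMatrix

logger = logging.getLogger(__name__)

#: Distance thresholds (nm) used in the standard analysis.
ANALYSIS_THRESHOLDS_NM = (95.0, 50.0, 20.0)


@dataclass
class ColocParams:
    threshold_nm: float = 95.0

    def __post_init__(self) -> None:
        if self.threshold_nm <= 0:
            raise ValueError("threshold_nm must be > 0")


@dataclass
class ColocResult:
    flags: np.ndarray  # per channel-A point
    n_a: int
    n_b: int
    n_coloc: int
    fraction_pct: float
    threshold_nm: float
    direction: str = "A->B"


def colocalize_points(
    orte_a: OrteMatrix | np.ndarray,
    orte_b: OrteMatrix | np.ndarray,
    params: ColocParams | None = None,
) -> ColocResult:
    """Flag channel-A events whose nearest B neighbor is within threshold.

    Directional (A->B).  An empty A channel is an error; an empty B
    channel gives fraction 0 with a warning.
    """
    params = params or ColocParams()
    a = orte_a.xy if isinstance(orte_a, OrteMatrix) else np.asarray(orte_a, float)
    b = orte_b.xy if isinstance(orte_b, OrteMatrix) else np.asarray(orte_b, float)
    if len(a) == 0:
        raise ValueError("channel A is empty")
    if len(b) == 0:
        warnings.warn("channel B is empty; co-localized fraction is 0", stacklevel=2)
        flags = np.zeros(len(a), dtype=bool)
        return ColocResult(flags, len(a), 0, 0, 0.0, params.threshold_nm)
    dist, _ = cKDTree(b).query(a, k=1)
    flags = dist <= params.threshold_nm
    n_coloc = int(flags.sum())
    return ColocResult(
        flags=flags,
        n_a=len(a),
        n_b=len(b),
        n_coloc=n_coloc,
        fraction_pct=100.0 * n_coloc / len(a),
        threshold_nm=params.threshold_nm,
    )


def colocalize_both_directions(orte_a, orte_b, params: ColocParams | None = None):
    """(A->B, B->A) co-localization results for one threshold."""
    fwd = colocalize_points(orte_a, orte_b, params)
    rev = colocalize_points(orte_b, orte_a, params)
    rev.direction = "B->A"
    return fwd, rev


def _hull_union(clusters: list[Cluster]):
    polys = [
        Polygon(c.hull_vertices_nm)
        for c in clusters
        if c.hull_vertices_nm is not None and c.area_um2 > 0
    ]
    return unary_union(polys) if polys else Polygon()


def cluster_overlap(
    clusters_a: list[Cluster], clusters_b: list[Cluster], raster_nm: float = 5.0
) -> float | None:
    """Overlap of the B hull union with the A hull union, in percent of A.

    Areas are measured on a raster of pixel size ``raster_nm`` over the
    A-union bounding box.  Zero A hull area -> None (undefined).
    """
    ua = _hull_union(clusters_a)
    if ua.area <= 0:
        return None
    ub = _hull_union(clusters_b)
    x0, y0, x1, y1 = ua.bounds
    xs = np.arange(x0 + raster_nm / 2, x1, raster_nm)
    ys = np.arange(y0 + raster_nm / 2, y1, raster_nm)
    xx, yy = np.meshgrid(xs, ys)
    in_a = shapely.contains_xy(ua, xx.ravel(), yy.ravel())
    n_a = int(in_a.sum())
    if n_a == 0:
        return None
    if ub.area <= 0:
        return 0.0
    in_b = shapely.contains_xy(ub, xx.ravel()[in_a], yy.ravel()[in_a])
    return 100.0 * int(in_b.sum()) / n_a


def density_in_clusters(orte_b, clusters_a: list[Cluster]) -> float | None:
    """Density (tags/µm²) of B events inside the union of A cluster hulls."""
    ua = _hull_union(clusters_a)
    if ua.area <= 0:
        return None
    b = orte_b.xy if isinstance(orte_b, OrteMatrix) else np.asarray(orte_b, float)
    if len(b) == 0:
        return 0.0
    inside = shapely.intersects_xy(ua, b[:, 0], b[:, 1])  # boundary counts as inside
    return float(inside.sum()) / (ua.area / 1e6)


def resample_control(rng: np.random.Generator, orte_b, nucleus_mask) -> np.ndarray:
    """Chance-co-localization baseline: B resampled uniformly over the nucleus."""
    n = len(orte_b.xy) if isinstance(orte_b, OrteMatrix) else len(orte_b)
    inside = np.argwhere(nucleus_mask.grid)
    pick = inside[rng.integers(0, len(inside), n)]
    jitter = rng.random((n, 2)) * nucleus_mask.pixel_size_nm
    x = nucleus_mask.origin_nm[0] + pick[:, 1] * nucleus_mask.pixel_size_nm + jitter[:, 0]
    y = nucleus_mask.origin_nm[1] + pick[:, 0] * nucleus_mask.pixel_size_nm + jitter[:, 1]
    return np.column_stack([x, y])
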