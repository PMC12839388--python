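"""Alpha-filtration persistent homology and barcode similarity heatmaps.

The alpha parameter is a radius: every point grows an imaginary disc of
radius alpha, and the connected components (dimension 0) and holes
(dimension 1) of the union are tracked as alpha increases.  The
filtration is built on the 2D Delaunay triangulation: triangles enter at
their circumradius, edges at half their length when Gabriel and at the
smallest incident circumradius otherwise, vertices at 0.  For points in
general position this has exactly the persistence of the Cech (growing
discs) filtration, which the test suite verifies against a brute-force
oracle.

Barcodes are compared with an interval-matching Jaccard score: bars are
greedily matched in descending interval-Jaccard order and the matched
overlap sum is normalized by the larger bar count, so identical barcodes
score 1 and barcodes with no overlap score 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

DEFAULT_ALPHA_MAX_NM = 500.0


@dataclass(frozen=True)
class PersistenceInterval:
    dimension: int
    birth_nm: float
    death_nm: float

    def __post_init__(self) -> None:
        if self.death_nm < self.birth_nm:
            raise ValueError("death must be >= birth")


@dataclass
class Barcode:
    """Persistence intervals of one point cloud, truncated at alpha_max."""

    intervals: list[PersistenceInterval]
    n_points: int
    alpha_max_nm: float

    def of_dimension(self, dimension: int) -> np.ndarray:
        """(k, 2) array of (birth, death) for one homology dimension."""
        ints = [(i.birth_nm, i.death_nm) for i in self.intervals if i.dimension == dimension]
        return np.array(ints, dtype=float).reshape(-1, 2)


@dataclass
class SimilarityHeatmap:
    generation: int
    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    dimension: str = "components"  # components | holes


# ---------------------------------------------------------------------------
# filtration construction


def _circumradius(a, b, c) -> float:
    la, lb, lc = np.linalg.norm(b - c), np.linalg.norm(a - c), np.linalg.norm(a - b)
    area2 = abs((b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0])  # 2*area
    if area2 < 1e-14 * max(la, lb, lc) ** 2:
        return float("inf")
    return la * lb * lc / (2.0 * area2)


def _min_enclosing_radius(a, b, c) -> float:
    """Radius of the smallest disc containing three points."""
    sides = sorted(
        [np.linalg.norm(a - b), np.linalg.norm(b - c), np.linalg.norm(a - c)]
    )
    if sides[2] ** 2 >= sides[0] ** 2 + sides[1] ** 2:  # obtuse or right
        return sides[2] / 2.0
    return _circumradius(a, b, c)


def _delaunay_filtration(points: np.ndarray):
    """(simplices, filtration values) of the 2D alpha filtration."""
    tri = Delaunay(points)
    triangles = [tuple(sorted(map(int, s))) for s in tri.simplices]
    tri_filt = {
        t: _circumradius(points[t[0]], points[t[1]], points[t[2]]) for t in triangles
    }
    # incident triangles per edge
    edge_tris: dict[tuple[int, int], list] = {}
    for t in triangles:
        for e in itertools.combinations(t, 2):
            edge_tris.setdefault(e, []).append(t)
    edge_filt = {}
    for (i, j), tris in edge_tris.items():
        d = np.linalg.norm(points[i] - points[j])
        mid = 0.5 * (points[i] + points[j])
        gabriel = True
        for t in tris:
            k = next(v for v in t if v not in (i, j))
            if np.linalg.norm(points[k] - mid) < d / 2.0:
                gabriel = False
                break
        edge_filt[(i, j)] = d / 2.0 if gabriel else min(tri_filt[t] for t in tris)
    simplices = (
        [((v,), 0.0) for v in range(len(points))]
        + [(e, f) for e, f in edge_filt.items()]
        + [(t, f) for t, f in tri_filt.items()]
    )
    return simplices


def _full_cech_filtration(points: np.ndarray):
    """All-subsets (<= triangles) Cech filtration; fallback for degenerate input."""
    n = len(points)
    simplices = [((v,), 0.0) for v in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        simplices.append(((i, j), np.linalg.norm(points[i] - points[j]) / 2.0))
    for i, j, k in itertools.combinations(range(n), 3):
        simplices.append(((i, j, k), _min_enclosing_radius(points[i], points[j], points[k])))
    return simplices


def _reduce_boundary(simplices):
    """Standard persistence pairing by column reduction over Z/2.

    ``simplices`` is a list of (vertex-tuple, filtration value); returns
    (order, pairs) where pairs maps creator index -> destroyer index in
    the sorted order.
    """
    order = sorted(range(len(simplices)), key=lambda s: (simplices[s][1], len(simplices[s][0]), simplices[s][0]))
    pos = {simplices[s][0]: rank for rank, s in enumerate(order)}
    reduced: list[int] = []
    pivot_owner: dict[int, int] = {}
    pairs: dict[int, int] = {}
    for rank, s in enumerate(order):
        verts = simplices[s][0]
        col = 0
        if len(verts) > 1:
            for face in itertools.combinations(verts, len(verts) - 1):
                col ^= 1 << pos[face]
        while col:
            low = col.bit_length() - 1
            owner = pivot_owner.get(low)
            if owner is None:
                break
            col ^= reduced[owner]
        reduced.append(col)
        if col:
            low = col.bit_length() - 1
            pivot_owner[low] = rank
            pairs[low] = rank
    return order, pairs


def alpha_persistence(points: np.ndarray, alpha_max_nm: float = DEFAULT_ALPHA_MAX_NM) -> Barcode:
    """Persistence barcode (dimensions 0 and 1) of the alpha filtration.

    Every point contributes a dimension-0 bar born at alpha = 0; the last
    surviving component (and any feature outliving ``alpha_max_nm``) is
    truncated at alpha_max.  Exactly coincident points are separated by a
    deterministic sub-nanometre perturbation so the filtration is always
    defined.  Fewer than 3 points cannot form holes.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n < 1:
        raise ValueError("alpha_persistence needs at least one point")
    if alpha_max_nm <= 0:
        raise ValueError("alpha_max_nm must be > 0")

    # deterministic symbolic-epsilon stand-in for exact duplicates
    if n > 1 and len(np.unique(points, axis=0)) < n:
        eps = 1e-9 * (1.0 + np.arange(n))[:, None] * np.array([[1.0, -0.7]])
        points = points + eps

    if n == 1:
        return Barcode([PersistenceInterval(0, 0.0, alpha_max_nm)], 1, alpha_max_nm)

    if n <= 3:
        simplices = _full_cech_filtration(points)
    else:
        try:
            simplices = _delaunay_filtration(points)
        except QhullError:
            if n > 300:
                raise ValueError(
                    "degenerate (collinear) input too large for the Cech fallback"
                ) from None
            simplices = _full_cech_filtration(points)

    order, pairs = _reduce_boundary(simplices)
    filt = [simplices[s][1] for s in order]
    dim = [len(simplices[s][0]) - 1 for s in order]

    destroyed = set(pairs.values())
    intervals: list[PersistenceInterval] = []
    for creator, destroyer in pairs.items():
        d = dim[creator]
        if d > 1:
            continue
        birth, death = filt[creator], filt[destroyer]
        if d == 1 and death - birth <= 1e-9 * max(1.0, abs(death)):
            continue  # zero-persistence hole artifacts (degenerate/cocircular input)
        birth = min(birth, alpha_max_nm)
        death = min(death, alpha_max_nm)
        intervals.append(PersistenceInterval(d, birth, death))
    for rank in range(len(order)):
        if rank not in pairs and rank not in destroyed and dim[rank] <= 1:
            # essential class (the final connected component)
            intervals.append(
                PersistenceInterval(dim[rank], min(filt[rank], alpha_max_nm), alpha_max_nm)
            )
    intervals.sort(key=lambda i: (i.dimension, i.birth_nm, i.death_nm))
    return Barcode(intervals, n, alpha_max_nm)


# ---------------------------------------------------------------------------
# barcode similarity


def _interval_jaccard(b1: float, d1: float, b2: float, d2: float) -> float:
    inter = max(0.0, min(d1, d2) - max(b1, b2))
    union = max(d1, d2) - min(b1, b2)
    if union <= 0.0:  # two zero-length intervals at the same alpha
        return 1.0 if (b1 == b2 and d1 == d2) else 0.0
    return inter / union


def jaccard_barcodes(b1: Barcode, b2: Barcode, dimension: int = 0) -> float:
    """Interval-matching Jaccard similarity S in [0, 1] for one dimension.

    Bars are matched greedily in descending interval-Jaccard order (each
    bar used at most once); S is the matched-overlap sum divided by the
    larger bar count.  Two empty barcodes are identical (S = 1); exactly
    one empty gives S = 0.
    """
    if b1.alpha_max_nm != b2.alpha_max_nm:
        raise ValueError("barcodes must be analyzed with the same alpha_max")
    i1, i2 = b1.of_dimension(dimension), b2.of_dimension(dimension)
    if len(i1) == 0 and len(i2) == 0:
        return 1.0
    if len(i1) == 0 or len(i2) == 0:
        return 0.0
    scored = []
    for a in range(len(i1)):
        for b in range(len(i2)):
            j = _interval_jaccard(i1[a, 0], i1[a, 1], i2[b, 0], i2[b, 1])
            if j > 0:
                scored.append((j, a, b))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1, used2 = set(), set()
    total = 0.0
    for j, a, b in scored:
        if a in used1 or b in used2:
            continue
        used1.add(a)
        used2.add(b)
        total += j
    return total / max(len(i1), len(i2))


def first_generation_heatmap(
    barcodes: list[Barcode], dimension: int = 0, labels: list[str] | None = None
) -> SimilarityHeatmap:
    """Pairwise S matrix of one labeling type: symmetric with unit diagonal."""
    if len(barcodes) < 2:
        raise ValueError("need >= 2 barcodes for a 1st-generation heatmap")
    k = len(barcodes)
    labels = labels or [f"s{i}" for i in range(k)]
    values = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = jaccard_barcodes(barcodes[i], barcodes[j], dimension)
            values[i, j] = values[j, i] = s
    dim_name = "components" if dimension == 0 else "holes"
    return SimilarityHeatmap(1, list(labels), list(labels), values, dim_name)


def cross_heatmap(
    barcodes_a: list[Barcode],
    barcodes_b: list[Barcode],
    dimension: int = 0,
    labels_a: list[str] | None = None,
    labels_b: list[str] | None = None,
) -> SimilarityHeatmap:
    """Rectangular S block between two labeling types (for gen-2 cells)."""
    la = labels_a or [f"a{i}" for i in range(len(barcodes_a))]
    lb = labels_b or [f"b{i}" for i in range(len(barcodes_b))]
    values = np.array(
        [[jaccard_barcodes(x, y, dimension) for y in barcodes_b] for x in barcodes_a]
    )
    dim_name = "components" if dimension == 0 else "holes"
    return SimilarityHeatmap(1, la, lb, values, dim_name)


def second_generation_heatmap(
    gen1_maps: dict[tuple[str, str], SimilarityHeatmap], labels: list[str]
) -> SimilarityHeatmap:
    """Label x label means of the 1st-generation heatmaps.

    Same-label cells average the off-diagonal entries; cross-label cells
    average the full rectangular block.  Missing pairs are NaN.
    """
    k = len(labels)
    values = np.full((k, k), np.nan)
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            hm = gen1_maps.get((la, lb)) or gen1_maps.get((lb, la))
            if hm is None:
                continue
            v = hm.values
            if la == lb:
                off = v[~np.eye(len(v), dtype=bool)]
                values[i, j] = off.mean() if len(off) else np.nan
            else:
                values[i, j] = v.mean()
    dims = {m.dimension for m in gen1_maps.values()}
    dim_name = dims.pop() if len(dims) == 1 else "mixed"
    return SimilarityHeatmap(2, list(labels), list(labels), values, dim_name)


def barcode_to_rows(barcode: Barcode):
    """Rows (dim, birth_nm, death_nm) for CSV serialization."""
    return [(i.dimension, i.birth_nm, i.death_nm) for i in barcode.intervals]
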