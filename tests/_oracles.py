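"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own spatial indexing and reduction
code paths: distances come from explicit O(n^2) matrices, persistence from
an all-subsets complex reduced with set symmetric differences.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# DBSCAN


def brute_dbscan(points: np.ndarray, radius: float, min_count: int) -> np.ndarray:
    """O(n^2) DBSCAN with self-inclusive neighbor counts and ascending-index
    cluster growth (FIFO, sorted neighbor expansion)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    neighbor_sets = [np.flatnonzero(dist[i] <= radius) for i in range(n)]
    core = np.array([len(s) >= min_count for s in neighbor_sets])

    cid = 0
    for start in range(n):
        if labels[start] != -1 or not core[start]:
            continue
        labels[start] = cid
        queue = [start]
        while queue:
            j = queue.pop(0)
            for k in neighbor_sets[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        queue.append(k)
        cid += 1
    return labels


# ---------------------------------------------------------------------------
# Cech persistence (dimensions 0 and 1) by full-subset enumeration


def _meb_radius_3(a, b, c):
    """Smallest enclosing disc radius of three points."""
    ab = np.linalg.norm(a - b)
    bc = np.linalg.norm(b - c)
    ca = np.linalg.norm(c - a)
    s = sorted([ab, bc, ca])
    if s[2] ** 2 >= s[0] ** 2 + s[1] ** 2:
        return s[2] / 2.0
    # acute: circumradius
    area2 = abs((b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0])
    return ab * bc * ca / (2.0 * area2)


def cech_persistence(points: np.ndarray, alpha_max: float):
    """All finite and essential (dim, birth, death) of the Cech filtration.

    Uses the full 2-skeleton (all edges, all triangles) with filtration
    value = minimal-enclosing-ball radius, and a textbook set-based column
    reduction.  Deaths capped at alpha_max; intended for small n.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    simplices = [(frozenset([i]), 0.0) for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        simplices.append((frozenset([i, j]), np.linalg.norm(points[i] - points[j]) / 2.0))
    for i, j, k in itertools.combinations(range(n), 3):
        simplices.append((frozenset([i, j, k]), _meb_radius_3(points[i], points[j], points[k])))

    simplices.sort(key=lambda s: (s[1], len(s[0]), sorted(s[0])))
    index_of = {s: i for i, (s, _) in enumerate(simplices)}

    columns: list[set] = []
    pivot_owner: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    positive: set[int] = set()
    for j, (simplex, _) in enumerate(simplices):
        if len(simplex) == 1:
            boundary: set = set()
        else:
            boundary = {
                index_of[frozenset(face)]
                for face in itertools.combinations(sorted(simplex), len(simplex) - 1)
            }
        while boundary:
            low = max(boundary)
            owner = pivot_owner.get(low)
            if owner is None:
                break
            boundary ^= columns[owner]
        columns.append(boundary)
        if boundary:
            low = max(boundary)
            pivot_owner[low] = j
            pairs.append((low, j))
            positive.discard(low)
        else:
            positive.add(j)

    destroyers = {j for _, j in pairs}
    bars = []
    for creator, destroyer in pairs:
        dim = len(simplices[creator][0]) - 1
        if dim > 1:
            continue
        birth = simplices[creator][1]
        death = simplices[destroyer][1]
        if dim == 1 and death - birth <= 1e-9 * max(1.0, abs(death)):
            continue
        bars.append((dim, min(birth, alpha_max), min(death, alpha_max)))
    for j in positive:
        if j in destroyers:
            continue
        dim = len(simplices[j][0]) - 1
        if dim <= 1:
            bars.append((dim, min(simplices[j][1], alpha_max), alpha_max))
    bars.sort()
    return bars


# ---------------------------------------------------------------------------
# co-localization


def brute_coloc_flags(a: np.ndarray, b: np.ndarray, threshold: float) -> np.ndarray:
    """All-pairs nearest-neighbor thresholding for channel A points."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    diff = a[:, None, :] - b[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    return dist.min(axis=1) <= threshold


def expected_coloc_fraction(scene, threshold: float, rng: np.random.Generator,
                            n_mc: int = 2000) -> float:
    """Sampling-oracle expectation of the ch2->ch1 co-localized fraction.

    Decomposes channel 2 into anchored focus events (closed-form Rayleigh
    probability of being within threshold of the anchor, localization
    noise of both channels included), free focus events and background
    events (both Monte-Carlo re-sampled against the realized channel-1
    orte positions with brute-force nearest neighbors).
    """
    params = scene.params
    sig2 = (
        params.coloc_displacement_sigma_nm**2
        + params.loc_error_ch1_nm**2
        + params.loc_error_ch2_nm**2
    )
    p_anchor = 1.0 - np.exp(-(threshold**2) / (2.0 * sig2)) if sig2 > 0 else 1.0

    # channel-1 orte stand-in: true positions + channel-1 localization noise
    ch1 = scene.positions_ch1 + rng.normal(0.0, params.loc_error_ch1_nm, scene.positions_ch1.shape)

    n_total = len(scene.positions_ch2)
    if n_total == 0:
        return 0.0
    n_anchored = int(scene.anchored_ch2.sum())
    n_focus_free = int(((scene.labels_ch2 >= 0) & ~scene.anchored_ch2).sum())
    n_bg = int((scene.labels_ch2 < 0).sum())

    def mc_prob(draw):
        pts = draw(n_mc)
        pts = pts + rng.normal(0.0, params.loc_error_ch2_nm, pts.shape)
        return brute_coloc_flags(pts, ch1, threshold).mean()

    p_focus = 0.0
    if n_focus_free:
        centers = scene.focus_centers
        sigma2 = getattr(params, "sigma_ch2_nm", params.focus_sigma_nm)
        def draw_focus(m):
            which = rng.integers(0, len(centers), m)
            return centers[which] + rng.normal(0.0, sigma2, (m, 2))
        p_focus = mc_prob(draw_focus)

    p_bg = 0.0
    if n_bg:
        r_nuc = params.nucleus_radius_nm
        cx, cy = scene.center_nm
        def draw_bg(m):
            r = r_nuc * np.sqrt(rng.random(m))
            t = rng.random(m) * 2 * np.pi
            return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
        p_bg = mc_prob(draw_bg)

    # anchored events may also colocalize via a *different* ch1 point, but the
    # anchor term already dominates; chance contribution is absorbed by max().
    p_anchored = max(p_anchor, p_focus)
    expected = (n_anchored * p_anchored + n_focus_free * p_focus + n_bg * p_bg) / n_total
    return 100.0 * expected
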