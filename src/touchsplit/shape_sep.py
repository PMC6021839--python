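"""Shape-based separation: holes, guideline, concave points, boundary.

The stage runs when box-based cutting is unavailable or rejected.  It
seeds the cut with a *hole* — an enclosed background region if one exists,
otherwise one manufactured by repeated erosion or, as a last resort, from
the medial-axis skeleton — stretches a *guideline* across each hole's
farthest point pair, locates up to two *concave points* on the outline via
convex-hull defect time series, and joins guideline and concave points
into a boundary line that splits the blob in two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateHullError, DegenerateShapeError, NoValidCutError
from .maskgeom import (
    BoundaryLine,
    Mask,
    Outline,
    Point,
    STRUCT_8,
    dedupe_path,
    extract_outline,
    make_4connected,
    rasterize_segment,
)

SQRT2 = math.sqrt(2.0)


@dataclass
class ShapeConfig:
    erosion_repeat_th: int = 8
    skeleton_scale: float = 0.5
    cp_band: float = 0.1
    cp_ratio_th: float = 1.05
    cp_min_depth: float = 2.0
    max_cps: int = 2

    def __post_init__(self):
        if self.erosion_repeat_th < 1:
            raise ValueError("erosion_repeat_th must be >= 1")
        if not (0 < self.cp_band < 1):
            raise ValueError("cp_band must be in (0,1)")


@dataclass
class Hole:
    pixels: List[Point]
    kind: str  # natural | erosion | skeleton


@dataclass
class Guideline:
    points: List[Point]
    end_a: Point
    end_b: Point


@dataclass
class ConcaveSeries:
    """Outline unrolled against its convex hull.

    ``L[i]`` is the perpendicular distance of outline point ``i`` from its
    covering hull chord (zero on the hull); ``G[i]`` is the Euclidean
    distance of outline point ``i`` from the traversal start point.
    ``hull_segments`` holds ``(start_outline_idx, end_outline_idx)`` pairs
    in traversal order, cyclic on the outline.
    """

    L: np.ndarray
    G: np.ndarray
    hull_segments: List[Tuple[int, int]]
    start_index: int
    outline: Outline


@dataclass
class ConcavePoint:
    index: int
    point: Point
    depth: float
    ratio: float = 0.0


# ---------------------------------------------------------------------------
# hole generation


def find_natural_holes(mask: Mask) -> List[Hole]:
    """Enclosed background components (4-connected), excluding any region
    reaching the grid border."""
    bg = ~mask.grid
    lbl, n = ndimage.label(bg, structure=ndimage.generate_binary_structure(2, 1))
    holes: List[Hole] = []
    edge_labels = set(np.unique(lbl[0, :])) | set(np.unique(lbl[-1, :]))
    edge_labels |= set(np.unique(lbl[:, 0])) | set(np.unique(lbl[:, -1]))
    for v in range(1, n + 1):
        if v in edge_labels:
            continue
        rs, cs = np.nonzero(lbl == v)
        holes.append(
            Hole(pixels=[Point(int(r), int(c)) for r, c in zip(rs, cs)], kind="natural")
        )
    return holes


def holes_by_erosion(mask: Mask, cfg: ShapeConfig = ShapeConfig()) -> List[Hole]:
    """Manufacture holes by eroding until the blob splits.

    After ``erosion_repeat_th`` erosions with a full 3x3 element, if the
    blob has fallen into two or more remnants, the equidistant ridge
    between the two largest remnants (restricted to eroded-away foreground)
    spans the vanished neck transversally; each connected piece of that
    ridge is returned as one erosion hole.  If erosion empties the blob or
    does not split it, the list is empty and the caller moves on to the
    skeleton generator.
    """
    grid = mask.grid
    eroded = ndimage.binary_erosion(
        grid, structure=STRUCT_8, iterations=cfg.erosion_repeat_th
    )
    lbl, n = ndimage.label(eroded, structure=STRUCT_8)
    if n < 2:
        return []
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[1]] < 5:  # second remnant is speckle, not a split
        return []
    c1 = lbl == (order[0] + 1)
    c2 = lbl == (order[1] + 1)
    d1 = ndimage.distance_transform_edt(~c1)
    d2 = ndimage.distance_transform_edt(~c2)
    ridge = grid & ~eroded & (np.abs(d1 - d2) <= 1.0)
    if not ridge.any():
        return []
    rlbl, rn = ndimage.label(ridge, structure=STRUCT_8)
    holes = []
    for v in range(1, rn + 1):
        rs, cs = np.nonzero(rlbl == v)
        holes.append(
            Hole(pixels=[Point(int(r), int(c)) for r, c in zip(rs, cs)], kind="erosion")
        )
    return holes


def _skeleton_longest_path(skel: np.ndarray) -> List[Point]:
    """Longest simple path on a skeleton via double breadth-first search."""
    pts = [Point(int(r), int(c)) for r, c in zip(*np.nonzero(skel))]
    if not pts:
        return []
    ptset = set(pts)

    def neighbors(p: Point):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                q = Point(p.row + dr, p.col + dc)
                if q in ptset:
                    yield q

    def bfs(src: Point):
        prev = {src: None}
        frontier = [src]
        last = src
        while frontier:
            nxt = []
            for p in frontier:
                for q in neighbors(p):
                    if q not in prev:
                        prev[q] = p
                        nxt.append(q)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, prev

    a, _ = bfs(pts[0])
    b, prev = bfs(a)
    path = []
    cur: Optional[Point] = b
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    return path


def hole_by_skeleton(mask: Mask, cfg: ShapeConfig = ShapeConfig()) -> Hole:
    """Last-resort hole from the medial-axis skeleton.

    The skeleton is computed on a downscaled copy and traced to its
    longest path; the waist of that path — the interior point with the
    smallest medial-axis radius, i.e. where the blob is narrowest — plays
    the role of the centroid (for a symmetric pair this coincides with the
    path midpoint).  The hole is the short transverse path through the
    centroid toward the two nearest outline points on opposite sides,
    trimmed to a 4-pixel neighborhood of the centroid.
    """
    from skimage.morphology import medial_axis

    grid = mask.grid
    step = max(1, int(round(1.0 / cfg.skeleton_scale)))
    small = grid[::step, ::step]
    if small.any():
        # rng pinned: medial_axis breaks ties in random order by default
        skel, radius = medial_axis(small, return_distance=True, rng=0)
    else:
        skel, radius = np.zeros_like(small), None
    path = _skeleton_longest_path(skel)
    if len(path) < 2:
        raise DegenerateShapeError("skeleton too small to trace")
    # waist = interior radius minimum, but only a genuine dip counts:
    # on a near-convex blob the radii just taper toward the tips and the
    # midpoint is the best neck estimate available
    radii = np.array([radius[p.row, p.col] for p in path], dtype=float)
    if len(radii) >= 5:
        radii = np.convolve(radii, np.ones(3) / 3.0, mode="same")
    k0 = max(1, len(path) // 6)
    inner = radii[k0 : len(path) - k0]
    mid = path[len(path) // 2]
    if inner.size:
        i = k0 + int(np.argmin(inner))
        if radii[i] < min(radii[k0], radii[len(path) - k0 - 1]) - 1e-9:
            mid = path[i]
    centroid = Point(mid.row * step, mid.col * step)
    if not grid[centroid.row, centroid.col]:
        rs, cs = np.nonzero(grid)
        k = np.argmin((rs - centroid.row) ** 2 + (cs - centroid.col) ** 2)
        centroid = Point(int(rs[k]), int(cs[k]))

    outline = extract_outline(mask)
    pts = outline.as_array()
    d2 = (pts[:, 0] - centroid.row) ** 2 + (pts[:, 1] - centroid.col) ** 2

    # steer the transverse direction by the local skeleton normal so the
    # hole crosses the blob instead of running to the nearest edge of a
    # tilted body
    ks = path.index(mid)
    lo_k, hi_k = max(0, ks - 3), min(len(path) - 1, ks + 3)
    tang = np.array(
        [path[hi_k].row - path[lo_k].row, path[hi_k].col - path[lo_k].col], float
    )
    tn = np.hypot(*tang)
    vecs = pts.astype(float) - np.array(centroid, float)
    norms = np.hypot(vecs[:, 0], vecs[:, 1])
    norms[norms == 0] = 1.0
    if tn > 0:
        normal = np.array([-tang[1], tang[0]]) / tn
        align = np.abs(vecs @ normal) / norms
        sel = align >= np.cos(np.pi / 3)  # within 60 deg of the normal
        cand1 = np.where(sel, d2, np.inf)
        i1 = int(np.argmin(cand1)) if np.isfinite(cand1).any() else int(np.argmin(d2))
    else:  # pragma: no cover - degenerate tangent
        i1 = int(np.argmin(d2))
    p1 = Point(*map(int, pts[i1]))
    v1 = pts[i1] - np.array(centroid)
    dots = vecs @ v1.astype(float)
    opposite = dots <= 0
    if opposite.any():
        cand = np.where(opposite, d2, np.inf)
        i2 = int(np.argmin(cand))
    else:  # pragma: no cover - convex degenerate fallback
        i2 = int(np.argmax(d2))
    p2 = Point(*map(int, pts[i2]))

    full = rasterize_segment(p1, centroid) + rasterize_segment(centroid, p2)[1:]
    near = [
        p
        for p in dedupe_path(full)
        if max(abs(p.row - centroid.row), abs(p.col - centroid.col)) <= 2
        and grid[p.row, p.col]
    ]
    if not near:
        near = [centroid]
    return Hole(pixels=near, kind="skeleton")


# ---------------------------------------------------------------------------
# guideline generation


def _farthest_pair(pixels: Sequence[Point]) -> Tuple[Point, Point]:
    """Brute-force diameter of a pixel set; ties break lexicographically."""
    arr = np.asarray(pixels, dtype=float)
    n = len(arr)
    if n == 1:
        return pixels[0], pixels[0]
    d = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2)
    best = -1.0
    pair = (pixels[0], pixels[0])
    for i in range(n):
        for j in range(i + 1, n):
            key_ij = (pixels[i], pixels[j])
            key_ij = key_ij if key_ij[0] <= key_ij[1] else (key_ij[1], key_ij[0])
            if d[i, j] > best or (d[i, j] == best and key_ij < pair):
                best = d[i, j]
                pair = key_ij
    return pair


def guideline_from_holes(holes: List[Hole]) -> Guideline:
    """Diameter segment per hole, chained across holes along their
    principal axis into a single polyline."""
    if not holes:
        raise ValueError("guideline requires at least one hole")

    semis = []
    for h in holes:
        a, b = _farthest_pair(h.pixels)
        semis.append((a, b, rasterize_segment(a, b)))

    if len(semis) == 1:
        a, b, seg = semis[0]
        return Guideline(points=seg, end_a=a, end_b=b)

    # order the semi-guidelines by projection onto the holes' principal axis
    allpix = np.asarray([p for h in holes for p in h.pixels], dtype=float)
    centered = allpix - allpix.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]

    def proj(semi):
        mid = (np.asarray(semi[0], float) + np.asarray(semi[1], float)) / 2
        return float((mid - allpix.mean(axis=0)) @ axis)

    semis.sort(key=proj)

    points: List[Point] = []
    cur_free: Point
    a, b, seg = semis[0]
    # orient the first semi so the end nearer the next hole is the tail
    nxt_mid = (np.asarray(semis[1][0], float) + np.asarray(semis[1][1], float)) / 2

    def dist(p, q):
        return float(np.hypot(p[0] - q[0], p[1] - q[1]))

    if dist(a, nxt_mid) < dist(b, nxt_mid):
        seg = list(reversed(seg))
        a, b = b, a
    end_a = a
    points.extend(seg)
    tail = b
    for (c, d, seg2) in semis[1:]:
        if dist(d, tail) < dist(c, tail):
            seg2 = list(reversed(seg2))
            c, d = d, c
        points.extend(rasterize_segment(tail, c)[1:])
        points.extend(seg2[1:] if seg2[0] == tail else seg2)
        tail = d
    return Guideline(points=dedupe_path(points), end_a=end_a, end_b=tail)


# ---------------------------------------------------------------------------
# concave-point generation


def _perp_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    nrm = np.hypot(*ab)
    if nrm == 0:
        return float(np.hypot(*(p - a)))
    ap = p - a
    return abs(float(ab[0] * ap[1] - ab[1] * ap[0])) / nrm


def build_series(outline: Outline) -> ConcaveSeries:
    """Unroll the outline against its convex hull into the L/G series.

    Hull vertices are located on the outline and taken in traversal order;
    the first hull vertex along the outline (the end of the wrap-around
    hull segment) is the series start point.
    """
    pts = outline.as_array()
    n = len(pts)
    if n < 3:
        raise DegenerateHullError("outline too short for a hull")
    try:
        hull = ConvexHull(pts[:, ::-1])  # (x, y) = (col, row)
    except QhullError as e:
        raise DegenerateHullError(str(e)) from e

    hull_pts = {tuple(pts[:, ::-1][v][::-1]) for v in hull.vertices}
    hull_idx = sorted(
        {next(i for i in range(n) if tuple(pts[i]) == hp) for hp in hull_pts}
    )
    if len(hull_idx) < 2:
        raise DegenerateHullError("degenerate hull")

    start_index = hull_idx[0]
    segments = [
        (hull_idx[k], hull_idx[(k + 1) % len(hull_idx)]) for k in range(len(hull_idx))
    ]

    L = np.zeros(n)
    for (i0, i1) in segments:
        a = pts[i0].astype(float)
        b = pts[i1].astype(float)
        j = i0
        while j != i1:
            L[j] = _perp_distance(pts[j].astype(float), a, b)
            j = (j + 1) % n
    for i in hull_idx:
        L[i] = 0.0

    start = pts[start_index].astype(float)
    G = np.hypot(pts[:, 0] - start[0], pts[:, 1] - start[1])
    return ConcaveSeries(
        L=L, G=G, hull_segments=segments, start_index=start_index, outline=outline
    )


#: Outline points closer than this to their hull chord count as touching
#: the hull (digitization tolerance).
HULL_TOUCH_TOL = 0.5


def candidate_cps(series: ConcaveSeries) -> List[ConcavePoint]:
    """One candidate per convexity defect: the deepest point of each
    maximal outline run that leaves the hull.

    Hull chords are split at every hull-touching outline point, so two
    defects lying under one long collinear chord yield two candidates.
    """
    pts = series.outline.as_array()
    n = len(pts)
    touch = [i for i in range(n) if series.L[i] < HULL_TOUCH_TOL]
    out: List[ConcavePoint] = []
    if not touch:
        return out
    for k in range(len(touch)):
        i0 = touch[k]
        i1 = touch[(k + 1) % len(touch)]
        best_idx = None
        best_val = 0.0
        j = (i0 + 1) % n
        while j != i1:
            if series.L[j] > best_val:
                best_val = series.L[j]
                best_idx = j
            j = (j + 1) % n
        if best_idx is not None and best_val > 0:
            out.append(
                ConcavePoint(
                    index=best_idx,
                    point=Point(int(pts[best_idx, 0]), int(pts[best_idx, 1])),
                    depth=float(best_val),
                )
            )
    return out


def _step_weight(p: np.ndarray, q: np.ndarray) -> float:
    return SQRT2 if (p[0] != q[0] and p[1] != q[1]) else 1.0


def final_cps(
    candidates: List[ConcavePoint],
    series: ConcaveSeries,
    cfg: ShapeConfig = ShapeConfig(),
) -> List[ConcavePoint]:
    """Filter candidates by degree of concavity; keep at most two.

    For each candidate, the concave section is the maximal contiguous
    outline run around it whose G values stay within +-``cp_band`` of the
    candidate's G value; its arc length divided by the straight-line
    distance between the run's two endpoints (the section's own chord)
    must reach ``cp_ratio_th``: a touching notch doubles back on itself
    (arc >> chord) while a gently bent back stays nearly straight.
    Candidates shallower than ``cp_min_depth`` are digitization roughness
    and are dropped first.  If more than two survive, the two deepest
    (largest L) win.
    """
    pts = series.outline.as_array().astype(float)
    n = len(pts)
    survivors: List[ConcavePoint] = []
    for cand in candidates:
        if cand.depth < cfg.cp_min_depth:
            continue
        gc = series.G[cand.index]
        # the band collapses when the candidate sits near the traversal
        # start (G -> 0); floor it at 2 px so the section stays measurable
        half = max(cfg.cp_band * gc, 2.0)
        lo, hi = gc - half, gc + half
        arc = 0.0
        j = cand.index
        while True:
            k = (j - 1) % n
            if not (lo <= series.G[k] <= hi) or k == cand.index:
                break
            arc += _step_weight(pts[j], pts[k])
            j = k
        lo_end = j
        j = cand.index
        while True:
            k = (j + 1) % n
            if not (lo <= series.G[k] <= hi) or k == lo_end:
                break
            arc += _step_weight(pts[j], pts[k])
            j = k
        hi_end = j
        chord = float(np.hypot(*(pts[hi_end] - pts[lo_end])))
        ratio = arc / chord if chord > 0 else np.inf
        if ratio >= cfg.cp_ratio_th:
            survivors.append(
                ConcavePoint(cand.index, cand.point, cand.depth, float(ratio))
            )
    survivors.sort(key=lambda c: (-c.depth, c.index))
    return survivors[: cfg.max_cps]


# ---------------------------------------------------------------------------
# boundary construction


def _supporting_normal(g: Guideline) -> Optional[np.ndarray]:
    v = np.asarray(g.end_b, float) - np.asarray(g.end_a, float)
    if np.hypot(*v) == 0:
        return None
    return np.array([-v[1], v[0]])


def _side(normal: np.ndarray, origin: Point, p: Point) -> float:
    return float(normal @ (np.asarray(p, float) - np.asarray(origin, float)))


def _dist(p, q) -> float:
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def _assemble(
    mask: Mask, *chunks: Sequence[Point]
) -> BoundaryLine:
    grid = mask.grid
    pts: List[Point] = []
    for ch in chunks:
        pts.extend(ch)
    pts = make_4connected(pts)
    pts = [p for p in pts if grid[p[0], p[1]]]
    return BoundaryLine(points=dedupe_path(pts))


def boundary_from_shape(
    guideline: Guideline,
    cps: List[ConcavePoint],
    outline: Outline,
    mask: Mask,
    validate=None,
    max_retries: int = 5,
) -> BoundaryLine:
    """Join guideline ends with concave points (or outline points) into a cut.

    ``validate`` is an optional callable raising on an invalid cut (the
    caller typically passes a ``split_by_line`` probe); retries walk to the
    next-nearest search-region point, at most ``max_retries`` times.
    """
    if not guideline.points:
        raise ValueError("empty guideline")
    ea, eb = guideline.end_a, guideline.end_b
    opts = outline.as_array()

    def check(line: BoundaryLine) -> bool:
        if validate is None:
            return True
        try:
            validate(line)
            return True
        except Exception:
            return False

    if len(cps) >= 2:
        c1, c2 = cps[0].point, cps[1].point
        variants = sorted(
            ((c1, ea, eb, c2), (c1, eb, ea, c2)),
            key=lambda v: _dist(v[0], v[1]) + _dist(v[2], v[3]),
        )
        for (p1, e1, e2, p2) in variants:
            line = _assemble(
                mask,
                rasterize_segment(p1, e1),
                guideline.points,
                rasterize_segment(e2, p2),
            )
            if check(line):
                return line
        raise NoValidCutError("both concave-point assignments failed")

    normal = _supporting_normal(guideline)

    def region_candidates(ref_point: Point, anchor: Point) -> List[Point]:
        """Outline points on the opposite side of the guideline from
        ``ref_point``, nearest to ``anchor`` first."""
        if normal is not None:
            s = _side(normal, ea, ref_point)
            sides = (opts - np.asarray(ea, float)) @ normal
            sel = sides * s < 0
        else:
            d = np.asarray(ref_point, float) - np.asarray(ea, float)
            sel = (opts - np.asarray(ea, float)) @ d < 0
        cand = opts[sel] if sel.any() else opts
        order = np.argsort(
            np.hypot(cand[:, 0] - anchor[0], cand[:, 1] - anchor[1]), kind="stable"
        )
        return [Point(int(r), int(c)) for r, c in cand[order]]

    if len(cps) == 1:
        cp = cps[0].point
        e1, e2 = (ea, eb) if _dist(cp, ea) <= _dist(cp, eb) else (eb, ea)
        for q in region_candidates(cp, e2)[: max_retries + 1]:
            line = _assemble(
                mask,
                rasterize_segment(cp, e1),
                guideline.points,
                rasterize_segment(e2, q),
            )
            if check(line):
                return line
        raise NoValidCutError("single concave-point construction failed")

    # no concave point: attach the end with the closer outline point first
    d_a = np.hypot(opts[:, 0] - ea[0], opts[:, 1] - ea[1])
    d_b = np.hypot(opts[:, 0] - eb[0], opts[:, 1] - eb[1])
    if d_a.min() <= d_b.min():
        e1, e2, q1 = ea, eb, Point(*map(int, opts[int(np.argmin(d_a))]))
    else:
        e1, e2, q1 = eb, ea, Point(*map(int, opts[int(np.argmin(d_b))]))
    for q2 in region_candidates(q1, e2)[: max_retries + 1]:
        line = _assemble(
            mask,
            rasterize_segment(q1, e1),
            guideline.points,
            rasterize_segment(e2, q2),
        )
        if check(line):
            return line
    raise NoValidCutError("no-concave-point construction failed")
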