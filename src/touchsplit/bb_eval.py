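"""Detector-box evaluation and box-based cutting.

Given one touching blob and a set of candidate detector boxes, score each
box against the blob (size condition, boundary condition, confidence),
select at most two useful boxes, derive a cut line from their geometry and
gate the resulting split on cut length and component size ratio.  Whenever
the geometry is ambiguous the stage raises :class:`Fallback` so the caller
can route the blob to the shape-analysis stage instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import EmptyMaskError, Fallback
from .maskgeom import (
    BBox,
    BoundaryLine,
    Mask,
    Point,
    border_pixels,
    dedupe_path,
    extend_through_blob,
    full_line_through,
    path8_length,
)


@dataclass
class BBEvalConfig:
    """Thresholds of the box-evaluation stage (defaults per the method)."""

    size_lo: float = 0.4
    size_hi: float = 0.6
    boundary_frac: float = 0.2
    probability_th: float = 1.0
    near_band: int = 2
    seg_length_th: int = 20
    seg_size_th: float = 1.5

    def __post_init__(self):
        if not (0 < self.size_lo < self.size_hi < 1):
            raise ValueError("require 0 < size_lo < size_hi < 1")
        if not (0 < self.boundary_frac < 1):
            raise ValueError("boundary_frac must be in (0,1)")
        if self.seg_length_th <= 0 or self.seg_size_th < 1:
            raise ValueError("bad segmentation thresholds")


@dataclass
class RoI:
    """Tight enclosing box of the blob plus its pixel statistics."""

    box: BBox
    pp_roi: int
    bp_roi: int


@dataclass
class UsefulBB:
    box: BBox
    pp_bb: int
    bp_bb: int
    size_ok: bool
    boundary_ok: bool
    confidence: Optional[float] = None

    @property
    def passes(self) -> bool:
        return self.size_ok and self.boundary_ok


def _near_box_perimeter(box: BBox, shape: Tuple[int, int], band: int) -> np.ndarray:
    """Boolean grid: pixels within ``band`` of the box perimeter.

    The band straddles the perimeter (inside and outside the box), so a
    box falling a pixel or two short of the blob tangent still counts the
    border pixels it almost reaches.
    """
    rows, cols = shape
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    outer = (
        (rr >= box.top - band)
        & (rr <= box.bottom + band)
        & (cc >= box.left - band)
        & (cc <= box.right + band)
    )
    inner = (
        (rr >= box.top + band + 1)
        & (rr <= box.bottom - band - 1)
        & (cc >= box.left + band + 1)
        & (cc <= box.right - band - 1)
    )
    return outer & ~inner


def build_roi(mask: Mask, cfg: BBEvalConfig = BBEvalConfig()) -> RoI:
    """Tight bounding box of the blob with pig-pixel and boundary-pixel counts.

    ``bp_roi`` counts the blob's border pixels (all of them lie within the
    RoI, which encloses the blob).
    """
    grid = mask.grid
    if not grid.any():
        raise EmptyMaskError("cannot build RoI of empty mask")
    rs, cs = np.nonzero(grid)
    box = BBox(int(rs.min()), int(cs.min()), int(rs.max()), int(cs.max()))
    return RoI(
        box=box, pp_roi=int(grid.sum()), bp_roi=int(border_pixels(grid).sum())
    )


def filter_candidates(
    bbs: List[BBox], roi: RoI, cfg: BBEvalConfig = BBEvalConfig()
) -> List[BBox]:
    """Drop low-probability boxes and boxes not contained in the RoI.

    Containment is tested with a tolerance of ``near_band`` pixels; boxes
    within tolerance are clipped to the RoI box.
    """
    out: List[BBox] = []
    t = cfg.near_band
    rb = roi.box
    for bb in bbs:
        if bb.probability < cfg.probability_th:
            continue
        if (
            bb.top < rb.top - t
            or bb.left < rb.left - t
            or bb.bottom > rb.bottom + t
            or bb.right > rb.right + t
        ):
            continue
        out.append(
            BBox(
                max(bb.top, rb.top),
                max(bb.left, rb.left),
                min(bb.bottom, rb.bottom),
                min(bb.right, rb.right),
                bb.probability,
            )
        )
    return out


#: Denominator floor for the confidence score when the box holds exactly
#: half the blob (the printed formula diverges there by construction).
CONFIDENCE_EPS = 0.5


def evaluate_bb(
    bb: BBox, mask: Mask, roi: RoI, cfg: BBEvalConfig = BBEvalConfig()
) -> UsefulBB:
    """Score one candidate box against the blob.

    size condition:      size_lo*PP_RoI <= PP_BB <= size_hi*PP_RoI
    boundary condition:  boundary_frac*BP_RoI <= BP_BB
    confidence:          (BP_BB - 0.2*BP_RoI) / |PP_BB - 0.5*PP_RoI|

    ``BP_BB`` counts blob border pixels within ``near_band`` of the box
    perimeter: a useful box must run close to a sizable share of the
    blob's outer boundary.
    """
    grid = mask.grid
    sub = grid[bb.top : bb.bottom + 1, bb.left : bb.right + 1]
    pp_bb = int(sub.sum())

    border = border_pixels(grid)
    near_bb = _near_box_perimeter(bb, grid.shape, cfg.near_band)
    bp_bb = int((border & near_bb).sum())

    size_ok = cfg.size_lo * roi.pp_roi <= pp_bb <= cfg.size_hi * roi.pp_roi
    boundary_ok = cfg.boundary_frac * roi.bp_roi <= bp_bb
    conf: Optional[float] = None
    if size_ok and boundary_ok:
        num = bp_bb - cfg.boundary_frac * roi.bp_roi
        den = abs(pp_bb - 0.5 * roi.pp_roi)
        conf = num / max(den, CONFIDENCE_EPS) if den == 0 else num / den
    return UsefulBB(
        box=bb, pp_bb=pp_bb, bp_bb=bp_bb, size_ok=size_ok, boundary_ok=boundary_ok,
        confidence=conf,
    )


def select_useful_bbs(bbs: List[UsefulBB], roi: RoI, mask: Mask) -> List[UsefulBB]:
    """Pick at most two useful boxes: best confidence, then coverage.

    The second box must cover at least half of the blob pixels left outside
    the first box (coverage condition).
    """
    cands = [b for b in bbs if b.passes]
    if not cands:
        return []

    def sort_key(b: UsefulBB):
        return (-b.confidence, -b.pp_bb, b.box.top, b.box.left)

    cands.sort(key=sort_key)
    first = cands[0]
    remaining_pp = roi.pp_roi - first.pp_bb
    if remaining_pp <= 0:
        return [first]

    grid = mask.grid
    outside_first = grid.copy()
    outside_first[
        first.box.top : first.box.bottom + 1, first.box.left : first.box.right + 1
    ] = False
    for b in cands[1:]:
        sub = outside_first[
            b.box.top : b.box.bottom + 1, b.box.left : b.box.right + 1
        ]
        if int(sub.sum()) >= 0.5 * remaining_pp:
            return [first, b]
    return [first]


def _perimeter_cycle(box: BBox) -> List[Point]:
    """Box perimeter pixels in cyclic order (clockwise from top-left)."""
    pts: List[Point] = []
    for c in range(box.left, box.right + 1):
        pts.append(Point(box.top, c))
    for r in range(box.top + 1, box.bottom + 1):
        pts.append(Point(r, box.right))
    if box.bottom > box.top:
        for c in range(box.right - 1, box.left - 1, -1):
            pts.append(Point(box.bottom, c))
    if box.right > box.left:
        for r in range(box.bottom - 1, box.top, -1):
            pts.append(Point(r, box.left))
    return pts


def perimeter_runs(box: BBox, mask: Mask) -> List[List[Point]]:
    """Connected runs of foreground pixels along the box perimeter (cyclic)."""
    cycle = _perimeter_cycle(box)
    grid = mask.grid
    inside = [
        0 <= p.row < grid.shape[0]
        and 0 <= p.col < grid.shape[1]
        and bool(grid[p.row, p.col])
        for p in cycle
    ]
    if all(inside):
        return [list(cycle)]
    if not any(inside):
        return []
    # rotate so the cycle starts on a background pixel, then split runs
    start = inside.index(False)
    order = list(range(start, len(cycle))) + list(range(start))
    runs: List[List[Point]] = []
    cur: List[Point] = []
    for i in order:
        if inside[i]:
            cur.append(cycle[i])
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def cut_with_one_bb(bb: UsefulBB, mask: Mask) -> BoundaryLine:
    """Cut along the single run where the box perimeter crosses the blob.

    Zero runs or two-plus runs are ambiguous and raise :class:`Fallback`.
    """
    runs = perimeter_runs(bb.box, mask)
    if len(runs) == 1 and len(runs[0]) == 2 * (bb.box.height + bb.box.width) - 4:
        # box entirely interior to the blob: every edge crosses
        raise Fallback("single-box perimeter lies wholly inside the blob")
    if len(runs) != 1:
        raise Fallback(f"single-box cut produced {len(runs)} boundary runs")
    return BoundaryLine(points=dedupe_path(runs[0]))


def _cut_is_valid(pts: List[Point], mask: Mask) -> bool:
    """True when removing ``pts`` leaves exactly two 8-connected components."""
    if not pts:
        return False
    from scipy import ndimage

    grid = mask.grid.copy()
    for p in pts:
        grid[p[0], p[1]] = False
    _, n = ndimage.label(grid, structure=np.ones((3, 3), bool))
    return n == 2


def cut_with_two_bbs(a: UsefulBB, b: UsefulBB, mask: Mask) -> BoundaryLine:
    """Cut from the relative geometry of two useful boxes.

    Overlapping rectangle: cut along the overlap diagonal more orthogonal
    to the segment joining the box centers, extended through the blob.
    Overlap degenerated to a line: cut along that shared edge.  Disjoint
    boxes: cut along the midline of the gap between the nearest edges.
    """
    grid = mask.grid
    ba, bb_ = a.box, b.box
    ov_top, ov_bottom = max(ba.top, bb_.top), min(ba.bottom, bb_.bottom)
    ov_left, ov_right = max(ba.left, bb_.left), min(ba.right, bb_.right)

    if ov_top <= ov_bottom and ov_left <= ov_right:
        if ov_top < ov_bottom and ov_left < ov_right:
            # Case 1: proper overlap rectangle -> transverse diagonal
            ca, cb = ba.center(), bb_.center()
            axis = np.array([cb[0] - ca[0], cb[1] - ca[1]], dtype=float)
            d1 = (Point(ov_top, ov_left), Point(ov_bottom, ov_right))
            d2 = (Point(ov_top, ov_right), Point(ov_bottom, ov_left))

            def alignment(diag):
                v = np.array(
                    [diag[1].row - diag[0].row, diag[1].col - diag[0].col], float
                )
                na = np.linalg.norm(axis)
                nv = np.linalg.norm(v)
                if na == 0 or nv == 0:
                    return 0.0
                return abs(float(np.dot(axis, v))) / (na * nv)

            first, second = (d1, d2) if alignment(d1) <= alignment(d2) else (d2, d1)
            # gather candidate cuts and keep the shortest valid one: the
            # seam between two touching bodies is the minimal cross-section
            ctr = Point(
                int(round((ov_top + ov_bottom) / 2.0)),
                int(round((ov_left + ov_right) / 2.0)),
            )
            candidates = [
                extend_through_blob(first[0], first[1], mask),
                extend_through_blob(second[0], second[1], mask),
            ]
            if np.hypot(*axis) > 0:
                candidates.append(
                    full_line_through(mask, ctr, (-axis[1], axis[0]))
                )
            for diag in (first, second):
                candidates.append(
                    full_line_through(
                        mask,
                        ctr,
                        (
                            float(diag[1].row - diag[0].row),
                            float(diag[1].col - diag[0].col),
                        ),
                    )
                )
            valid = [c for c in candidates if _cut_is_valid(c, mask)]
            pts = min(valid, key=path8_length) if valid else candidates[0]
        else:
            # Case 2: overlap is a single row or column (or a point)
            pts = extend_through_blob(
                Point(ov_top, ov_left), Point(ov_bottom, ov_right), mask
            )
    else:
        # Case 3: disjoint boxes -> midline of the separating gap
        gap_c = ov_left - ov_right  # >0 when separated horizontally
        gap_r = ov_top - ov_bottom
        if gap_c >= gap_r:
            mid = (ov_right + ov_left) // 2  # between right edge of one, left of other
            lo = min(ba.top, bb_.top)
            hi = max(ba.bottom, bb_.bottom)
            pts = extend_through_blob(Point(lo, mid), Point(hi, mid), mask)
        else:
            mid = (ov_bottom + ov_top) // 2
            lo = min(ba.left, bb_.left)
            hi = max(ba.right, bb_.right)
            pts = extend_through_blob(Point(mid, lo), Point(mid, hi), mask)

    pts = [p for p in pts if grid[p.row, p.col]]
    if not pts:
        raise Fallback("two-box cut does not intersect the blob")
    return BoundaryLine(points=dedupe_path(pts))


def quality_gate(
    line: BoundaryLine, labels: np.ndarray, cfg: BBEvalConfig = BBEvalConfig()
) -> bool:
    """Accept a box-based split only if the cut is short and balanced."""
    if line.length > cfg.seg_length_th:
        return False
    n1 = int((labels == 1).sum())
    n2 = int((labels == 2).sum())
    if min(n1, n2) == 0:
        return False
    return max(n1, n2) / min(n1, n2) <= cfg.seg_size_th
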