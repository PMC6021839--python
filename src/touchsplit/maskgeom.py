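"""Grid and geometry primitives: masks, outlines, boxes, boundary lines.

Conventions used throughout the package:

* coordinates are 0-based ``(row, col)`` with the origin at the top-left
  and rows increasing downward;
* foreground is 8-connected, background 4-connected (standard duality);
* box bounds are inclusive on all four sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import BadCutError, EmptyMaskError, MultiComponentError

#: 3x3 structuring element for 8-connected labelling.
STRUCT_8 = np.ones((3, 3), dtype=bool)


class Point(NamedTuple):
    row: int
    col: int


@dataclass(frozen=True)
class Mask:
    """A dense binary grid holding one blob (or a whole frame's foreground)."""

    grid: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        object.__setattr__(self, "grid", g.astype(bool))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape

    def count(self) -> int:
        return int(self.grid.sum())

    def is_single_component(self) -> bool:
        _, n = ndimage.label(self.grid, structure=STRUCT_8)
        return n == 1


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box with inclusive pixel bounds and a detector probability."""

    top: int
    left: int
    bottom: int
    right: int
    probability: float = 1.0

    def __post_init__(self):
        if self.top > self.bottom or self.left > self.right:
            raise ValueError(f"degenerate box {self}")

    @property
    def height(self) -> int:
        return self.bottom - self.top + 1

    @property
    def width(self) -> int:
        return self.right - self.left + 1

    def area(self) -> int:
        return self.height * self.width

    def clip(self, rows: int, cols: int) -> "BBox":
        return BBox(
            max(0, self.top),
            max(0, self.left),
            min(rows - 1, self.bottom),
            min(cols - 1, self.right),
            self.probability,
        )

    def center(self) -> Tuple[float, float]:
        return ((self.top + self.bottom) / 2.0, (self.left + self.right) / 2.0)


@dataclass
class Outline:
    """Closed 8-connected border contour, clockwise in image view."""

    points: List[Point]
    start_index: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=int)


@dataclass
class BoundaryLine:
    """Pixel path whose removal is meant to split a blob in two.

    ``points`` may be thickened to 4-connectivity so the cut actually
    severs an 8-connected blob; ``length`` reports the 8-connected pixel
    count (corner pixels inserted to fill diagonal steps do not count).
    """

    points: List[Point]

    @property
    def length(self) -> int:
        return path8_length(self.points)


def path8_length(points: Sequence[Point]) -> int:
    """Pixel count of a path with 4-connect corner fills collapsed.

    A corner pixel q between p and r where p,r are diagonal 8-neighbors
    and q is 4-adjacent to both is an artifact of :func:`make_4connected`
    and is not counted.
    """
    n = len(points)
    if n < 3:
        return n
    count = 1
    prev = points[0]
    i = 1
    while i < n:
        if i + 1 < n:
            q, r = points[i], points[i + 1]
            if (
                r[0] != prev[0]
                and r[1] != prev[1]
                and max(abs(prev[0] - r[0]), abs(prev[1] - r[1])) == 1
                and abs(prev[0] - q[0]) + abs(prev[1] - q[1]) == 1
                and abs(r[0] - q[0]) + abs(r[1] - q[1]) == 1
            ):
                count += 1
                prev = r
                i += 2
                continue
        count += 1
        prev = points[i]
        i += 1
    return count


def border_pixels(grid: np.ndarray) -> np.ndarray:
    """Foreground pixels having at least one background 4-neighbor.

    Pixels on the grid edge count as border (the outside is background).
    """
    g = np.asarray(grid, dtype=bool)
    padded = np.pad(g, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return g & ~interior


# Moore neighborhood in clockwise order (image view, rows increase downward),
# starting from west: W, NW, N, NE, E, SE, S, SW.
_MOORE_CW = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def extract_outline(mask: Mask) -> Outline:
    """Trace the closed outer contour of a single-component blob.

    Moore-neighbor tracing with Jacob's stopping criterion; the walk is
    clockwise when viewed with rows increasing downward.  Interior hole
    borders are not visited.
    """
    grid = mask.grid
    if not grid.any():
        raise EmptyMaskError("no foreground pixel")
    _, n = ndimage.label(grid, structure=STRUCT_8)
    if n > 1:
        raise MultiComponentError(f"{n} components")

    rows, cols = grid.shape
    rs, cs = np.nonzero(grid)
    start = Point(int(rs[0]), int(cs[0]))  # topmost, then leftmost

    def fg(r: int, c: int) -> bool:
        return 0 <= r < rows and 0 <= c < cols and bool(grid[r, c])

    if not any(fg(start.row + dr, start.col + dc) for dr, dc in _MOORE_CW):
        return Outline(points=[start])

    contour: List[Point] = []
    # backtrack starts west of the raster-first pixel, which is background
    p = start
    back = (0, -1)
    first_state = (p, back)
    max_steps = 4 * len(rs) + 8
    for _ in range(max_steps):
        contour.append(p)
        k = _MOORE_CW.index(back)
        nxt = None
        for j in range(1, 9):
            dr, dc = _MOORE_CW[(k + j) % 8]
            if fg(p.row + dr, p.col + dc):
                nxt = Point(p.row + dr, p.col + dc)
                # new backtrack: the neighbor examined just before the hit,
                # expressed relative to the next pixel
                pdr, pdc = _MOORE_CW[(k + j - 1) % 8]
                prev_bg = (p.row + pdr, p.col + pdc)
                back = (prev_bg[0] - nxt.row, prev_bg[1] - nxt.col)
                break
        if nxt is None:  # pragma: no cover - guarded by isolated-pixel check
            break
        p = nxt
        if (p, back) == first_state:
            break
    return Outline(points=contour)


def rasterize_segment(a: Point, b: Point) -> List[Point]:
    """8-connected digital straight segment from ``a`` to ``b`` inclusive.

    Bresenham convention.  ``rasterize_segment(a, b)`` and
    ``rasterize_segment(b, a)`` are each valid 8-paths of the same length
    but are not guaranteed to be point-for-point mirror images (the
    classic Bresenham asymmetry); callers must not rely on symmetry.
    """
    r0, c0 = int(a[0]), int(a[1])
    r1, c1 = int(b[0]), int(b[1])
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    pts: List[Point] = []
    if dc >= dr:
        err = dc // 2
        r = r0
        for c in range(c0, c1 + sc, sc):
            pts.append(Point(r, c))
            err -= dr
            if err < 0:
                r += sr
                err += dc
    else:
        err = dr // 2
        c = c0
        for r in range(r0, r1 + sr, sr):
            pts.append(Point(r, c))
            err -= dc
            if err < 0:
                c += sc
                err += dr
    return pts


def split_by_line(mask: Mask, line: BoundaryLine) -> np.ndarray:
    """Remove the line's pixels and label the two remaining components.

    Returns a label map with 0 = background and 1/2 = the two blob halves.
    Line pixels are re-assigned each to the label of the nearest component
    pixel (Euclidean; ties go to the lower label), so the result partitions
    the input foreground exactly.  Label 1 is the component with the
    smaller centroid row (ties: smaller centroid column).

    Raises :class:`BadCutError` if removal yields anything but exactly two
    8-connected components.
    """
    grid = mask.grid
    line_mask = np.zeros_like(grid)
    for p in line.points:
        if 0 <= p[0] < grid.shape[0] and 0 <= p[1] < grid.shape[1]:
            line_mask[p[0], p[1]] = True
    line_mask &= grid

    remaining = grid & ~line_mask
    lbl, n = ndimage.label(remaining, structure=STRUCT_8)
    if n != 2:
        raise BadCutError(f"cut produced {n} components", n_components=n)

    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[lbl == 1] = 1
    labels[lbl == 2] = 2
    if line_mask.any():
        d1 = ndimage.distance_transform_edt(lbl != 1)
        d2 = ndimage.distance_transform_edt(lbl != 2)
        on_line = line_mask
        labels[on_line & (d1 <= d2)] = 1
        labels[on_line & (d1 > d2)] = 2

    return _order_labels(labels)


def _order_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel so component 1 has the smaller centroid row (ties: col)."""
    keys = []
    for v in (1, 2):
        rs, cs = np.nonzero(labels == v)
        keys.append((float(rs.mean()), float(cs.mean())))
    if keys[1] < keys[0]:
        out = labels.copy()
        out[labels == 1] = 2
        out[labels == 2] = 1
        return out
    return labels


def make_4connected(points: Sequence[Point]) -> List[Point]:
    """Insert a pixel at every diagonal step so the path becomes
    4-connected.  Removing a 4-connected path is what actually severs an
    8-connected blob; a purely diagonal cut leaves its two sides touching.
    """
    out: List[Point] = []
    prev: Point | None = None
    for p in points:
        p = Point(int(p[0]), int(p[1]))
        if prev is not None and p[0] != prev[0] and p[1] != prev[1]:
            out.append(Point(prev[0], p[1]))
        out.append(p)
        prev = p
    return out


def extend_through_blob(a: Point, b: Point, mask: Mask) -> List[Point]:
    """Rasterize ``a``->``b`` and extend both ends along the same direction
    until leaving the foreground; returns only foreground pixels."""
    grid = mask.grid
    rows, cols = grid.shape
    seg = rasterize_segment(a, b)
    dr = b.row - a.row
    dc = b.col - a.col
    if dr == 0 and dc == 0:
        dc = 1  # degenerate segment: extend horizontally
    norm = max(abs(dr), abs(dc), 1)
    fdr, fdc = dr / norm, dc / norm

    def march(start: Point, sgn: int) -> List[Point]:
        out: List[Point] = []
        t = 1
        while t <= rows + cols:
            r = int(round(start[0] + sgn * fdr * t))
            c = int(round(start[1] + sgn * fdc * t))
            if not (0 <= r < rows and 0 <= c < cols) or not grid[r, c]:
                break
            out.append(Point(r, c))
            t += 1
        return out

    head = march(seg[0], -1)
    tail = march(seg[-1], +1)
    full = make_4connected(list(reversed(head)) + seg + tail)
    return dedupe_path([p for p in full if grid[p[0], p[1]]])


def full_line_through(
    mask: Mask, origin: Point, direction: Tuple[float, float]
) -> List[Point]:
    """Foreground pixels of the full straight line through ``origin`` with
    ``direction``, spanning the whole grid (4-connected)."""
    grid = mask.grid
    rows, cols = grid.shape
    dr, dc = direction
    norm = max(abs(dr), abs(dc))
    if norm == 0:
        dr, dc, norm = 0.0, 1.0, 1.0
    dr, dc = dr / norm, dc / norm
    span = rows + cols
    pts = []
    for t in range(-span, span + 1):
        r = int(round(origin[0] + dr * t))
        c = int(round(origin[1] + dc * t))
        if 0 <= r < rows and 0 <= c < cols:
            pts.append(Point(r, c))
    pts = make_4connected(dedupe_path(pts))
    return [p for p in pts if grid[p[0], p[1]]]


def dedupe_path(points: Sequence[Point]) -> List[Point]:
    """Drop consecutive duplicates and repeated pixels, preserving order."""
    seen = set()
    out: List[Point] = []
    for p in points:
        p = Point(int(p[0]), int(p[1]))
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out
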