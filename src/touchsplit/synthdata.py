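"""Synthetic touching-ellipse fixtures with per-pixel ground truth.

Generates pairs of rasterized ellipses whose union forms one 8-connected
blob with a controllable contact (neck) width, optional enclosed holes at
the contact, border noise, and simulated detector boxes — enough to drive
every stage of the separation pipeline without any real imagery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .maskgeom import BBox, Mask, STRUCT_8, border_pixels

#: Default ellipse semi-axes: length about 35 px, width about 10 px.
DEFAULT_AXES = (17.0, 5.0)


@dataclass(frozen=True)
class PairSpec:
    axes_a: Tuple[float, float] = DEFAULT_AXES
    axes_b: Tuple[float, float] = DEFAULT_AXES
    angle_a: float = 0.0
    angle_b: float = 0.0
    contact_width: float = 8.0
    hole_prob: float = 0.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.axes_a[1], self.axes_b[1]) < 3:
            raise ValueError("semi-minor axes must be >= 3")
        if self.contact_width < 0:
            raise ValueError("contact_width must be >= 0")
        for p in (self.hole_prob, self.noise_rate):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0,1]")


@dataclass
class Fixture:
    mask: Mask
    truth: np.ndarray  # {0,1,2}
    bbs: List[BBox]
    spec: PairSpec


def ellipse_inside(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    axes: Tuple[float, float],
    angle: float,
) -> np.ndarray:
    """Boolean raster of a rotated ellipse (pixel-center inclusion test)."""
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    # major axis runs along columns when angle == 0
    u = cc * ca + rr * sa
    v = -cc * sa + rr * ca
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _raster_pair(spec: PairSpec, dist: float):
    """Rasterize the two ellipses separated by ``dist`` along the column
    axis, in a grid with a 6-pixel margin."""
    margin = 6.0
    ext_a = max(spec.axes_a)
    ext_b = max(spec.axes_b)
    height = 2 * max(ext_a, ext_b) + 2 * margin
    width = ext_a + dist + ext_b + 2 * margin
    shape = (int(math.ceil(height)) + 1, int(math.ceil(width)) + 1)
    cy = shape[0] / 2.0
    cx_a = margin + ext_a
    cx_b = cx_a + dist
    ea = ellipse_inside(shape, (cy, cx_a), spec.axes_a, spec.angle_a)
    eb = ellipse_inside(shape, (cy, cx_b), spec.axes_b, spec.angle_b)
    return ea, eb, (cy, cx_a), (cy, cx_b)


def _neck_width(ea: np.ndarray, eb: np.ndarray, cx_a: float, cx_b: float) -> float:
    """Minimum union cross-section (pixels per column) between the centers.

    Returns 0 when the union is not a single 8-connected component.
    """
    union = ea | eb
    _, n = ndimage.label(union, structure=STRUCT_8)
    if n != 1:
        return 0.0
    lo, hi = int(math.floor(cx_a)) + 1, int(math.ceil(cx_b)) - 1
    if hi <= lo:
        return float(union.sum(axis=0).max())
    counts = union[:, lo:hi].sum(axis=0)
    return float(counts.min())


def _fit_distance(spec: PairSpec) -> Tuple[float, float]:
    """Bisect the center distance for the requested neck width.

    Returns ``(distance, achieved_width)``.  Raises when even deep overlap
    cannot reach the request.
    """
    d_hi = (max(spec.axes_a) + max(spec.axes_b)) * 1.2
    d_lo = max(2.0, 0.15 * d_hi)
    lo, hi = d_lo, d_hi
    ea, eb, ca, cb = _raster_pair(spec, lo)
    if _neck_width(ea, eb, ca[1], cb[1]) < spec.contact_width:
        raise ValueError(
            f"contact_width {spec.contact_width} unattainable for these axes"
        )
    for _ in range(40):
        mid = (lo + hi) / 2
        ea, eb, ca, cb = _raster_pair(spec, mid)
        if _neck_width(ea, eb, ca[1], cb[1]) >= spec.contact_width:
            lo = mid
        else:
            hi = mid
    ea, eb, ca, cb = _raster_pair(spec, lo)
    return lo, _neck_width(ea, eb, ca[1], cb[1])


def _achieved_width(spec: PairSpec) -> float:
    return _fit_distance(spec)[1]


def gen_pair(spec: PairSpec) -> Fixture:
    """Build one touching-ellipse fixture.

    The center distance is found by bisection so the neck width comes out
    at ``contact_width`` (within a pixel).  Strongly tilted pairs can make
    the neck width jump discontinuously (the flanks kiss along a line); if
    the achieved width overshoots the request by more than 3 px the angles
    are damped toward zero and the search repeats, and the damped angles
    are recorded on the returned spec.  Overlap pixels go to the nearer
    ellipse center (ties to label 1).  ``contact_width == 0`` yields two
    just-separated components (a negative control for the touching gate).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.contact_width > 0:
        for _ in range(4):
            w = _achieved_width(spec)
            if w <= spec.contact_width + 3:
                break
            spec = replace(
                spec, angle_a=spec.angle_a * 0.6, angle_b=spec.angle_b * 0.6
            )

    if spec.contact_width == 0:
        d = (max(spec.axes_a) + max(spec.axes_b)) * 1.2
        ea, eb, ca, cb = _raster_pair(spec, d)
        while _neck_width(ea, eb, ca[1], cb[1]) > 0 and d < 5 * max(spec.axes_a):
            d *= 1.05
            ea, eb, ca, cb = _raster_pair(spec, d)
    else:
        d, _ = _fit_distance(spec)
        ea, eb, ca, cb = _raster_pair(spec, d)

    union = ea | eb
    truth = np.zeros(union.shape, dtype=np.uint8)
    rr = np.arange(union.shape[0])[:, None]
    cc = np.arange(union.shape[1])[None, :]
    da = (rr - ca[0]) ** 2 + (cc - ca[1]) ** 2
    db = (rr - cb[0]) ** 2 + (cc - cb[1]) ** 2
    truth[ea & ~eb] = 1
    truth[eb & ~ea] = 2
    both = ea & eb
    truth[both & (da <= db)] = 1
    truth[both & (da > db)] = 2

    if spec.contact_width > 0 and rng.random() < spec.hole_prob:
        union, truth = _carve_hole(union, truth, ca[1], cb[1], rng)
    if spec.noise_rate > 0:
        union, truth = _apply_noise(union, truth, spec.noise_rate, rng)

    return Fixture(mask=Mask(union), truth=truth, bbs=[], spec=spec)


def _carve_hole(union, truth, cx_a, cx_b, rng):
    """Remove a short horizontal run of interior pixels at the neck center,
    keeping the resulting background region fully enclosed."""
    lo, hi = int(cx_a) + 1, int(cx_b)
    if hi <= lo:
        return union, truth
    counts = union[:, lo:hi].sum(axis=0)
    c_star = lo + int(np.argmin(counts))
    rows = np.nonzero(union[:, c_star])[0]
    if len(rows) < 5:
        return union, truth
    r_star = int(rows[len(rows) // 2])
    h = int(rng.integers(1, 5))
    h = min(h, 4)
    # the contact seam runs transverse to the join axis: carve vertically
    cand = [(r_star + k - h // 2, c_star) for k in range(h)]
    out_u = union.copy()
    for (r, c) in cand:
        if 0 <= r < union.shape[0] and 0 <= c < union.shape[1]:
            out_u[r, c] = False
    # accept only if the carved region is enclosed and the blob stays whole
    bg_lbl, _ = ndimage.label(~out_u, structure=ndimage.generate_binary_structure(2, 1))
    edge = set(np.unique(bg_lbl[0, :])) | set(np.unique(bg_lbl[-1, :]))
    edge |= set(np.unique(bg_lbl[:, 0])) | set(np.unique(bg_lbl[:, -1]))
    carved_labels = {bg_lbl[r, c] for (r, c) in cand if 0 <= r < union.shape[0]}
    _, n = ndimage.label(out_u, structure=STRUCT_8)
    if n != 1 or carved_labels & edge:
        return union, truth
    out_t = truth.copy()
    out_t[~out_u] = 0
    return out_u, out_t


def _apply_noise(union, truth, rate, rng):
    """Flip a fraction of border pixels to background, then keep the
    largest component and re-tidy the truth labels."""
    border = border_pixels(union)
    idx = np.transpose(np.nonzero(border))
    k = int(round(rate * len(idx)))
    if k == 0:
        return union, truth
    pick = rng.choice(len(idx), size=k, replace=False)
    out_u = union.copy()
    out_u[idx[pick, 0], idx[pick, 1]] = False
    lbl, n = ndimage.label(out_u, structure=STRUCT_8)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, n + 1))
        out_u = lbl == (int(np.argmax(sizes)) + 1)
    out_t = truth.copy()
    out_t[~out_u] = 0
    # keep each truth label a single component: fold strays into the other label
    for v, other in ((1, 2), (2, 1)):
        l2, m = ndimage.label(out_t == v, structure=STRUCT_8)
        if m > 1:
            sizes = ndimage.sum_labels(np.ones_like(l2), l2, index=range(1, m + 1))
            keep = int(np.argmax(sizes)) + 1
            out_t[(l2 > 0) & (l2 != keep)] = other
    return out_u, out_t


def gen_bbs(
    fixture: Fixture, jitter: int = 0, drop_prob: float = 0.0, seed: int = 0
) -> List[BBox]:
    """Simulated detector boxes: jittered truth boxes plus distractors."""
    rng = np.random.default_rng(seed)
    rows, cols = fixture.truth.shape
    out: List[BBox] = []
    for v in (1, 2):
        rs, cs = np.nonzero(fixture.truth == v)
        if len(rs) == 0:
            continue
        if rng.random() < drop_prob:
            continue
        j = rng.integers(-jitter, jitter + 1, size=4) if jitter > 0 else np.zeros(4, int)
        top = int(np.clip(rs.min() + j[0], 0, rows - 1))
        left = int(np.clip(cs.min() + j[1], 0, cols - 1))
        bottom = int(np.clip(rs.max() + j[2], top, rows - 1))
        right = int(np.clip(cs.max() + j[3], left, cols - 1))
        out.append(BBox(top, left, bottom, right, float(rng.uniform(0.8, 1.0))))
    for _ in range(int(rng.integers(0, 3))):
        # small distractor at the top-left margin, outside the RoI
        out.append(BBox(0, 0, 1, 1, float(rng.uniform(0.8, 1.0))))
    return out


def gen_suite(n: int, seed: int = 0) -> List[Fixture]:
    """A stratified, deterministic suite of ``n`` fixtures.

    Sweeps contact widths 4..24, angles, hole/no-hole and border noise in
    {0, 0.02, 0.05}; semi-axes scale up with the requested neck so wide
    contacts stay attainable.  Every 13th fixture is a deeply-overlapped
    "smooth" pair (a near-convex union exercising the 0-CP branch).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    base = np.random.default_rng(seed)
    widths = list(range(4, 25, 2))
    noises = [0.0, 0.02, 0.05]
    out: List[Fixture] = []
    for i in range(n):
        fseed = int(base.integers(0, 2**31 - 1))
        cw = widths[i % len(widths)]
        smooth = i % 13 == 12
        # keep the neck notch at least ~4 px deep so concavities are real
        semi_minor = max(5.0, cw / 2.0 + 4.0)
        semi_major = 2.8 * semi_minor
        if smooth:
            cw = int(2 * semi_minor - 2)
            angle_a = angle_b = 0.0
        else:
            angle_a = float(base.uniform(-0.5, 0.5))
            angle_b = float(base.uniform(-0.5, 0.5))
        spec = PairSpec(
            axes_a=(semi_major, semi_minor),
            axes_b=(semi_major * float(base.uniform(0.9, 1.1)), semi_minor),
            angle_a=angle_a,
            angle_b=angle_b,
            contact_width=float(cw),
            hole_prob=1.0 if i % 5 == 0 else 0.0,
            noise_rate=noises[i % len(noises)],
            seed=fseed,
        )
        fix = gen_pair(spec)
        fix.bbs = gen_bbs(fix, jitter=2, drop_prob=0.0, seed=fseed + 1)
        out.append(fix)
    return out
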