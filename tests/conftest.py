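"""Shared fixtures: small deterministic shapes and the synthetic suite."""

import numpy as np
import pytest

from touchsplit.maskgeom import Mask
from touchsplit.synthdata import ellipse_inside, gen_suite

SUITE_N = 200
SUITE_SEED = 0


@pytest.fixture(scope="session")
def suite200():
    return gen_suite(SUITE_N, SUITE_SEED)


@pytest.fixture
def square10():
    return Mask(np.ones((10, 10), dtype=bool))


@pytest.fixture
def disc(radius=12):
    g = ellipse_inside((30, 30), (15, 15), (12, 12), 0.0)
    return Mask(g)


@pytest.fixture
def filled_ellipse():
    """50x30-ish filled ellipse in a padded grid."""
    return Mask(ellipse_inside((40, 62), (20, 31), (25, 15), 0.0))


@pytest.fixture
def annulus():
    outer = ellipse_inside((30, 30), (15, 15), (12, 12), 0.0)
    inner = ellipse_inside((30, 30), (15, 15), (5, 5), 0.0)
    return Mask(outer & ~inner)


def make_dumbbell(neck_half_width=2, neck_len=8, r=10):
    """Two discs joined by a thin horizontal bar; returns (Mask, bar columns)."""
    rows, cols = 2 * r + 9, 4 * r + neck_len + 9
    c1 = (rows // 2, r + 4)
    c2 = (rows // 2, cols - r - 5)
    g = ellipse_inside((rows, cols), c1, (r, r), 0.0) | ellipse_inside(
        (rows, cols), c2, (r, r), 0.0
    )
    bar_cols = range(c1[1], c2[1] + 1)
    for c in bar_cols:
        g[rows // 2 - neck_half_width : rows // 2 + neck_half_width + 1, c] = True
    return Mask(g), (c1, c2)


@pytest.fixture
def dumbbell():
    return make_dumbbell()[0]


# ---------------------------------------------------------------------------
# independent oracles (loop-based on purpose; keep them dumb)


def oracle_border_pixels(grid):
    """Foreground pixels with a background 4-neighbor, by explicit loops."""
    rows, cols = grid.shape
    out = set()
    for r in range(rows):
        for c in range(cols):
            if not grid[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or not grid[rr, cc]:
                    out.add((r, c))
                    break
    return out


def oracle_components(grid):
    """8-connected components by explicit flood fill; returns list of sets."""
    rows, cols = grid.shape
    seen = set()
    comps = []
    for r in range(rows):
        for c in range(cols):
            if grid[r, c] and (r, c) not in seen:
                stack = [(r, c)]
                comp = set()
                while stack:
                    p = stack.pop()
                    if p in seen:
                        continue
                    seen.add(p)
                    comp.add(p)
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            q = (p[0] + dr, p[1] + dc)
                            if (
                                0 <= q[0] < rows
                                and 0 <= q[1] < cols
                                and grid[q[0], q[1]]
                                and q not in seen
                            ):
                                stack.append(q)
                comps.append(comp)
    return comps
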