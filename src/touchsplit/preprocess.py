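"""Depth-frame preprocessing: interpolation, foreground extraction, size gate.

This is a deliberately minimal acquisition chain: depth noise removal is a
2x2 spatial block mean plus an optional 3-frame temporal mean, foreground
extraction is plain background differencing, and motion modelling is left
to the caller (any binary motion mask will do).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage

from .maskgeom import Mask, STRUCT_8


@dataclass
class DepthFrame:
    """Dense non-negative depth grid; ``invalid_value`` marks undefined depth."""

    grid: np.ndarray
    invalid_value: float = 0.0

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("depth grid must be a non-empty 2-D array")
        self.grid = g

    def valid(self) -> np.ndarray:
        return self.grid != self.invalid_value


@dataclass
class GateConfig:
    size_threshold: int = 500
    single_pig_size: int = 350

    def __post_init__(self):
        if self.size_threshold <= 0:
            raise ValueError("size_threshold must be positive")


def spatial_interpolate_2x2(frame: DepthFrame) -> DepthFrame:
    """Halve resolution by averaging valid depths in each 2x2 block.

    Blocks with no valid pixel stay invalid.  Odd dimensions are padded by
    edge replication before blocking.
    """
    g = frame.grid
    if g.shape[0] % 2 or g.shape[1] % 2:
        g = np.pad(g, ((0, g.shape[0] % 2), (0, g.shape[1] % 2)), mode="edge")
    valid = g != frame.invalid_value
    vals = np.where(valid, g, 0.0)

    blocks = vals.reshape(g.shape[0] // 2, 2, g.shape[1] // 2, 2)
    counts = valid.reshape(g.shape[0] // 2, 2, g.shape[1] // 2, 2).sum(axis=(1, 3))
    sums = blocks.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), frame.invalid_value)
    return DepthFrame(out, frame.invalid_value)


def temporal_interpolate(
    current: DepthFrame, next1: DepthFrame, next2: DepthFrame
) -> DepthFrame:
    """Per-pixel mean of the valid depths across three consecutive frames."""
    frames = (current, next1, next2)
    if not (current.grid.shape == next1.grid.shape == next2.grid.shape):
        raise ValueError("temporal_interpolate: frame dimension mismatch")
    inv = current.invalid_value
    stack = np.stack([f.grid for f in frames])
    valid = np.stack([f.valid() for f in frames])
    counts = valid.sum(axis=0)
    sums = np.where(valid, stack, 0.0).sum(axis=0)
    out = np.where(counts > 0, sums / np.maximum(counts, 1), inv)
    return DepthFrame(out, inv)


def foreground_mask(
    frame: DepthFrame, background: DepthFrame, depth_delta: float
) -> Mask:
    """Pixels nearer the overhead camera than the floor by >= depth_delta.

    Invalid pixels (in either frame) are background.
    """
    if frame.grid.shape != background.grid.shape:
        raise ValueError("foreground_mask: dimension mismatch")
    if depth_delta <= 0:
        raise ValueError("depth_delta must be positive")
    ok = frame.valid() & background.valid()
    return Mask(ok & (background.grid - frame.grid >= depth_delta))


def motion_mask(a: DepthFrame, b: DepthFrame, delta: float) -> Mask:
    """Two-frame absolute-difference motion stand-in (both depths valid)."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("motion_mask: dimension mismatch")
    ok = a.valid() & b.valid()
    return Mask(ok & (np.abs(a.grid - b.grid) >= delta))


def gate_touching(labels: np.ndarray, cfg: GateConfig) -> List[Mask]:
    """Keep components strictly larger than the size threshold.

    Each surviving component is returned as its own full-frame-shaped crop:
    the component's bounding box plus a 2-pixel margin, with only that
    component's pixels set.
    """
    labels = np.asarray(labels)
    out: List[Mask] = []
    for v in range(1, int(labels.max()) + 1):
        comp = labels == v
        n = int(comp.sum())
        if n <= cfg.size_threshold:
            continue
        rs, cs = np.nonzero(comp)
        r0 = max(0, rs.min() - 2)
        r1 = min(labels.shape[0], rs.max() + 3)
        c0 = max(0, cs.min() - 2)
        c1 = min(labels.shape[1], cs.max() + 3)
        out.append(Mask(comp[r0:r1, c0:c1]))
    return out


def label_components(mask: Mask) -> np.ndarray:
    """8-connected component labelling of a binary motion/foreground mask."""
    lbl, _ = ndimage.label(mask.grid, structure=STRUCT_8)
    return lbl
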