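"""File I/O: PNG / .npy grids and JSON box lists."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import numpy as np
from PIL import Image

from .maskgeom import BBox, Mask
from .preprocess import DepthFrame

PathLike = Union[str, Path]

# label -> RGB for the paletted preview
_PALETTE = {0: (0, 0, 0), 1: (230, 80, 80), 2: (80, 120, 230)}


def read_mask(path: PathLike) -> Mask:
    path = Path(path)
    if path.suffix == ".npy":
        return Mask(np.load(path) != 0)
    arr = np.asarray(Image.open(path).convert("L"))
    return Mask(arr >= 128)


def write_mask(mask: Mask, path: PathLike) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, mask.grid.astype(np.uint8))
        return
    Image.fromarray((mask.grid * 255).astype(np.uint8)).save(path)


def read_labels(path: PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path).astype(np.uint8)
    return np.asarray(Image.open(path).convert("L")).astype(np.uint8)


def write_labels(labels: np.ndarray, path: PathLike, preview: bool = False) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, labels.astype(np.uint8))
        return
    Image.fromarray(labels.astype(np.uint8)).save(path)
    if preview:
        rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
        for v, color in _PALETTE.items():
            rgb[labels == v] = color
        Image.fromarray(rgb).save(path.with_name(path.stem + "_preview.png"))


def read_depth(path: PathLike, invalid_value: float = 0.0) -> DepthFrame:
    path = Path(path)
    if path.suffix == ".npy":
        return DepthFrame(np.load(path).astype(float), invalid_value)
    img = Image.open(path)
    return DepthFrame(np.asarray(img).astype(float), invalid_value)


def write_depth(frame: DepthFrame, path: PathLike) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, frame.grid)
        return
    Image.fromarray(np.round(frame.grid).astype(np.uint16)).save(path)


def read_bbs(path: PathLike) -> List[BBox]:
    """JSON list of boxes, either ``{top,left,bottom,right,probability}``
    or ``{x,y,w,h,probability}`` (x/y = left/top corner, w/h = pixel
    extents, so right = x + w - 1 and bottom = y + h - 1)."""
    with open(path) as fh:
        data = json.load(fh)
    out: List[BBox] = []
    for item in data:
        prob = float(item.get("probability", 1.0))
        if "top" in item:
            out.append(
                BBox(
                    int(item["top"]),
                    int(item["left"]),
                    int(item["bottom"]),
                    int(item["right"]),
                    prob,
                )
            )
        elif "x" in item:
            out.append(
                BBox(
                    int(item["y"]),
                    int(item["x"]),
                    int(item["y"]) + int(item["h"]) - 1,
                    int(item["x"]) + int(item["w"]) - 1,
                    prob,
                )
            )
        else:
            raise ValueError(f"unrecognized box record: {item}")
    return out


def write_bbs(bbs: List[BBox], path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "top": b.top,
                    "left": b.left,
                    "bottom": b.bottom,
                    "right": b.right,
                    "probability": b.probability,
                }
                for b in bbs
            ],
            fh,
            indent=2,
        )
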