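"""Flat run configuration shared by the CLI subcommands.

The config file is plain ``key = value`` lines (TOML-style scalars, no
sections); unknown keys are rejected.  Precedence: CLI flag > config file
> built-in default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

from .bb_eval import BBEvalConfig
from .preprocess import GateConfig
from .shape_sep import ShapeConfig

CONFIG_SCHEMA_VERSION = "1"


@dataclass
class RunConfig:
    # box-evaluation stage
    size_lo: float = 0.4
    size_hi: float = 0.6
    boundary_frac: float = 0.2
    probability_th: float = 1.0
    near_band: int = 2
    seg_length_th: int = 20
    seg_size_th: float = 1.5
    # shape stage
    erosion_repeat_th: int = 8
    skeleton_scale: float = 0.5
    cp_band: float = 0.1
    cp_ratio_th: float = 1.05
    # preprocessing gate
    size_threshold: int = 500
    single_pig_size: int = 350

    def bb(self) -> BBEvalConfig:
        return BBEvalConfig(
            size_lo=self.size_lo,
            size_hi=self.size_hi,
            boundary_frac=self.boundary_frac,
            probability_th=self.probability_th,
            near_band=self.near_band,
            seg_length_th=self.seg_length_th,
            seg_size_th=self.seg_size_th,
        )

    def shape(self) -> ShapeConfig:
        return ShapeConfig(
            erosion_repeat_th=self.erosion_repeat_th,
            skeleton_scale=self.skeleton_scale,
            cp_band=self.cp_band,
            cp_ratio_th=self.cp_ratio_th,
        )

    def gate(self) -> GateConfig:
        return GateConfig(
            size_threshold=self.size_threshold,
            single_pig_size=self.single_pig_size,
        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional file, and overrides.

    ``overrides`` with value ``None`` are ignored (unset CLI flags).
    """
    known = {f.name: f.type for f in fields(RunConfig)}
    values = {}
    if path is not None:
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = val.strip()
    for k, v in overrides.items():
        if v is None:
            continue
        if k not in known:
            raise ValueError(f"unknown config key {k!r}")
        values[k] = v

    cfg = RunConfig()
    for k, v in values.items():
        cur = getattr(cfg, k)
        setattr(cfg, k, type(cur)(v))
    # trigger the owning dataclasses' validation
    cfg.bb(), cfg.shape(), cfg.gate()
    return cfg
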