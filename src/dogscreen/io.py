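"""Run configuration and file round-trips.

One JSON config drives a whole run; every output CSV carries a comment
header recording the master seed and the config hash, so any table can be
traced back to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import NoiseConfig, ScreenConfig, TileRaster

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_table",
    "read_table",
    "read_tile_tiff",
    "find_tile_tiffs",
]


@dataclass
class RunConfig:
    """Top-level run configuration (JSON-serializable)."""

    seed: int = 0
    layouts: tuple[str, ...] = ("S-W", "T-S", "T-W", "T-S|W")
    cell_types: tuple[str, ...] = ("MCF10a", "MCF7")
    timepoints_h: tuple[int, ...] = (24, 72)
    replicates: int = 3
    pixel_size_um: float = 0.85
    tile_cols: int | None = None
    tile_rows: int | None = None
    grid_kind: str = "datapoint"
    cluster_um2: float = 2000.0
    min_nucleus_um2: float = 20.0
    min_object_um2: float = 100.0
    bg_radius_um: float = 50.0
    jitter_scale: float = 0.3
    noise: dict = field(default_factory=dict)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            layouts=tuple(self.layouts),
            cell_types=tuple(self.cell_types),
            timepoints_h=tuple(self.timepoints_h),
            replicates=self.replicates,
            pixel_size_um=self.pixel_size_um,
            tile_cols=self.tile_cols,
            tile_rows=self.tile_rows,
            jitter_scale=self.jitter_scale,
            noise=NoiseConfig(**self.noise) if self.noise else NoiseConfig(),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    known = {k: v for k, v in data.items() if k in RunConfig.__dataclass_fields__}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("layouts", "cell_types", "timepoints_h"):
        if key in known:
            known[key] = tuple(known[key])
    return RunConfig(**known)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """CSV with a provenance comment header."""
    parts = []
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    with open(path, "w") as fh:
        if parts:
            fh.write("# " + " ".join(parts) + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def find_tile_tiffs(directory: str | Path) -> list[Path]:
    return sorted(Path(directory).glob("tile_*.tif"))


def read_tile_tiff(path: str | Path, pixel_size_um: float | None = None) -> TileRaster:
    """Read a 3-page tile TIFF (nuclei, cytoskeleton, proliferation).

    Pixel size and tile origin come from the TIFF metadata written by the
    simulator; ``pixel_size_um`` overrides (required for plain TIFFs from
    other sources that carry no metadata).
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-page (C, Y, X) tile stack")
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata; pass pixel_size_um")
    origin = (float(meta.get("origin_u_mm", 0.0)), float(meta.get("origin_v_mm", 0.0)))
    index = (int(meta.get("tile_i", 0)), int(meta.get("tile_j", 0)))
    return TileRaster(
        nuclei=stack[0],
        cytoskeleton=stack[1],
        proliferation=stack[2],
        pixel_size_um=float(px),
        origin_mm=origin,
        index=index,
    )
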