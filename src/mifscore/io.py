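"""Readers and writers binding the pipeline together.

Formats: multi-page TIFF tiles (one page per channel) named ``row_col.tif``
plus a JSON layout file; a single-channel TIFF ground-truth mask; CSV cell
tables; feature tables as CSV and Parquet with a JSON registry manifest.
Channel order is fixed: DAPI, CD3, CD4, CD8, PD-L1, FoxP3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .features import FeatureTable
from .registry import CHANNELS, FeatureRegistry
from .simulate import GroundTruth
from .tiling import Tile

LAYOUT_FILE = "layout.json"
MASK_FILE = "mask.tif"
CELLS_FILE = "truth_cells.csv"


@dataclass
class SlideBundle:
    """One slide as loaded from disk: tiles, layout, mask, optional truth cells."""

    tiles: list[Tile]
    mask: np.ndarray
    grid_shape: tuple[int, int]
    tile_size_px: int
    tile_overlap_px: int
    slide_shape: tuple[int, int]
    channels: tuple[str, ...] = CHANNELS
    truth_cells: pd.DataFrame | None = None
    tile_true_offsets: dict = field(default_factory=dict)
    slide_id: str = "slide"


def write_slide_bundle(
    out_dir: str | Path, tiles: list[Tile], truth: GroundTruth, slide_id: str = "slide"
) -> Path:
    """Write tiles, layout JSON, mask and truth cells; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid_rows = max(t.grid_index[0] for t in tiles) + 1
    grid_cols = max(t.grid_index[1] for t in tiles) + 1
    layout = {
        "slide_id": slide_id,
        "channels": list(CHANNELS),
        "grid_shape": [grid_rows, grid_cols],
        "tile_size_px": tiles[0].size[0],
        "tile_overlap_px": tiles[0].overlap_px,
        "slide_shape": list(truth.mask.shape),
        "tiles": [],
        "true_offsets": {f"{r}_{c}": list(v) for (r, c), v in truth.tile_true_offsets.items()},
    }
    for t in tiles:
        r, c = t.grid_index
        name = f"{r}_{c}.tif"
        tifffile.imwrite(out / name, t.pixels.astype(np.float32))
        layout["tiles"].append(
            {"grid_index": [r, c], "file": name, "nominal_offset_px": list(t.nominal_offset_px)}
        )
    (out / LAYOUT_FILE).write_text(json.dumps(layout, indent=1))
    tifffile.imwrite(out / MASK_FILE, truth.mask.astype(np.uint8))
    truth.cells.to_csv(out / CELLS_FILE)
    return out


def read_slide_bundle(bundle_dir: str | Path) -> SlideBundle:
    """Read a slide bundle written by :func:`write_slide_bundle`.

    Raises specific errors for a missing tile (naming its grid index), a
    channel-count mismatch, or a mask whose size differs from the layout."""
    bundle_dir = Path(bundle_dir)
    layout = json.loads((bundle_dir / LAYOUT_FILE).read_text())
    tiles: list[Tile] = []
    for entry in layout["tiles"]:
        r, c = entry["grid_index"]
        path = bundle_dir / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"missing tile file for grid index ({r}, {c}): {path.name}")
        pixels = tifffile.imread(path)
        if pixels.ndim != 3 or pixels.shape[0] != len(layout["channels"]):
            raise ValueError(
                f"tile ({r}, {c}) has {pixels.shape[0] if pixels.ndim == 3 else 1} channels, "
                f"expected {len(layout['channels'])}"
            )
        tiles.append(
            Tile(
                pixels=pixels,
                grid_index=(r, c),
                nominal_offset_px=tuple(entry["nominal_offset_px"]),
                overlap_px=layout["tile_overlap_px"],
            )
        )
    mask = tifffile.imread(bundle_dir / MASK_FILE)
    if list(mask.shape) != layout["slide_shape"]:
        raise ValueError(
            f"mask shape {mask.shape} does not match slide shape {layout['slide_shape']}"
        )
    cells_path = bundle_dir / CELLS_FILE
    truth_cells = pd.read_csv(cells_path, index_col=0) if cells_path.exists() else None
    true_offsets = {
        tuple(int(v) for v in k.split("_")): tuple(v2 for v2 in v)
        for k, v in layout.get("true_offsets", {}).items()
    }
    return SlideBundle(
        tiles=tiles,
        mask=mask,
        grid_shape=tuple(layout["grid_shape"]),
        tile_size_px=layout["tile_size_px"],
        tile_overlap_px=layout["tile_overlap_px"],
        slide_shape=tuple(layout["slide_shape"]),
        channels=tuple(layout["channels"]),
        truth_cells=truth_cells,
        tile_true_offsets=true_offsets,
        slide_id=layout.get("slide_id", "slide"),
    )


def fuse_tiles_to_slide(
    tiles: list[Tile], offsets: dict, slide_shape: tuple[int, int]
) -> np.ndarray:
    """Paste tiles at the given offsets into one slide raster (later tiles
    overwrite overlap seams; adequate for synthetic data without vignetting)."""
    n_ch = tiles[0].pixels.shape[0]
    slide = np.zeros((n_ch,) + tuple(slide_shape), dtype=np.float32)
    for t in sorted(tiles, key=lambda t: t.grid_index):
        oy, ox = offsets[t.grid_index]
        th, tw = t.size
        # clip to the slide bounds (refined offsets may run slightly outside)
        y0, x0 = max(0, oy), max(0, ox)
        y1, x1 = min(slide_shape[0], oy + th), min(slide_shape[1], ox + tw)
        if y1 <= y0 or x1 <= x0:
            continue
        slide[:, y0:y1, x0:x1] = t.pixels[:, y0 - oy : y1 - oy, x0 - ox : x1 - ox]
    return slide


def write_feature_table(table: FeatureTable, out_prefix: str | Path) -> None:
    """Write CSV + Parquet + JSON registry manifest, self-describing."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    df = table.df.copy()
    df["label"] = table.labels
    df.to_csv(out_prefix.with_suffix(".csv"))
    df.to_parquet(out_prefix.with_suffix(".parquet"))
    manifest = table.registry.manifest()
    manifest["slide_id"] = table.slide_id
    manifest["n_cells"] = len(table)
    out_prefix.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))


def read_feature_table(out_prefix: str | Path) -> FeatureTable:
    out_prefix = Path(out_prefix)
    manifest = json.loads(out_prefix.with_suffix(".manifest.json").read_text())
    df = pd.read_csv(out_prefix.with_suffix(".csv"), index_col=0)
    labels = df.pop("label").to_numpy()
    names = [f["name"] for f in manifest["features"]]
    registry = FeatureRegistry.default()
    if registry.names != names:
        from .registry import FeatureEntry

        registry = FeatureRegistry([FeatureEntry(f["name"], f["group"]) for f in manifest["features"]])
    table = FeatureTable(df[names], labels, registry, manifest.get("slide_id", "slide"))
    table.validate()
    return table
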