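"""Rasterise per-cell features into the 10-channel U-net input image.

The channels are, in fixed order: the six per-cell mean channel intensities
(DAPI, CD3, CD4, CD8, PD-L1, FoxP3), the local cell density, the nucleus
area, and the minor and major axis lengths.  Each cell's values are painted
over its nucleus footprint — the true segment footprint when a label image
is available, otherwise a disc of equivalent area centred on the centroid.
Background is 0; where footprints overlap the later cell id wins
(deterministic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..registry import CHANNELS

UNET_CHANNELS: tuple[str, ...] = tuple(
    [f"mean_{ch}" for ch in CHANNELS] + ["density", "area", "minor_axis", "major_axis"]
)


def _disc_coords(cy: float, cx: float, radius: float, shape: tuple[int, int]):
    r = max(int(np.ceil(radius)), 1)
    y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return yy[inside], xx[inside]


def rasterize_cells(
    cells: pd.DataFrame,
    shape: tuple[int, int],
    channels: tuple[str, ...] = UNET_CHANNELS,
    centroid_cols: tuple[str, str] = ("centroid_y", "centroid_x"),
    label_image: np.ndarray | None = None,
    downsample: int = 1,
) -> np.ndarray:
    """Paint cell feature values into a (len(channels), H, W) float raster.

    ``cells`` must contain the centroid columns, every channel column, and —
    when no ``label_image`` is given — an ``area`` column for the equivalent
    disc footprint.  ``label_image`` maps pixels to the DataFrame index of
    the owning cell (0 = background).  Optional integer ``downsample``
    averages non-overlapping blocks.
    """
    out = np.zeros((len(channels),) + tuple(shape), dtype=np.float32)
    ycol, xcol = centroid_cols
    if len(cells):
        ys = cells[ycol].to_numpy(dtype=float)
        xs = cells[xcol].to_numpy(dtype=float)
        if ys.min() < 0 or xs.min() < 0 or ys.max() >= shape[0] or xs.max() >= shape[1]:
            raise ValueError("cell centroid outside the slide bounds")
        values = cells[list(channels)].to_numpy(dtype=np.float32)
        if label_image is not None:
            labs = label_image.astype(np.int64)
            lut = np.full(int(labs.max()) + 1, -1, dtype=np.int64)
            for i, cid in enumerate(cells.index):
                if 0 < int(cid) < len(lut):
                    lut[int(cid)] = i
            py, px = np.nonzero(labs > 0)
            rows = lut[labs[py, px]]
            ok = rows >= 0
            out[:, py[ok], px[ok]] = values[rows[ok]].T
        else:
            areas = cells["area"].to_numpy(dtype=float)
            for i in range(len(cells)):
                radius = np.sqrt(max(areas[i], 1.0) / np.pi)
                yy, xx = _disc_coords(ys[i], xs[i], radius, shape)
                out[:, yy, xx] = values[i][:, None]
    if downsample > 1:
        h = (shape[0] // downsample) * downsample
        w = (shape[1] // downsample) * downsample
        out = (
            out[:, :h, :w]
            .reshape(len(channels), h // downsample, downsample, w // downsample, downsample)
            .mean(axis=(2, 4))
        )
    return out
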