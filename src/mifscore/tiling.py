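"""Tile alignment and detection fusion.

Whole-slide scanners acquire a grid of partially overlapping image tiles whose
nominal positions are known from the stage layout, but the true positions can
be off by a few pixels of mechanical jitter.  Because nucleus detection runs
per tile, the per-tile detection sets must be (1) re-aligned by a
multi-resolution grid search that minimises nearest-neighbour distances
between detections of adjacent tiles in their overlap zones, and (2) fused so
that each nucleus seen by two tiles is kept exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["y", "x", "label", "area"]


@dataclass
class Tile:
    """One 6-channel image tile of the slide grid."""

    pixels: np.ndarray  # (channels, h, w)
    grid_index: tuple[int, int]
    nominal_offset_px: tuple[int, int]  # (y, x) in slide coordinates
    overlap_px: int

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass
class DetectionSet:
    """Per-tile nucleus detections in tile-local (y, x) coordinates."""

    per_tile: dict[tuple[int, int], pd.DataFrame] = field(default_factory=dict)

    def add(self, grid_index: tuple[int, int], detections: pd.DataFrame) -> None:
        missing = [c for c in DETECTION_COLUMNS if c not in detections.columns]
        if missing:
            raise ValueError(f"detections missing columns {missing}")
        self.per_tile[grid_index] = detections.reset_index(drop=True)

    def n_detections(self) -> int:
        return sum(len(df) for df in self.per_tile.values())


def _in_box(pts: np.ndarray, box: tuple[float, float, float, float], pad: float) -> np.ndarray:
    y0, x0, y1, x1 = box
    return pts[
        (pts[:, 0] >= y0 - pad)
        & (pts[:, 0] < y1 + pad)
        & (pts[:, 1] >= x0 - pad)
        & (pts[:, 1] < x1 + pad)
    ]


class _PairMatcher:
    """Fixed query/candidate sets for one adjacent tile pair.

    The overlap box is taken from the *nominal* geometry and the query sets
    are frozen before the search, so every candidate offset is scored on the
    same detections (a shift cannot lower its cost by pushing detections out
    of the overlap).  Candidate sets are padded by the search range so a
    duplicate detection near the box edge still matches its twin.
    """

    def __init__(
        self,
        tile_pts_nominal: np.ndarray,  # tile detections at the nominal offset
        nb_pts: np.ndarray,  # anchored neighbour detections, slide coords
        box: tuple[float, float, float, float],
        pad: float,
    ):
        self.query_tile = _in_box(tile_pts_nominal, box, pad / 2)
        self.query_nb = _in_box(nb_pts, box, pad / 2)
        cand_nb = _in_box(nb_pts, box, 2 * pad)
        cand_tile = _in_box(tile_pts_nominal, box, 2 * pad)
        self.tree_nb = cKDTree(cand_nb) if len(cand_nb) else None
        self.tree_tile = cKDTree(cand_tile) if len(cand_tile) else None
        # truncation cap: a detection with no twin on the other side (cell
        # seen by only one tile) contributes a constant instead of dragging
        # the optimum toward an unrelated cell
        self.cap = pad + 2.0

    @property
    def empty(self) -> bool:
        return (len(self.query_tile) == 0 or self.tree_nb is None) and (
            len(self.query_nb) == 0 or self.tree_tile is None
        )

    def cost(self, delta: np.ndarray) -> float:
        """Summed NN distances at tile displacement ``delta`` from nominal."""
        c = 0.0
        if len(self.query_tile) and self.tree_nb is not None:
            d = self.tree_nb.query(self.query_tile + delta)[0]
            c += float(np.minimum(d, self.cap).sum())
        if len(self.query_nb) and self.tree_tile is not None:
            # shifting the tile by delta moves its candidates by delta;
            # equivalently query the fixed tree at (neighbour - delta)
            d = self.tree_tile.query(self.query_nb - delta)[0]
            c += float(np.minimum(d, self.cap).sum())
        return c


def refine_alignment(
    detections: DetectionSet,
    tiles: list[Tile],
    levels: int = 3,
    max_shift_px: int = 8,
) -> dict[tuple[int, int], tuple[int, int]]:
    """Refine per-tile offsets by coarse-to-fine grid search.

    The anchor tile (0, 0) keeps its nominal offset.  The remaining tiles are
    processed in row-major order; each is shifted within ``±max_shift_px`` of
    its nominal offset to minimise the summed nearest-neighbour distances
    between its detections and those of already-anchored neighbour tiles in
    the geometric overlap.  The search uses ``levels`` resolutions with stride
    halving (default strides 4, 2, 1) and always includes the nominal offset,
    so the returned cost never exceeds the nominal cost.

    Returns a dict mapping grid index to integer (y, x) offset.
    """
    if not tiles:
        raise ValueError("at least one tile is required")
    for t in tiles:
        if max_shift_px > t.overlap_px / 2 and t.overlap_px > 0:
            raise ValueError(
                f"max_shift_px={max_shift_px} exceeds overlap_px/2={t.overlap_px / 2}"
            )
    tiles_sorted = sorted(tiles, key=lambda t: t.grid_index)
    refined: dict[tuple[int, int], tuple[int, int]] = {}
    # tiles whose offset is trustworthy as an anchor for later tiles: the
    # anchor tile itself, plus tiles actually aligned against an informative
    # overlap.  A tile left at its nominal offset for lack of detections must
    # not propagate its unknown jitter down the scan order.
    anchored: set[tuple[int, int]] = set()
    by_index = {t.grid_index: t for t in tiles_sorted}
    total = detections.n_detections()

    for tile in tiles_sorted:
        gi = tile.grid_index
        nominal = np.asarray(tile.nominal_offset_px, dtype=float)
        dets = detections.per_tile.get(gi)
        if gi == (0, 0) or total == 0 or dets is None or len(dets) == 0:
            refined[gi] = tuple(int(v) for v in nominal)
            if gi == (0, 0):
                anchored.add(gi)
            continue
        pts = dets[["y", "x"]].to_numpy(dtype=float)
        h, w = tile.size
        matchers: list[_PairMatcher] = []
        for nb_gi in ((gi[0] - 1, gi[1]), (gi[0], gi[1] - 1)):
            if nb_gi in anchored and nb_gi in by_index:
                nb_dets = detections.per_tile.get(nb_gi)
                if nb_dets is None or len(nb_dets) == 0:
                    logger.warning("no detections in neighbour tile %s; pair skipped", nb_gi)
                    continue
                nb_off = np.asarray(refined[nb_gi], dtype=float)
                box = (
                    max(nominal[0], nb_off[0]),
                    max(nominal[1], nb_off[1]),
                    min(nominal[0] + h, nb_off[0] + h),
                    min(nominal[1] + w, nb_off[1] + w),
                )
                if box[2] <= box[0] or box[3] <= box[1]:
                    continue
                matcher = _PairMatcher(
                    pts + nominal,
                    nb_dets[["y", "x"]].to_numpy(dtype=float) + nb_off,
                    box,
                    float(max_shift_px),
                )
                if matcher.empty:
                    logger.warning("overlap of %s and %s has no detections", gi, nb_gi)
                    continue
                matchers.append(matcher)
        if not matchers:
            refined[gi] = tuple(int(v) for v in nominal)
            continue
        anchored.add(gi)

        strides = [2 ** (levels - 1 - k) for k in range(levels)]
        best = np.zeros(2)
        radius = max_shift_px
        for stride in strides:
            cands = np.arange(-radius, radius + 1, stride)
            best_cost = np.inf
            best_d = best.copy()
            for dy in cands:
                for dx in cands:
                    d = best + np.array([dy, dx])
                    if np.any(np.abs(d) > max_shift_px):
                        continue
                    cost = sum(mt.cost(d) for mt in matchers)
                    if cost < best_cost - 1e-12:
                        best_cost = cost
                        best_d = d
            best = best_d
            radius = stride  # refine around the level's optimum
        refined[gi] = (int(nominal[0] + best[0]), int(nominal[1] + best[1]))
    return refined


def alignment_cost(
    detections: DetectionSet,
    tiles: list[Tile],
    offsets: dict[tuple[int, int], tuple[int, int]],
) -> float:
    """Total pairwise nearest-neighbour cost of a full offset assignment."""
    cost = 0.0
    by_index = {t.grid_index: t for t in tiles}
    for gi, tile in by_index.items():
        dets = detections.per_tile.get(gi)
        if dets is None or len(dets) == 0:
            continue
        off = np.asarray(offsets[gi], dtype=float)
        pts = dets[["y", "x"]].to_numpy(dtype=float) + off
        h, w = tile.size
        for nb_gi in ((gi[0] - 1, gi[1]), (gi[0], gi[1] - 1)):
            nb_dets = detections.per_tile.get(nb_gi)
            if nb_gi not in by_index or nb_dets is None or len(nb_dets) == 0:
                continue
            nb_off = np.asarray(offsets[nb_gi], dtype=float)
            nb_pts = nb_dets[["y", "x"]].to_numpy(dtype=float) + nb_off
            box = (
                max(off[0], nb_off[0]),
                max(off[1], nb_off[1]),
                min(off[0] + h, nb_off[0] + h),
                min(off[1] + w, nb_off[1] + w),
            )
            if box[2] <= box[0] or box[3] <= box[1]:
                continue
            in_a = _in_box(pts, box, 0.0)
            in_b = _in_box(nb_pts, box, 0.0)
            if len(in_a) and len(in_b):
                cost += float(cKDTree(in_b).query(in_a)[0].sum())
                cost += float(cKDTree(in_a).query(in_b)[0].sum())
    return cost


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def fuse_detections(
    detections: DetectionSet,
    offsets: dict[tuple[int, int], tuple[int, int]],
    match_radius_px: float = 5.0,
) -> pd.DataFrame:
    """Map detections to slide coordinates and de-duplicate across tiles.

    Detections from *different* tiles closer than ``match_radius_px`` are
    grouped (transitively) and each group keeps one representative: the
    detection with the largest nucleus area, ties broken by lexicographically
    smaller (tile row, tile col) and then smaller label id.  Fusing an
    already-fused set is a no-op.

    Returns a DataFrame with columns y, x, area, label, tile_row, tile_col
    (slide coordinates), deterministically ordered.
    """
    if match_radius_px < 0:
        raise ValueError("match_radius_px must be non-negative")
    frames = []
    for gi in sorted(detections.per_tile):
        df = detections.per_tile[gi]
        if len(df) == 0:
            continue
        if gi not in offsets:
            raise ValueError(f"no offset for tile {gi}")
        oy, ox = offsets[gi]
        out = pd.DataFrame(
            {
                "y": df["y"].to_numpy(dtype=float) + oy,
                "x": df["x"].to_numpy(dtype=float) + ox,
                "area": df["area"].to_numpy(dtype=float),
                "label": df["label"].to_numpy(),
                "tile_row": gi[0],
                "tile_col": gi[1],
            }
        )
        frames.append(out)
    if not frames:
        return pd.DataFrame(columns=["y", "x", "area", "label", "tile_row", "tile_col"])
    all_dets = pd.concat(frames, ignore_index=True)

    uf = _UnionFind(len(all_dets))
    if match_radius_px > 0:
        tree = cKDTree(all_dets[["y", "x"]].to_numpy())
        tiles_arr = all_dets[["tile_row", "tile_col"]].to_numpy()
        for i, j in sorted(tree.query_pairs(match_radius_px)):
            if tuple(tiles_arr[i]) != tuple(tiles_arr[j]):
                uf.union(i, j)

    roots = np.array([uf.find(i) for i in range(len(all_dets))])
    # representative per group: largest area, tie -> smaller (tile_row, tile_col, label)
    order_key = list(
        zip(
            -all_dets["area"].to_numpy(),
            all_dets["tile_row"].to_numpy(),
            all_dets["tile_col"].to_numpy(),
            all_dets["label"].to_numpy(),
        )
    )
    keep: dict[int, int] = {}
    for i in range(len(all_dets)):
        r = roots[i]
        if r not in keep or order_key[i] < order_key[keep[r]]:
            keep[r] = i
    kept = sorted(keep.values())
    fused = all_dets.iloc[kept].reset_index(drop=True)
    return fused.sort_values(["tile_row", "tile_col", "label"], kind="stable").reset_index(
        drop=True
    )
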