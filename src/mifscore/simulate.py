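"""Synthetic multiplex-slide generator with known ground truth.

Emulates a six-channel immunofluorescence slide of liver tissue: a smooth
random tumour region, elliptical nuclei whose per-cell mean intensities are
drawn from class-conditional log-normal distributions (fluorescence is
positive and right-skewed), an additive per-channel autofluorescence
baseline, Gaussian pixel noise clipped at zero, and a grid of overlapping
tiles whose true positions are jittered relative to the nominal grid layout.

The generator exists so that every downstream stage — alignment, fusion,
feature extraction, scoring, evaluation — can be tested against a known
truth without any external data.  It does not model optics (PSF, spectral
cross-talk) and the tumour geometry is a smoothed-noise blob field, not a
histological simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import FeatureTable
from .registry import CHANNELS, MARKERS, FeatureRegistry
from .tiling import Tile

#: class labels
NON_TUMOUR, TUMOUR = 0, 1


@dataclass
class LogNormal:
    """Log-normal over a positive quantity, parameterised by log-space mean/SD."""

    mu: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(self.mu, self.sigma, size=n))


@dataclass
class ClassChannelModel:
    """Per-class intensity model for one channel.

    ``base`` is the log-normal of per-cell mean intensity of marker-negative
    cells.  If ``positive_fraction`` is set, that fraction of cells draws
    instead from ``base`` scaled by ``positive_boost`` — a bright,
    well-separated sub-population that the 2-SD positivity rule should
    recover.
    """

    base: LogNormal
    positive_fraction: float | None = None
    positive_boost: float = 30.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        values = self.base.sample(rng, n)
        if self.positive_fraction:
            hot = rng.random(n) < self.positive_fraction
            values[hot] *= self.positive_boost
        return values


def default_channel_models() -> dict[int, dict[str, ClassChannelModel]]:
    """Class-conditional intensity models for the 6 channels.

    DAPI is brighter and slightly more variable in tumour nuclei (aneuploidy);
    marker positive fractions default to the study's observed per-marker
    positive-cell percentages in primary tumour (class 1) vs non-tumour liver
    (class 0): CD3 3.85/8.08, CD4 2.83/6.14, CD8 0.90/3.21, FoxP3 5.23/3.05,
    PD-L1 4.00/3.81 (percent).
    """
    marker_fracs = {
        "CD3": (0.0385, 0.0808),
        "CD4": (0.0283, 0.0614),
        "CD8": (0.0090, 0.0321),
        "FoxP3": (0.0523, 0.0305),
        "PDL1": (0.0400, 0.0381),
    }
    models: dict[int, dict[str, ClassChannelModel]] = {NON_TUMOUR: {}, TUMOUR: {}}
    models[TUMOUR]["DAPI"] = ClassChannelModel(LogNormal(np.log(120.0), 0.35))
    models[NON_TUMOUR]["DAPI"] = ClassChannelModel(LogNormal(np.log(80.0), 0.25))
    for m in MARKERS:
        pt_frac, ntl_frac = marker_fracs[m]
        models[TUMOUR][m] = ClassChannelModel(LogNormal(np.log(10.0), 0.3), pt_frac)
        models[NON_TUMOUR][m] = ClassChannelModel(LogNormal(np.log(10.0), 0.3), ntl_frac)
    return models


@dataclass
class MorphologyModel:
    """Per-class nucleus morphology: log-normal area, uniform axis ratio."""

    area: LogNormal
    axis_ratio: tuple[float, float] = (1.0, 1.8)  # major/minor


def default_morphology() -> dict[int, MorphologyModel]:
    # tumour nuclei larger and more pleomorphic than hepatocyte/lymphocyte mix
    return {
        TUMOUR: MorphologyModel(LogNormal(np.log(110.0), 0.25), (1.0, 2.2)),
        NON_TUMOUR: MorphologyModel(LogNormal(np.log(70.0), 0.20), (1.0, 1.6)),
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic slide.  Defaults give a desk-scale slide
    with the study's imaging conventions (0.32 um/px)."""

    seed: int = 0
    slide_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.32
    tile_size_px: int = 160
    tile_overlap_px: int = 32
    jitter_max_px: int = 5
    n_cells_target: int = 400
    tumour_coverage: float = 0.5
    tumour_smoothness_px: float = 60.0
    channel_models: dict[int, dict[str, ClassChannelModel]] = field(
        default_factory=default_channel_models
    )
    morphology: dict[int, MorphologyModel] = field(default_factory=default_morphology)
    autofluorescence_level: tuple[float, ...] = (2.0, 3.0, 3.0, 3.0, 3.0, 3.0)
    pixel_noise_sd: float = 2.0
    min_cell_distance_px: float = 14.0
    # feature-table generation
    informative_features: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.tile_size_px <= self.tile_overlap_px:
            raise ValueError("tile size must exceed overlap")
        if self.tile_overlap_px <= 2 * self.jitter_max_px:
            raise ValueError("tile_overlap_px must exceed 2 * jitter_max_px")
        if len(self.autofluorescence_level) != len(CHANNELS):
            raise ValueError("autofluorescence_level must have one entry per channel")
        for cls in (NON_TUMOUR, TUMOUR):
            for ch in CHANNELS:
                if ch not in self.channel_models.get(cls, {}):
                    raise ValueError(f"missing channel model for class {cls}, channel {ch}")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything the generator knows: region mask, true cells, tile offsets."""

    mask: np.ndarray  # (h, w) uint8, 1 = tumour
    cells: pd.DataFrame  # y, x, cls, area, major, minor, orientation, I_<ch>...
    tile_true_offsets: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)

    def validate(self, slide_shape: tuple[int, int]) -> None:
        if self.mask.shape != tuple(slide_shape):
            raise ValueError("mask shape differs from slide shape")
        ys = self.cells["y"].to_numpy()
        xs = self.cells["x"].to_numpy()
        if len(ys) and (
            ys.min() < 0 or xs.min() < 0 or ys.max() >= slide_shape[0] or xs.max() >= slide_shape[1]
        ):
            raise ValueError("cell centroid outside the slide")
        at_centroid = self.mask[ys.astype(int), xs.astype(int)] if len(ys) else np.zeros(0)
        if len(ys) and not np.array_equal(at_centroid, self.cells["cls"].to_numpy()):
            raise ValueError("cell class inconsistent with mask at centroid")


# ---------------------------------------------------------------------------


def make_tumour_mask(
    shape: tuple[int, int],
    rng: np.random.Generator,
    coverage: float = 0.5,
    smoothness_px: float = 60.0,
) -> np.ndarray:
    """Smoothed random field thresholded at the requested coverage quantile."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=smoothness_px)
    threshold = np.quantile(smooth, 1.0 - coverage)
    return (smooth >= threshold).astype(np.uint8)


def _sample_centroids(
    shape: tuple[int, int], n_target: int, min_dist: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing with a grid index; returns <= n_target (y, x) points."""
    h, w = shape
    margin = 4
    cell = max(min_dist, 1.0)
    grid: dict[tuple[int, int], list[np.ndarray]] = {}
    accepted: list[np.ndarray] = []
    attempts = n_target * 12
    pts = np.column_stack(
        [rng.uniform(margin, h - margin, attempts), rng.uniform(margin, w - margin, attempts)]
    )
    for p in pts:
        if len(accepted) >= n_target:
            break
        gi = (int(p[0] // cell), int(p[1] // cell))
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for q in grid.get((gi[0] + dy, gi[1] + dx), ()):
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < min_dist**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(p)
            grid.setdefault(gi, []).append(p)
    return np.array(accepted) if accepted else np.zeros((0, 2))


def sample_cells(config: SimulationConfig, mask: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Draw true cells: centroid, class from the mask, morphology, intensities."""
    pts = _sample_centroids(mask.shape, config.n_cells_target, config.min_cell_distance_px, rng)
    n = len(pts)
    cls = mask[pts[:, 0].astype(int), pts[:, 1].astype(int)] if n else np.zeros(0, dtype=int)
    cols: dict[str, np.ndarray] = {
        "y": pts[:, 0] if n else np.zeros(0),
        "x": pts[:, 1] if n else np.zeros(0),
        "cls": cls.astype(int),
    }
    area = np.zeros(n)
    ratio = np.zeros(n)
    for c in (NON_TUMOUR, TUMOUR):
        sel = cls == c
        k = int(sel.sum())
        if k == 0:
            continue
        morph = config.morphology[c]
        area[sel] = morph.area.sample(rng, k)
        ratio[sel] = rng.uniform(*morph.axis_ratio, size=k)
    # ellipse area = pi * a * b with a = ratio * b (semi-axes)
    b = np.sqrt(area / (np.pi * np.maximum(ratio, 1e-9))) if n else np.zeros(0)
    a = ratio * b
    cols["area"] = area
    cols["semi_major"] = a
    cols["semi_minor"] = b
    cols["orientation"] = rng.uniform(0, np.pi, size=n)
    for ch in CHANNELS:
        vals = np.zeros(n)
        for c in (NON_TUMOUR, TUMOUR):
            sel = cls == c
            k = int(sel.sum())
            if k:
                vals[sel] = config.channel_models[c][ch].sample(rng, k)
        cols[f"I_{ch}"] = vals
    df = pd.DataFrame(cols)
    df.index.name = "cell_id"
    return df


def _paint_cells(slide: np.ndarray, cells: pd.DataFrame) -> None:
    """Rasterise each cell as a filled rotated ellipse in all channels."""
    h, w = slide.shape[1:]
    for row in cells.itertuples():
        a, b = row.semi_major, row.semi_minor
        ct, st = np.cos(row.orientation), np.sin(row.orientation)
        r = int(np.ceil(max(a, b))) + 1
        y0, y1 = max(0, int(row.y) - r), min(h, int(row.y) + r + 1)
        x0, x1 = max(0, int(row.x) - r), min(w, int(row.x) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - row.y, xx - row.x
        u = dy * ct + dx * st
        v = -dy * st + dx * ct
        inside = (u / max(a, 1e-9)) ** 2 + (v / max(b, 1e-9)) ** 2 <= 1.0
        for ci, ch in enumerate(CHANNELS):
            patch = slide[ci, y0:y1, x0:x1]
            patch[inside] = getattr(row, f"I_{ch}")


def _grid_layout(config: SimulationConfig) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    """Tile grid covering the slide; slide size is rounded up to fit exactly."""
    step = config.tile_size_px - config.tile_overlap_px
    h, w = config.slide_size_px
    n_rows = max(1, int(np.ceil((h - config.tile_overlap_px) / step)))
    n_cols = max(1, int(np.ceil((w - config.tile_overlap_px) / step)))
    offsets = [(r * step, c * step) for r in range(n_rows) for c in range(n_cols)]
    return (n_rows, n_cols), offsets


def slide_shape_for(config: SimulationConfig) -> tuple[int, int]:
    step = config.tile_size_px - config.tile_overlap_px
    (n_rows, n_cols), _ = _grid_layout(config)
    return (n_rows * step + config.tile_overlap_px, n_cols * step + config.tile_overlap_px)


def generate_slide(config: SimulationConfig) -> tuple[list[Tile], GroundTruth]:
    """Generate one synthetic slide as overlapping jittered tiles plus truth.

    The full slide raster is built first (autofluorescence baseline, painted
    nuclei, clipped Gaussian pixel noise); tiles are then cropped at their
    *true* offsets (nominal grid position plus per-tile integer jitter,
    anchor tile (0, 0) unjittered) while reporting only nominal offsets, so
    alignment must recover the jitter.  Same config and seed give bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = slide_shape_for(config)
    mask = make_tumour_mask(shape, rng, config.tumour_coverage, config.tumour_smoothness_px)
    cells = sample_cells(config, mask, rng)

    slide = np.zeros((len(CHANNELS),) + shape, dtype=np.float32)
    for ci, level in enumerate(config.autofluorescence_level):
        slide[ci] = level
    _paint_cells(slide, cells)
    if config.pixel_noise_sd > 0:
        slide += rng.normal(0.0, config.pixel_noise_sd, size=slide.shape).astype(np.float32)
    np.clip(slide, 0.0, None, out=slide)

    (n_rows, n_cols), nominal = _grid_layout(config)
    ts = config.tile_size_px
    tiles: list[Tile] = []
    true_offsets: dict[tuple[int, int], tuple[int, int]] = {}
    for (oy, ox), (r, c) in zip(nominal, [(r, c) for r in range(n_rows) for c in range(n_cols)]):
        if (r, c) == (0, 0) or config.jitter_max_px == 0:
            jy = jx = 0
        else:
            jy = int(rng.integers(-config.jitter_max_px, config.jitter_max_px + 1))
            jx = int(rng.integers(-config.jitter_max_px, config.jitter_max_px + 1))
        ty = int(np.clip(oy + jy, 0, shape[0] - ts))
        tx = int(np.clip(ox + jx, 0, shape[1] - ts))
        true_offsets[(r, c)] = (ty, tx)
        tiles.append(
            Tile(
                pixels=slide[:, ty : ty + ts, tx : tx + ts].copy(),
                grid_index=(r, c),
                nominal_offset_px=(oy, ox),
                overlap_px=config.tile_overlap_px,
            )
        )
    truth = GroundTruth(mask=mask, cells=cells, tile_true_offsets=true_offsets)
    truth.validate(shape)
    return tiles, truth


def generate_feature_table(
    config: SimulationConfig, registry: FeatureRegistry | None = None
) -> tuple[FeatureTable, np.ndarray]:
    """Generate a per-cell feature table directly, bypassing imaging.

    Every feature is standard normal noise independent of the class label,
    except the features named in ``config.informative_features``, which get a
    standardised class shift of the given effect size d (label-1 cells are
    shifted by +d).  Labels are Bernoulli(``tumour_coverage``).  Used to
    unit-test the scoring models on tables with known statistical structure.
    """
    registry = registry or FeatureRegistry.default()
    unknown = [f for f in config.informative_features if f not in registry.names]
    if unknown:
        raise KeyError(f"unknown informative feature(s): {unknown}")
    rng = np.random.default_rng(config.seed)
    n = config.n_cells_target
    labels = (rng.random(n) < config.tumour_coverage).astype(np.int64)
    X = rng.standard_normal((n, len(registry)))
    for name, d in config.informative_features.items():
        X[:, registry.index(name)] += d * labels
    df = pd.DataFrame(X, columns=registry.names)
    df.index.name = "cell_id"
    table = FeatureTable(df, labels, registry, slide_id=f"synthetic-{config.seed}")
    table.validate()
    return table, labels


def detections_from_truth(
    truth: GroundTruth, tiles: list[Tile]
) -> "DetectionSet":
    """Project true cells into each tile (at its true offset) as detections.

    Convenience for alignment/fusion tests: the detection a segmenter would
    ideally produce, in tile-local coordinates, for every tile whose true
    footprint contains the cell centroid.
    """
    from .tiling import DetectionSet

    dets = DetectionSet()
    ys = truth.cells["y"].to_numpy()
    xs = truth.cells["x"].to_numpy()
    areas = truth.cells["area"].to_numpy()
    for tile in tiles:
        ty, tx = truth.tile_true_offsets[tile.grid_index]
        th, tw = tile.size
        sel = (ys >= ty) & (ys < ty + th) & (xs >= tx) & (xs < tx + tw)
        idx = np.nonzero(sel)[0]
        dets.add(
            tile.grid_index,
            pd.DataFrame(
                {
                    "y": ys[idx] - ty,
                    "x": xs[idx] - tx,
                    "label": idx,
                    "area": areas[idx],
                }
            ),
        )
    return dets
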