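"""High-level pipeline helpers shared by the CLI, the examples and the tests.

Each function is a thin composition of the library modules: simulate a
cohort of synthetic slides, extract feature tables through the imaging path,
run one cross-validated model, and summarise metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import stage_seed
from .evaluate import CVSplit, MetricsRecord, compute_metrics, make_cv_splits
from .features import FeatureTable, compute_feature_table, segment_nuclei
from .io import fuse_tiles_to_slide
from .models import (
    MLPConfig,
    Normalizer,
    UNetConfig,
    classify_scores,
    combine_score,
    icf_select,
    manova_select,
    predict_mlp,
    predict_unet,
    rasterize_cells,
    train_mlp,
    train_unet,
)
from .models.raster import UNET_CHANNELS
from .simulate import SimulationConfig, generate_slide, slide_shape_for
from .tiling import DetectionSet, fuse_detections, refine_alignment


def simulate_cohort(
    base_config: SimulationConfig, n_slides: int, run_seed: int = 0
) -> list[tuple[list, "object"]]:
    """Generate ``n_slides`` independent synthetic slides from one run seed."""
    return [
        generate_slide(base_config.replace(seed=stage_seed(run_seed, "simulate", i)))
        for i in range(n_slides)
    ]


def extract_slide_features(
    tiles: list,
    truth,
    radius_px: float = 300.0,
    min_area: int = 15,
    refine: bool = True,
    slide_id: str = "slide",
) -> FeatureTable:
    """Imaging path for one slide: per-tile segmentation, alignment refinement,
    detection fusion, slide fusion, then feature extraction on fused segments.

    For simplicity the fused slide raster is segmented once at the refined
    offsets, which gives one consistent nucleus set (the per-tile detections
    only drive alignment)."""
    dets = DetectionSet()
    for tile in tiles:
        segs = segment_nuclei(tile.pixels[0], min_area=min_area)
        dets.add(
            tile.grid_index,
            pd.DataFrame(
                {
                    "y": [s.centroid[0] for s in segs],
                    "x": [s.centroid[1] for s in segs],
                    "label": [s.label for s in segs],
                    "area": [s.area for s in segs],
                }
            ),
        )
    if refine:
        offsets = refine_alignment(dets, tiles, max_shift_px=max(1, tiles[0].overlap_px // 4))
    else:
        offsets = {t.grid_index: t.nominal_offset_px for t in tiles}
    slide = fuse_tiles_to_slide(tiles, offsets, truth.mask.shape)
    segments = segment_nuclei(slide[0], min_area=min_area)
    return compute_feature_table(
        slide, truth.mask, segments, radius_px=radius_px, slide_id=slide_id
    )


def run_linear_cv(
    tables: dict[str, FeatureTable],
    method: str = "icf",
    normalisation: str = "none",
    n_select: int = 5,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Leave-one-slide-out cross-validation of the ICF or MANOVA model."""
    select = {"icf": icf_select, "manova": manova_select}[method]
    splits = make_cv_splits(sorted(tables), "table")
    rows = []
    for split in splits:
        train_df = pd.concat([tables[s].df for s in split.train], ignore_index=True)
        train_labels = np.concatenate([tables[s].labels for s in split.train])
        norm = Normalizer(normalisation).fit(train_df)
        model = select(norm.transform(train_df), train_labels, n_select=n_select)
        test = tables[split.test]
        scores = combine_score(norm.transform(test.df), model)
        rec = compute_metrics(classify_scores(scores, threshold), test.labels)
        rows.append({"test_slide": split.test, "model": method, **rec.as_dict()})
    return pd.DataFrame(rows)


def run_mlp_cv(
    tables: dict[str, FeatureTable],
    normalisation: str = "none",
    config: MLPConfig | None = None,
    run_seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-slide-out cross-validation of the MLP model."""
    splits = make_cv_splits(sorted(tables), "table")
    rows = []
    for i, split in enumerate(splits):
        train_df = pd.concat([tables[s].df for s in split.train], ignore_index=True)
        train_labels = np.concatenate([tables[s].labels for s in split.train])
        norm = Normalizer(normalisation).fit(train_df)
        model = train_mlp(
            norm.transform(train_df).to_numpy(dtype=float),
            train_labels,
            config,
            seed=stage_seed(run_seed, "train", i),
        )
        test = tables[split.test]
        scores = predict_mlp(model, norm.transform(test.df).to_numpy(dtype=float))
        rec = compute_metrics(scores > model.label_midpoint, test.labels)
        rows.append({"test_slide": split.test, "model": "mlp", **rec.as_dict()})
    return pd.DataFrame(rows)


def table_to_raster(table: FeatureTable, shape: tuple[int, int]) -> np.ndarray:
    """The 10-channel U-net input raster of one slide's feature table."""
    return rasterize_cells(table.df, shape, UNET_CHANNELS)


def run_unet_split(
    rasters: dict[str, np.ndarray],
    masks: dict[str, np.ndarray],
    tables: dict[str, FeatureTable],
    split: CVSplit,
    config: UNetConfig,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[MetricsRecord, "object"]:
    """Train the U-net on one (train, validation, test) split and evaluate
    per-cell accuracy on the test slide (score sampled at each centroid)."""
    train = [(rasters[s], masks[s]) for s in split.train]
    val = [(rasters[split.validation], masks[split.validation])]
    model = train_unet(train, val, config, seed=seed)
    score = predict_unet(model, rasters[split.test], slide_id=str(split.test))
    table = tables[split.test]
    cy = table.df["centroid_y"].to_numpy(dtype=float).round().astype(int)
    cx = table.df["centroid_x"].to_numpy(dtype=float).round().astype(int)
    cell_scores = score.values[cy, cx]
    rec = compute_metrics(classify_scores(cell_scores, threshold), table.labels)
    return rec, score


# ---------------------------------------------------------------------------
# reference synthetic scenarios
# ---------------------------------------------------------------------------


def strong_separation_config(seed: int = 0, size: int = 128) -> SimulationConfig:
    """A small single-tile slide with strong tumour/non-tumour separation.

    Tumour nuclei are brighter in DAPI (median 140 vs 80), nearly twice as
    large (median area 130 vs 55 px^2) and strongly depleted in CD3 (median
    4 vs 60) — an idealised, clearly separable tissue used to exercise the
    learning models at desk scale.
    """
    from .simulate import (
        ClassChannelModel,
        LogNormal,
        MorphologyModel,
        default_channel_models,
    )

    channel_models = default_channel_models()
    channel_models[1]["DAPI"] = ClassChannelModel(LogNormal(np.log(140.0), 0.2))
    channel_models[0]["DAPI"] = ClassChannelModel(LogNormal(np.log(80.0), 0.2))
    channel_models[1]["CD3"] = ClassChannelModel(LogNormal(np.log(4.0), 0.2))
    channel_models[0]["CD3"] = ClassChannelModel(LogNormal(np.log(60.0), 0.2))
    morphology = {
        1: MorphologyModel(LogNormal(np.log(130.0), 0.15), (1.0, 1.6)),
        0: MorphologyModel(LogNormal(np.log(55.0), 0.15), (1.0, 1.6)),
    }
    return SimulationConfig(
        seed=seed,
        slide_size_px=(size, size),
        tile_size_px=size,
        tile_overlap_px=1,
        jitter_max_px=0,
        n_cells_target=110,
        min_cell_distance_px=9.0,
        tumour_smoothness_px=20.0,
        channel_models=channel_models,
        morphology=morphology,
    )


def build_unet_slide(
    config: SimulationConfig, radius_px: float = 32.0
) -> tuple[np.ndarray, np.ndarray, FeatureTable]:
    """One synthetic slide ready for the U-net: (10-channel raster, mask, table).

    Runs the full imaging path on a single-tile slide: segmentation of the
    DAPI channel, feature extraction (a neighbourhood radius scaled to the
    small slide), and rasterisation of the U-net input channels.
    """
    from .features import compute_feature_table, segment_nuclei

    tiles, truth = generate_slide(config)
    slide = fuse_tiles_to_slide(
        tiles, {t.grid_index: t.nominal_offset_px for t in tiles}, truth.mask.shape
    )
    segments = segment_nuclei(slide[0], min_area=10)
    table = compute_feature_table(
        slide, truth.mask, segments, radius_px=radius_px, slide_id=f"synthetic-{config.seed}"
    )
    raster = rasterize_cells(table.df, truth.mask.shape, UNET_CHANNELS)
    return raster, truth.mask.astype(np.float32), table


def cell_accuracy(score_map, table: FeatureTable, threshold: float = 0.5) -> float:
    """Per-cell accuracy of a score map: score sampled at each centroid."""
    cy = table.df["centroid_y"].to_numpy(dtype=float).round().astype(int)
    cx = table.df["centroid_x"].to_numpy(dtype=float).round().astype(int)
    values = score_map.values if hasattr(score_map, "values") else score_map
    calls = classify_scores(np.asarray(values)[cy, cx], threshold)
    return compute_metrics(calls, table.labels).accuracy
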