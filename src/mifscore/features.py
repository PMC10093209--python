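"""Per-cell feature extraction.

Turns segmented nuclei plus the six channel rasters into the 68-feature
table: intensity statistics (mean, mean-of-brightest-25%, pixel SD) per
channel, autofluorescence-corrected marker means, nuclear morphology,
marker positivity by the 2-SD rule, and 300-px-radius neighbourhood
statistics (cell density, positive-cell counts, environment SDs).

Conventions (fixed and documented):

* population SDs (``ddof=0``) throughout;
* positivity is strict: ``value > mean + 2 * SD``, statistics taken over all
  cells of the same slide;
* neighbour distances are Euclidean between centroids, radius-inclusive;
* the neighbour set for density and positive counts excludes the focal cell,
  the environment-SD set includes it;
* 0-based (y, x) pixel coordinates, origin top-left.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .registry import CHANNELS, ENV_SD_BASES, MARKERS, FeatureRegistry

logger = logging.getLogger(__name__)


@dataclass
class NucleusSegment:
    """One segmented nucleus: pixel support plus derived morphology."""

    label: int
    pixels: np.ndarray  # (n, 2) integer (y, x)
    centroid: tuple[float, float]
    area: int
    minor_axis: float
    major_axis: float
    eccentricity: float
    circularity: float
    perimeter: float


# ---------------------------------------------------------------------------
# segmentation backends
# ---------------------------------------------------------------------------

_BACKENDS: dict = {}


def register_backend(name: str, fn) -> None:
    """Register a segmentation backend: fn(dapi_raster, **kw) -> label image."""
    _BACKENDS[name] = fn


def _reference_backend(
    dapi: np.ndarray,
    min_area: int = 15,
    min_distance: int = 5,
    **_: object,
) -> np.ndarray:
    """Otsu threshold + distance-transform watershed + min-area filter.

    A dependency-free nucleus segmenter adequate for well-separated synthetic
    nuclei; heavier models (e.g. Cellpose) can be plugged in behind the same
    label-image contract via :func:`register_backend`.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size == 0 or np.ptp(dapi) == 0:
        return np.zeros(dapi.shape, dtype=np.int32)
    binary = dapi > threshold_otsu(dapi)
    if not binary.any():
        return np.zeros(dapi.shape, dtype=np.int32)
    distance = ndimage.distance_transform_edt(binary)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=binary, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    if markers.max() == 0:
        labels = sk_label(binary)
    else:
        labels = watershed(-distance, markers, mask=binary)
    # min-area filter
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    small = ids[counts < min_area]
    if len(small):
        labels[np.isin(labels, small)] = 0
    return labels


register_backend("reference", _reference_backend)


def segment_nuclei(
    dapi_raster: np.ndarray, backend: str = "reference", **backend_kwargs
) -> list[NucleusSegment]:
    """Segment nuclei in a single-channel DAPI raster.

    Returns disjoint labelled segments with morphology filled in.  A blank
    raster yields an empty list.
    """
    if dapi_raster.ndim != 2:
        raise ValueError("segment_nuclei expects a single-channel 2-D raster")
    if backend not in _BACKENDS:
        raise KeyError(f"unknown segmentation backend {backend!r}")
    labels = _BACKENDS[backend](dapi_raster, **backend_kwargs)
    segments = []
    for lab in np.unique(labels[labels > 0]):
        ys, xs = np.nonzero(labels == lab)
        segments.append(extract_morphology(np.column_stack([ys, xs]), label=int(lab)))
    return segments


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def extract_morphology(pixels: np.ndarray, label: int = 0) -> NucleusSegment:
    """Measure morphology of one nucleus from its pixel set.

    Area is the pixel count; axis lengths and eccentricity come from the
    second central moments (ellipse-equivalent convention, as in
    ``skimage.measure.regionprops``); circularity = 4*pi*area / perimeter**2.
    Axis lengths are floored at 1 px (a pixel has unit extent) and
    eccentricity recomputed from the floored axes, so degenerate single-row
    segments stay within [0, 1).  A single pixel is by convention
    (area 1, axes 1, eccentricity 0, circularity 1).
    """
    pixels = np.asarray(pixels, dtype=np.int64)
    if pixels.ndim != 2 or pixels.shape[1] != 2 or len(pixels) == 0:
        raise ValueError("pixel set must be a non-empty (n, 2) array")
    area = len(pixels)
    cy, cx = pixels.mean(axis=0)
    if area == 1:
        return NucleusSegment(label, pixels, (float(cy), float(cx)), 1, 1.0, 1.0, 0.0, 1.0, 0.0)

    ymin, xmin = pixels.min(axis=0)
    crop = np.zeros(tuple(pixels.max(axis=0) - (ymin, xmin) + 1), dtype=np.uint8)
    crop[pixels[:, 0] - ymin, pixels[:, 1] - xmin] = 1
    props = regionprops(crop.astype(np.int32))[0]
    major = max(float(props.axis_major_length), 1.0)
    minor = max(float(props.axis_minor_length), 1.0)
    minor = min(minor, major)
    ecc = float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)))
    perimeter = float(props.perimeter)
    circularity = 4 * np.pi * area / perimeter**2 if perimeter > 0 else 1.0
    return NucleusSegment(
        label, pixels, (float(cy), float(cx)), area, minor, major, ecc, circularity, perimeter
    )


# ---------------------------------------------------------------------------
# intensity statistics
# ---------------------------------------------------------------------------


def measure_intensities(
    segment: NucleusSegment, channel_rasters: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel (mean, mean25, pixel SD) over the nucleus pixel set.

    ``mean25`` is the mean of the brightest ``ceil(0.25 * area)`` pixels; the
    SD is the population SD.  Raises if any segment pixel is outside the
    raster, naming the segment.
    """
    rasters = np.asarray(channel_rasters, dtype=float)
    if rasters.ndim != 3:
        raise ValueError("channel_rasters must be (channels, h, w)")
    _, h, w = rasters.shape
    ys, xs = segment.pixels[:, 0], segment.pixels[:, 1]
    if ys.min() < 0 or xs.min() < 0 or ys.max() >= h or xs.max() >= w:
        raise ValueError(f"segment {segment.label} has pixels outside the raster bounds")
    values = rasters[:, ys, xs]  # (channels, n_pixels)
    mean = values.mean(axis=1)
    k = int(np.ceil(0.25 * values.shape[1]))
    top = np.sort(values, axis=1)[:, -k:]
    mean25 = top.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    return mean, mean25, sd


def correct_autofluorescence(
    marker_means: np.ndarray, baseline_percentile: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract a per-slide autofluorescence baseline from marker means.

    The baseline for each marker channel is the ``baseline_percentile``-th
    percentile of the per-cell mean intensities of that slide (default 5th);
    corrected values are clamped at zero, so corrected <= raw always.
    Returns (corrected (n_cells, n_markers), baselines (n_markers,)).
    """
    marker_means = np.asarray(marker_means, dtype=float)
    if marker_means.size == 0:
        return marker_means.copy(), np.zeros(marker_means.shape[-1])
    baselines = np.percentile(marker_means, baseline_percentile, axis=0)
    corrected = np.clip(marker_means - baselines, 0.0, None)
    return corrected, baselines


def call_positivity(values: np.ndarray) -> np.ndarray:
    """Flag cells whose marker statistic exceeds the slide mean by > 2 SD.

    Mean and (population) SD are computed over all supplied cells — i.e. all
    cells of one slide for one marker.  The inequality is strict, so a
    constant-valued slide yields zero positives.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        warnings.warn("fewer than 2 cells: positivity undefined, all flags False")
        return np.zeros(values.shape, dtype=bool)
    threshold = values.mean() + 2.0 * values.std(ddof=0)
    return values > threshold


# ---------------------------------------------------------------------------
# neighbourhood features
# ---------------------------------------------------------------------------


def neighbourhood_features(
    centroids: np.ndarray,
    positive_flags: np.ndarray,
    positive_flags_af: np.ndarray,
    env_values: np.ndarray,
    radius_px: float = 300.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact neighbourhood statistics within ``radius_px`` of each centroid.

    For each cell: ``density`` = number of *other* cells within the radius
    (inclusive boundary); positive counts per marker over that same neighbour
    set, for the raw and the autofluorescence-corrected positivity flags; and
    the population SD of each column of ``env_values`` over the neighbour set
    *including* the cell itself (a lone cell gets SD 0).

    Computed with a k-d tree; results are exact, no approximation.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    pos = np.asarray(positive_flags, dtype=float)
    pos_af = np.asarray(positive_flags_af, dtype=float)
    env = np.asarray(env_values, dtype=float)
    density = np.zeros(n)
    counts = np.zeros((n, pos.shape[1] if pos.ndim == 2 else 0))
    counts_af = np.zeros_like(counts)
    env_sd = np.zeros((n, env.shape[1] if env.ndim == 2 else 0))
    if n == 0:
        return density, counts, counts_af, env_sd
    tree = cKDTree(centroids)
    neighbour_lists = tree.query_ball_point(centroids, r=radius_px)
    for i, nb in enumerate(neighbour_lists):
        nb = np.asarray(nb)
        density[i] = len(nb) - 1
        others = nb[nb != i]
        if len(others):
            counts[i] = pos[others].sum(axis=0)
            counts_af[i] = pos_af[others].sum(axis=0)
        env_sd[i] = env[nb].std(axis=0, ddof=0)
    return density, counts, counts_af, env_sd


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Cells x features matrix with registry-ordered columns and labels."""

    df: pd.DataFrame  # index = cell ids, columns = registry names
    labels: np.ndarray  # binary per-cell pathologist-mask label
    registry: FeatureRegistry
    slide_id: str = "slide"
    centroids: np.ndarray | None = None  # optional (n, 2) slide (y, x)
    extras: dict = field(default_factory=dict)  # e.g. positivity flag frames

    @property
    def X(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        if list(self.df.columns) != self.registry.names:
            raise ValueError("feature columns do not match registry order")
        if len(self.labels) != len(self.df):
            raise ValueError("label count differs from row count")
        if self.df.isna().any().any():
            raise ValueError("feature table contains missing values")


def assemble_features(
    segments: list[NucleusSegment],
    intensity_stats: dict[str, np.ndarray],
    af_means: np.ndarray,
    neighbourhood: dict[str, np.ndarray],
    mask: np.ndarray,
    registry: FeatureRegistry | None = None,
    slide_id: str = "slide",
    pos_flags: np.ndarray | None = None,
    pos_flags_af: np.ndarray | None = None,
) -> FeatureTable:
    """Assemble the per-cell feature table in registry column order.

    ``intensity_stats`` maps "mean"/"mean25"/"sd" to (n_cells, 6) arrays;
    ``neighbourhood`` maps "density"/"pos_count"/"pos_count_af"/"env_sd" to
    the arrays produced by :func:`neighbourhood_features`.  The label of each
    cell is the mask value at its centroid (error if outside the mask).
    """
    registry = registry or FeatureRegistry.default()
    n = len(segments)
    columns: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(CHANNELS):
        for stat in ("mean", "mean25", "sd"):
            columns[f"{stat}_{ch}"] = np.asarray(intensity_stats[stat])[:, ci] if n else np.zeros(0)
    for mi, m in enumerate(MARKERS):
        columns[f"af_mean_{m}"] = np.asarray(af_means)[:, mi] if n else np.zeros(0)
    columns["area"] = np.array([s.area for s in segments], dtype=float)
    columns["centroid_y"] = np.array([s.centroid[0] for s in segments])
    columns["centroid_x"] = np.array([s.centroid[1] for s in segments])
    columns["minor_axis"] = np.array([s.minor_axis for s in segments])
    columns["major_axis"] = np.array([s.major_axis for s in segments])
    columns["eccentricity"] = np.array([s.eccentricity for s in segments])
    columns["circularity"] = np.array([s.circularity for s in segments])
    columns["density"] = np.asarray(neighbourhood["density"], dtype=float)
    for mi, m in enumerate(MARKERS):
        columns[f"pos_count_{m}"] = np.asarray(neighbourhood["pos_count"])[:, mi] if n else np.zeros(0)
        columns[f"pos_count_af_{m}"] = (
            np.asarray(neighbourhood["pos_count_af"])[:, mi] if n else np.zeros(0)
        )
    env_sd = np.asarray(neighbourhood["env_sd"])
    for bi, base in enumerate(ENV_SD_BASES):
        columns[f"env_sd_{base}"] = env_sd[:, bi] if n else np.zeros(0)

    labels = np.zeros(n, dtype=np.int64)
    mh, mw = mask.shape
    for i, s in enumerate(segments):
        iy, ix = int(round(s.centroid[0])), int(round(s.centroid[1]))
        if not (0 <= iy < mh and 0 <= ix < mw):
            raise ValueError(f"centroid of segment {s.label} lies outside the mask raster")
        labels[i] = int(mask[iy, ix] > 0)

    df = pd.DataFrame({name: columns[name] for name in registry.names})
    df.index = pd.Index([s.label for s in segments], name="cell_id")
    centroids = (
        np.array([s.centroid for s in segments]) if n else np.zeros((0, 2))
    )
    extras = {}
    if pos_flags is not None:
        extras["pos_flags"] = pd.DataFrame(pos_flags, columns=list(MARKERS), index=df.index)
    if pos_flags_af is not None:
        extras["pos_flags_af"] = pd.DataFrame(
            pos_flags_af, columns=list(MARKERS), index=df.index
        )
    table = FeatureTable(df, labels, registry, slide_id, centroids, extras)
    table.validate()
    return table


def compute_feature_table(
    channel_rasters: np.ndarray,
    mask: np.ndarray,
    segments: list[NucleusSegment],
    registry: FeatureRegistry | None = None,
    radius_px: float = 300.0,
    slide_id: str = "slide",
    baseline_percentile: float = 5.0,
) -> FeatureTable:
    """Full extraction chain for one slide: intensities, AF correction,
    positivity, neighbourhood statistics, and assembly in registry order."""
    registry = registry or FeatureRegistry.default()
    n = len(segments)
    mean = np.zeros((n, len(CHANNELS)))
    mean25 = np.zeros_like(mean)
    sd = np.zeros_like(mean)
    for i, seg in enumerate(segments):
        mean[i], mean25[i], sd[i] = measure_intensities(seg, channel_rasters)
    marker_means = mean[:, 1:]  # markers exclude DAPI
    af_means, _ = correct_autofluorescence(marker_means, baseline_percentile)
    if n >= 2:
        pos_flags = np.column_stack(
            [call_positivity(marker_means[:, j]) for j in range(len(MARKERS))]
        )
        pos_flags_af = np.column_stack(
            [call_positivity(af_means[:, j]) for j in range(len(MARKERS))]
        )
    else:
        pos_flags = np.zeros((n, len(MARKERS)), dtype=bool)
        pos_flags_af = np.zeros((n, len(MARKERS)), dtype=bool)

    centroids = np.array([s.centroid for s in segments]) if n else np.zeros((0, 2))
    area = np.array([s.area for s in segments], dtype=float)
    minor = np.array([s.minor_axis for s in segments])
    major = np.array([s.major_axis for s in segments])

    # base values whose environment SD is computed; density is filled after the
    # density pass (two-stage: density first, then env SD including density)
    density, counts, counts_af, _ = neighbourhood_features(
        centroids, pos_flags, pos_flags_af, np.zeros((n, 0)), radius_px
    ) if n else (np.zeros(0), np.zeros((0, 5)), np.zeros((0, 5)), np.zeros((0, 0)))

    env_cols = []
    intensity_by_name = {}
    for ci, ch in enumerate(CHANNELS):
        intensity_by_name[f"mean_{ch}"] = mean[:, ci]
        intensity_by_name[f"mean25_{ch}"] = mean25[:, ci]
        intensity_by_name[f"sd_{ch}"] = sd[:, ci]
    for mi, m in enumerate(MARKERS):
        intensity_by_name[f"af_mean_{m}"] = af_means[:, mi]
    intensity_by_name.update(
        {"area": area, "minor_axis": minor, "major_axis": major, "density": density}
    )
    for base in ENV_SD_BASES:
        env_cols.append(intensity_by_name[base])
    env_values = np.column_stack(env_cols) if n else np.zeros((0, len(ENV_SD_BASES)))

    if n:
        _, _, _, env_sd = neighbourhood_features(
            centroids, pos_flags, pos_flags_af, env_values, radius_px
        )
    else:
        env_sd = np.zeros((0, len(ENV_SD_BASES)))

    return assemble_features(
        segments,
        {"mean": mean, "mean25": mean25, "sd": sd},
        af_means,
        {"density": density, "pos_count": counts, "pos_count_af": counts_af, "env_sd": env_sd},
        mask,
        registry,
        slide_id,
        pos_flags,
        pos_flags_af,
    )
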