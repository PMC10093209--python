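"""Cross-validation, confusion metrics, virtual biopsies and robustness sweeps.

Table models (ICF, MANOVA, MLP) use leave-one-out cross-validation over
slides; the image model (U-net) additionally needs a validation slide, so it
uses every ordered (validation, test) pair — n*(n-1) splits for n slides.
Accuracy, sensitivity, specificity and precision are the confusion-matrix
ratios; per-cell truth is the pathologist-mask value at the cell centroid.

Virtual biopsies are randomly placed square regions of interest measured in
fields of view (1 field = 0.15 mm^2); marker and marker-combination
positive-cell percentages are computed per ROI and compared between primary
tumour (PT) and non-tumour liver (NTL) ROIs with the Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .registry import MARKERS

FIELD_AREA_MM2 = 0.15  # one field of view


@dataclass(frozen=True)
class CVSplit:
    train: tuple
    test: object
    validation: object | None = None


def make_cv_splits(slide_ids: list, model_kind: str) -> list[CVSplit]:
    """Leave-one-out splits (table models) or ordered (val, test) pairs (image).

    ``model_kind`` is "table" or "image".  For n slides the table models get
    n splits; the image model gets n*(n-1).  Ordering is deterministic
    (input order, test-major)."""
    ids = list(slide_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate slide ids")
    if model_kind == "table":
        if len(ids) < 2:
            raise ValueError("table models need at least 2 slides")
        return [CVSplit(tuple(s for s in ids if s != t), t) for t in ids]
    if model_kind == "image":
        if len(ids) < 3:
            raise ValueError("the image model needs at least 3 slides")
        splits = []
        for t in ids:
            for v in ids:
                if v == t:
                    continue
                splits.append(CVSplit(tuple(s for s in ids if s not in (t, v)), t, v))
        return splits
    raise ValueError(f"unknown model kind {model_kind!r}")


@dataclass
class MetricsRecord:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_calls(cls, calls: np.ndarray, truth: np.ndarray) -> "MetricsRecord":
        calls = np.asarray(calls).astype(bool)
        truth = np.asarray(truth).astype(bool)
        if calls.shape != truth.shape:
            raise ValueError("calls and truth have different lengths")
        return cls(
            tp=int(np.sum(calls & truth)),
            fp=int(np.sum(calls & ~truth)),
            tn=int(np.sum(~calls & ~truth)),
            fn=int(np.sum(~calls & truth)),
        )

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def compute_metrics(calls: np.ndarray, truth: np.ndarray) -> MetricsRecord:
    return MetricsRecord.from_calls(calls, truth)


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value: exact for small tie-free samples
    (n <= 20 per group), otherwise the normal approximation with tie
    correction."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


# ---------------------------------------------------------------------------
# virtual biopsies
# ---------------------------------------------------------------------------


@dataclass
class ROISpec:
    size_fields: int = 16
    n_per_class: int = 10
    seed: int = 0
    pixel_size_um: float = 0.32
    purity: float = 0.95
    max_attempts: int = 20000

    def side_px(self) -> int:
        side_um = np.sqrt(self.size_fields * FIELD_AREA_MM2) * 1000.0
        return max(1, int(round(side_um / self.pixel_size_um)))


@dataclass
class ROI:
    y: int
    x: int
    side: int
    cls: int
    cell_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


def sample_virtual_biopsies(
    mask: np.ndarray,
    cells: pd.DataFrame,
    spec: ROISpec,
    side_px: int | None = None,
    centroid_cols: tuple[str, str] = ("y", "x"),
) -> list[ROI]:
    """Sample square ROIs that are >= ``purity`` single-class, per class.

    Positions are drawn uniformly with a fixed seed; cells are assigned to an
    ROI by centroid inclusion.  If a class has no admissible position within
    the attempt budget, fewer ROIs are returned with a warning."""
    rng = np.random.default_rng(spec.seed)
    side = side_px if side_px is not None else spec.side_px()
    h, w = mask.shape
    if side > h or side > w:
        raise ValueError(f"ROI side {side} px exceeds the slide {mask.shape}")
    integral = np.pad(np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1), ((1, 0), (1, 0)))

    def tumour_fraction(y: int, x: int) -> float:
        s = (
            integral[y + side, x + side]
            - integral[y, x + side]
            - integral[y + side, x]
            + integral[y, x]
        )
        return s / (side * side)

    ys = cells[centroid_cols[0]].to_numpy(dtype=float)
    xs = cells[centroid_cols[1]].to_numpy(dtype=float)
    rois: list[ROI] = []
    for cls in (1, 0):
        found = 0
        attempts = 0
        while found < spec.n_per_class and attempts < spec.max_attempts:
            attempts += 1
            y = int(rng.integers(0, h - side + 1))
            x = int(rng.integers(0, w - side + 1))
            frac = tumour_fraction(y, x)
            if (cls == 1 and frac >= spec.purity) or (cls == 0 and frac <= 1 - spec.purity):
                inside = (ys >= y) & (ys < y + side) & (xs >= x) & (xs < x + side)
                rois.append(ROI(y, x, side, cls, np.nonzero(inside)[0]))
                found += 1
        if found < spec.n_per_class:
            warnings.warn(
                f"only {found}/{spec.n_per_class} admissible ROIs found for class {cls}"
            )
    return rois


def tabulate_marker_combinations(
    rois: list[ROI], pos_flags: pd.DataFrame
) -> pd.DataFrame:
    """Mean (SD) percent positive per marker and per exact marker combination.

    ``pos_flags`` holds one boolean column per marker for every cell of the
    slide (positional row order matching the indices stored in the ROIs).
    Percentages are computed per ROI and then averaged within each class;
    PT vs NTL rows are compared with the Mann-Whitney U test over the per-ROI
    percentages.  Rows: 5 any-marker rows, then all 32 exact combinations
    (including all-negative); the exact-combination percentages of one ROI
    sum to 100."""
    flags = pos_flags[list(MARKERS)].to_numpy(dtype=bool)
    combos = list(itertools.product([False, True], repeat=len(MARKERS)))
    per_roi: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for roi in rois:
        if len(roi.cell_index) == 0:
            warnings.warn(f"ROI at ({roi.y}, {roi.x}) contains no cells; excluded")
            continue
        f = flags[roi.cell_index]
        n = len(f)
        any_pct = 100.0 * f.mean(axis=0)
        combo_pct = np.array(
            [100.0 * np.mean(np.all(f == np.array(combo), axis=1)) for combo in combos]
        )
        per_roi[roi.cls].append(np.concatenate([any_pct, combo_pct]))

    rows = []
    n_any = len(MARKERS)
    for i in range(n_any + len(combos)):
        if i < n_any:
            pattern = {m: ("pos." if j == i else "n. d.") for j, m in enumerate(MARKERS)}
            kind = "any"
        else:
            combo = combos[i - n_any]
            pattern = {m: ("pos." if combo[j] else "neg.") for j, m in enumerate(MARKERS)}
            kind = "combination"
        pt = np.array([v[i] for v in per_roi[1]])
        ntl = np.array([v[i] for v in per_roi[0]])
        rows.append(
            {
                "kind": kind,
                **pattern,
                "pt_mean": pt.mean() if len(pt) else float("nan"),
                "pt_sd": pt.std(ddof=0) if len(pt) else float("nan"),
                "ntl_mean": ntl.mean() if len(ntl) else float("nan"),
                "ntl_sd": ntl.std(ddof=0) if len(ntl) else float("nan"),
                "p_value": mann_whitney_u(pt, ntl),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# robustness sweeps
# ---------------------------------------------------------------------------


def threshold_sweep(
    scores: np.ndarray, truth: np.ndarray, thresholds: np.ndarray
) -> pd.DataFrame:
    """Confusion metrics at each cancer-score threshold (strict > calls).

    As the threshold rises, sensitivity is non-increasing and specificity
    non-decreasing — a structural property of thresholding."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    scores = np.asarray(scores, dtype=float)
    records = []
    for t in thresholds:
        rec = compute_metrics(scores > t, truth)
        records.append({"threshold": t, **rec.as_dict()})
    return pd.DataFrame(records)


WHOLE_SLIDE = "whole"


def roi_size_sweep(
    cell_scores: np.ndarray,
    cell_labels: np.ndarray,
    cells: pd.DataFrame,
    mask: np.ndarray,
    sizes_fields: list,
    spec: ROISpec,
    threshold: float = 0.5,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Per-cell accuracy inside randomly drawn ROIs of increasing size.

    Each entry of ``sizes_fields`` is a number of fields of view or the
    ``"whole"`` sentinel (accuracy over all cells, computed once).  For each
    size, ``n_repeats`` seeded draws give an accuracy distribution; the
    interquartile range is reported as the dispersion.  Sizes larger than
    the slide are skipped with a warning."""
    calls = np.asarray(cell_scores) > threshold
    labels = np.asarray(cell_labels).astype(bool)
    rows = []
    for size in sizes_fields:
        if size == WHOLE_SLIDE:
            acc = compute_metrics(calls, labels).accuracy
            rows.append(
                {"size_fields": size, "mean_accuracy": acc, "iqr": 0.0, "n_rois": len(labels)}
            )
            continue
        spec_s = ROISpec(
            size_fields=int(size),
            n_per_class=spec.n_per_class,
            seed=spec.seed,
            pixel_size_um=spec.pixel_size_um,
            purity=spec.purity,
        )
        if spec_s.side_px() > min(mask.shape):
            warnings.warn(f"ROI size {size} fields exceeds the slide; skipped")
            continue
        accs = []
        for rep in range(n_repeats):
            spec_r = ROISpec(
                size_fields=int(size),
                n_per_class=spec.n_per_class,
                seed=spec.seed + rep,
                pixel_size_um=spec.pixel_size_um,
                purity=spec.purity,
            )
            rois = sample_virtual_biopsies(mask, cells, spec_r)
            idx = np.concatenate([r.cell_index for r in rois]) if rois else np.zeros(0, int)
            if len(idx) == 0:
                continue
            accs.append(compute_metrics(calls[idx], labels[idx]).accuracy)
        accs = np.array(accs)
        rows.append(
            {
                "size_fields": size,
                "mean_accuracy": accs.mean() if len(accs) else float("nan"),
                "iqr": (
                    float(np.percentile(accs, 75) - np.percentile(accs, 25)) if len(accs) else float("nan")
                ),
                "n_rois": len(accs) * 2 * spec.n_per_class,
            }
        )
    return pd.DataFrame(rows)


def ablate_features(
    train_fn,
    feature_names: list[str],
    all_names: list[str],
) -> pd.DataFrame:
    """Leave-one-feature-out ablation.

    ``train_fn(kept_names)`` retrains the model without the omitted input
    and returns its test accuracy; the result has one row per omitted
    feature, ranked by the accuracy obtained without it (lowest first — the
    most important input)."""
    unknown = [f for f in feature_names if f not in all_names]
    if unknown:
        raise KeyError(f"unknown feature(s) to ablate: {unknown}")
    rows = []
    for name in feature_names:
        kept = [f for f in all_names if f != name]
        rows.append({"omitted": name, "accuracy": float(train_fn(kept))})
    return (
        pd.DataFrame(rows).sort_values("accuracy", kind="stable").reset_index(drop=True)
    )
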