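"""Cross-validation splits, confusion metrics, virtual biopsies, sweeps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mifscore as m
from mifscore.evaluate import (
    WHOLE_SLIDE,
    ROISpec,
    ablate_features,
    mann_whitney_u,
    roi_size_sweep,
)
from mifscore.registry import MARKERS


class TestSplits:
    def test_study_scale_split_counts(self):
        ids = [f"s{i}" for i in range(12)]
        assert len(m.make_cv_splits(ids, "image")) == 132
        assert len(m.make_cv_splits(ids, "table")) == 12

    def test_three_slide_image_splits_enumerated(self):
        splits = m.make_cv_splits(["a", "b", "c"], "image")
        got = {(s.validation, s.test) for s in splits}
        expected = {(v, t) for t, v in itertools.product("abc", repeat=2) if v != t}
        assert got == expected and len(splits) == 6

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_split_count_formulas(self, n):
        ids = list(range(n))
        assert len(m.make_cv_splits(ids, "table")) == n
        if n >= 3:
            assert len(m.make_cv_splits(ids, "image")) == n * (n - 1)

    def test_splits_are_disjoint_and_cover(self):
        for split in m.make_cv_splits(list("abcde"), "image"):
            parts = set(split.train) | {split.test, split.validation}
            assert parts == set("abcde")
            assert split.test not in split.train and split.validation not in split.train

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            m.make_cv_splits(["a", "a", "b"], "table")


class TestMetrics:
    def test_perfect_prediction(self):
        truth = np.array([0, 1, 1, 0, 1])
        rec = m.compute_metrics(truth, truth)
        assert (rec.accuracy, rec.sensitivity, rec.specificity, rec.precision) == (1, 1, 1, 1)

    def test_all_positive_on_balanced_set(self):
        truth = np.array([0, 0, 1, 1])
        rec = m.compute_metrics(np.ones(4), truth)
        assert rec.accuracy == 0.5 and rec.sensitivity == 1.0 and rec.specificity == 0.0

    def test_hand_computed_confusion_table(self):
        # TP=3 FP=1 TN=4 FN=2
        truth = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        calls = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        rec = m.compute_metrics(calls, truth)
        assert rec.accuracy == pytest.approx(0.7)
        assert rec.sensitivity == pytest.approx(0.6)
        assert rec.specificity == pytest.approx(0.8)
        assert rec.precision == pytest.approx(0.75)

    def test_undefined_ratio_reported_as_nan(self):
        rec = m.compute_metrics(np.zeros(3), np.zeros(3))
        assert np.isnan(rec.sensitivity) and np.isnan(rec.precision)
        assert rec.specificity == 1.0

    @given(st.lists(st.booleans(), min_size=1, max_size=200), st.data())
    @settings(max_examples=100, deadline=None)
    def test_metric_identities_over_random_confusions(self, truth, data):
        truth = np.array(truth)
        calls = np.array(data.draw(st.lists(st.booleans(), min_size=len(truth),
                                            max_size=len(truth))))
        rec = m.compute_metrics(calls, truth)
        total = rec.tp + rec.fp + rec.tn + rec.fn
        assert total == len(truth)
        assert rec.accuracy == pytest.approx((rec.tp + rec.tn) / total)
        if rec.tp + rec.fn:
            assert rec.sensitivity == pytest.approx(rec.tp / (rec.tp + rec.fn))
        if rec.tn + rec.fp:
            assert rec.specificity == pytest.approx(rec.tn / (rec.tn + rec.fp))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.compute_metrics(np.zeros(3), np.zeros(4))


class TestThresholdSweep:
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=100),
           st.lists(st.booleans(), min_size=5, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_sensitivity_specificity_monotone(self, scores, truth):
        n = min(len(scores), len(truth))
        scores, truth = np.array(scores[:n]), np.array(truth[:n])
        if truth.all() or not truth.any():
            return
        sweep = m.threshold_sweep(scores, truth, np.linspace(0.1, 0.9, 9))
        sens = sweep["sensitivity"].to_numpy()
        spec = sweep["specificity"].to_numpy()
        assert np.all(np.diff(sens) <= 1e-12)
        assert np.all(np.diff(spec) >= -1e-12)

    def test_extreme_thresholds(self):
        scores = np.array([0.2, 0.6, 0.9, 0.4])
        truth = np.array([0, 1, 1, 0])
        sweep = m.threshold_sweep(scores, truth, np.array([0.0, 1.0]))
        assert sweep.iloc[0]["sensitivity"] == 1.0  # every score > 0 called positive
        assert sweep.iloc[1]["specificity"] == 1.0  # nothing exceeds 1


@pytest.fixture(scope="module")
def biopsy_slide():
    """Half-tumour slide with cells on a grid and planted positivity flags."""
    rng = np.random.default_rng(8)
    mask = np.zeros((400, 400), dtype=np.uint8)
    mask[:200] = 1
    ys, xs = np.mgrid[5:395:8, 5:395:8]
    cells = pd.DataFrame({"y": ys.ravel(), "x": xs.ravel()})
    flags = pd.DataFrame(
        {marker: rng.random(len(cells)) < 0.1 for marker in MARKERS}
    )
    return mask, cells, flags


class TestVirtualBiopsies:
    def test_fixed_seed_reproducible(self, biopsy_slide):
        mask, cells, _ = biopsy_slide
        spec = ROISpec(seed=1, n_per_class=5)
        a = m.sample_virtual_biopsies(mask, cells, spec, side_px=60)
        b = m.sample_virtual_biopsies(mask, cells, spec, side_px=60)
        assert [(r.y, r.x, r.cls) for r in a] == [(r.y, r.x, r.cls) for r in b]

    def test_tumour_roi_contains_only_tumour_cells(self, biopsy_slide):
        mask, cells, _ = biopsy_slide
        rois = m.sample_virtual_biopsies(mask, cells, ROISpec(seed=2, n_per_class=5, purity=1.0),
                                         side_px=60)
        for roi in rois:
            inside = cells.iloc[roi.cell_index]
            assert np.all(mask[inside.y.to_numpy(), inside.x.to_numpy()] == roi.cls)

    def test_roi_cells_unique_and_subset(self, biopsy_slide):
        mask, cells, _ = biopsy_slide
        rois = m.sample_virtual_biopsies(mask, cells, ROISpec(seed=3, n_per_class=5), side_px=60)
        for roi in rois:
            assert len(np.unique(roi.cell_index)) == len(roi.cell_index)
            assert roi.cell_index.max() < len(cells)

    def test_oversized_roi_rejected(self, biopsy_slide):
        mask, cells, _ = biopsy_slide
        with pytest.raises(ValueError):
            m.sample_virtual_biopsies(mask, cells, ROISpec(seed=0), side_px=1000)


class TestMarkerCombinations:
    def test_all_negative_cells(self, biopsy_slide):
        mask, cells, _ = biopsy_slide
        flags = pd.DataFrame({marker: np.zeros(len(cells), bool) for marker in MARKERS})
        rois = m.sample_virtual_biopsies(mask, cells, ROISpec(seed=4, n_per_class=4), side_px=60)
        out = m.tabulate_marker_combinations(rois, flags)
        combos = out[out.kind == "combination"]
        allneg = combos[(combos[list(MARKERS)] == "neg.").all(axis=1)]
        assert allneg.iloc[0]["pt_mean"] == 100.0 and allneg.iloc[0]["ntl_mean"] == 100.0
        assert combos["pt_mean"].sum() == pytest.approx(100.0)

    def test_combination_rows_partition_each_roi(self, biopsy_slide):
        mask, cells, flags = biopsy_slide
        rois = m.sample_virtual_biopsies(mask, cells, ROISpec(seed=5, n_per_class=6), side_px=60)
        out = m.tabulate_marker_combinations(rois, flags)
        combos = out[out.kind == "combination"]
        assert combos["pt_mean"].sum() == pytest.approx(100.0, abs=1e-9)
        assert combos["ntl_mean"].sum() == pytest.approx(100.0, abs=1e-9)
        assert len(out) == 5 + 32

    def test_planted_fraction_difference_detected(self):
        """CD3 fractions seeded at the study's tumour/non-tumour values are
        reproduced by the ROI tabulation within sampling tolerance."""
        rng = np.random.default_rng(9)
        mask = np.zeros((400, 400), dtype=np.uint8)
        mask[:200] = 1
        ys, xs = np.mgrid[2:398:4, 2:398:4]
        cells = pd.DataFrame({"y": ys.ravel(), "x": xs.ravel()})
        tumour = mask[cells.y, cells.x] == 1
        p = np.where(tumour, 0.0385, 0.0808)
        flags = pd.DataFrame({marker: np.zeros(len(cells), bool) for marker in MARKERS})
        flags["CD3"] = rng.random(len(cells)) < p
        rois = m.sample_virtual_biopsies(mask, cells, ROISpec(seed=6, n_per_class=10), side_px=80)
        out = m.tabulate_marker_combinations(rois, flags)
        cd3_any = out[(out.kind == "any") & (out["CD3"] == "pos.")].iloc[0]
        assert cd3_any["pt_mean"] == pytest.approx(3.85, abs=1.5)
        assert cd3_any["ntl_mean"] == pytest.approx(8.08, abs=1.5)
        assert cd3_any["p_value"] < 0.05


class TestSweepsAndAblation:
    def test_whole_slide_equals_global_metrics(self, biopsy_slide):
        mask, cells, _ = biopsy_slide
        rng = np.random.default_rng(10)
        labels = mask[cells.y, cells.x]
        scores = np.clip(labels * 0.6 + rng.random(len(cells)) * 0.4, 0, 1)
        sweep = roi_size_sweep(scores, labels, cells, mask, [WHOLE_SLIDE], ROISpec(seed=0))
        expected = m.compute_metrics(scores > 0.5, labels).accuracy
        assert sweep.iloc[0]["mean_accuracy"] == pytest.approx(expected)

    def test_roi_sizes_bounded_and_reported(self, biopsy_slide):
        mask, cells, _ = biopsy_slide
        rng = np.random.default_rng(11)
        labels = mask[cells.y, cells.x]
        scores = np.clip(labels * 0.8 + rng.random(len(cells)) * 0.2, 0, 1)
        spec = ROISpec(seed=1, n_per_class=4, pixel_size_um=2.0)
        sweep = roi_size_sweep(scores, labels, cells, mask, [1, WHOLE_SLIDE], spec, n_repeats=3)
        assert set(sweep["size_fields"]) == {1, WHOLE_SLIDE}
        assert ((sweep["mean_accuracy"] >= 0.5) & (sweep["mean_accuracy"] <= 1.0)).all()

    def test_ablation_one_row_per_feature_and_ranking(self):
        rng = np.random.default_rng(12)
        n = 3000
        labels = (rng.random(n) < 0.5).astype(int)
        df = pd.DataFrame(
            {
                "signal": rng.standard_normal(n) + 2.5 * labels,
                "noise_a": rng.standard_normal(n),
                "noise_b": rng.standard_normal(n),
            }
        )

        def train_without(kept):
            model = m.icf_select(df[kept], labels, n_select=len(kept))
            scores = m.combine_score(df[kept], model)
            return m.compute_metrics(m.classify_scores(scores), labels).accuracy

        out = ablate_features(train_without, ["signal", "noise_a", "noise_b"], list(df.columns))
        assert len(out) == 3
        assert out.iloc[0]["omitted"] == "signal"  # losing the signal hurts most
        base = train_without(list(df.columns))
        assert base - out[out.omitted == "signal"].iloc[0]["accuracy"] > 0.2
        for noise in ("noise_a", "noise_b"):
            assert abs(out[out.omitted == noise].iloc[0]["accuracy"] - base) < 0.05

    def test_unknown_ablation_feature_rejected(self):
        with pytest.raises(KeyError):
            ablate_features(lambda kept: 1.0, ["nope"], ["a", "b"])


def test_mann_whitney_small_samples_exact():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([10.0, 11.0, 12.0])
    p = mann_whitney_u(x, y)
    assert p == pytest.approx(0.1, abs=1e-9)  # exact two-sided p for total separation
    assert np.isnan(mann_whitney_u(x, np.array([])))
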