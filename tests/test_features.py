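"""Per-cell feature extraction: segmentation, morphology, intensity
statistics, positivity, neighbourhood features, and table assembly."""

import numpy as np
import pandas as pd
import pytest

import mifscore as m
from mifscore.features import assemble_features, compute_feature_table
from mifscore.registry import ENV_SD_BASES, MARKERS


def _draw_ellipse(raster, cy, cx, a, b, value):
    yy, xx = np.mgrid[: raster.shape[0], : raster.shape[1]]
    inside = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    raster[inside] = value
    return inside


class TestSegmentation:
    def test_two_separated_ellipses_found(self):
        dapi = np.zeros((128, 128), dtype=float)
        _draw_ellipse(dapi, 30, 30, 8, 6, 100.0)
        _draw_ellipse(dapi, 90, 95, 7, 9, 120.0)
        segments = m.segment_nuclei(dapi)
        assert len(segments) == 2
        centroids = sorted(s.centroid for s in segments)
        assert abs(centroids[0][0] - 30) <= 1 and abs(centroids[0][1] - 30) <= 1
        assert abs(centroids[1][0] - 90) <= 1 and abs(centroids[1][1] - 95) <= 1

    def test_blank_raster_yields_no_segments(self):
        assert m.segment_nuclei(np.zeros((64, 64))) == []

    def test_min_area_filter_removes_speck(self):
        dapi = np.zeros((64, 64))
        _draw_ellipse(dapi, 20, 20, 8, 8, 100.0)
        dapi[50, 50] = 100.0  # 1-px speck
        assert len(m.segment_nuclei(dapi, min_area=15)) == 1

    def test_unknown_backend_rejected(self):
        with pytest.raises(KeyError):
            m.segment_nuclei(np.zeros((8, 8)), backend="no_such_backend")


class TestMorphology:
    def test_disc_measurements_match_moment_oracle(self):
        yy, xx = np.mgrid[:32, :32]
        pixels = np.column_stack(np.nonzero((yy - 15) ** 2 + (xx - 15) ** 2 <= 100))
        seg = m.extract_morphology(pixels)
        assert 305 <= seg.area <= 325
        assert seg.eccentricity <= 0.1
        # brute-force second-central-moment oracle on the same pixel set
        c = pixels.mean(axis=0)
        d = pixels - c
        cov = d.T @ d / len(d)
        eigs = np.linalg.eigvalsh(cov)
        major_oracle, minor_oracle = 4 * np.sqrt(eigs[1]), 4 * np.sqrt(eigs[0])
        assert seg.major_axis == pytest.approx(major_oracle, rel=1e-6)
        assert seg.minor_axis == pytest.approx(minor_oracle, rel=1e-6)

    def test_axis_ratio_of_2to1_ellipse(self):
        raster = np.zeros((64, 64))
        _draw_ellipse(raster, 32, 32, 20, 10, 1.0)
        seg = m.extract_morphology(np.column_stack(np.nonzero(raster)))
        assert seg.major_axis / seg.minor_axis == pytest.approx(2.0, rel=0.1)

    def test_single_pixel_convention(self):
        seg = m.extract_morphology(np.array([[5, 7]]))
        assert (seg.area, seg.minor_axis, seg.major_axis, seg.eccentricity, seg.circularity) == (
            1, 1.0, 1.0, 0.0, 1.0,
        )

    def test_degenerate_line_stays_in_bounds(self):
        seg = m.extract_morphology(np.array([[0, x] for x in range(10)]))
        assert seg.minor_axis >= 1.0
        assert 0 <= seg.eccentricity < 1


class TestIntensities:
    def _segment(self, pixels):
        return m.extract_morphology(np.asarray(pixels))

    def test_uniform_segment(self):
        rasters = np.full((6, 8, 8), 7.5)
        seg = self._segment([[2, 2], [2, 3], [3, 2], [3, 3]])
        mean, mean25, sd = m.measure_intensities(seg, rasters)
        assert np.allclose(mean, 7.5) and np.allclose(mean25, 7.5) and np.allclose(sd, 0.0)

    def test_hand_computed_four_pixel_values(self):
        rasters = np.zeros((1, 4, 4))
        rasters[0, 0, :4] = [1.0, 2.0, 3.0, 4.0]
        seg = self._segment([[0, 0], [0, 1], [0, 2], [0, 3]])
        mean, mean25, sd = m.measure_intensities(seg, rasters)
        assert mean[0] == pytest.approx(2.5)
        assert mean25[0] == pytest.approx(4.0)  # ceil(0.25*4)=1 brightest pixel
        assert sd[0] == pytest.approx(np.sqrt(1.25))

    def test_mean25_dominates_mean_on_random_segments(self):
        rng = np.random.default_rng(0)
        rasters = rng.random((6, 64, 64)) * 100
        for _ in range(200):
            n = int(rng.integers(1, 40))
            pix = np.unique(rng.integers(0, 64, size=(n, 2)), axis=0)
            mean, mean25, _ = m.measure_intensities(self._segment(pix), rasters)
            assert np.all(mean25 >= mean - 1e-9)

    def test_out_of_bounds_pixel_names_segment(self):
        seg = self._segment([[70, 2]])
        with pytest.raises(ValueError, match=str(seg.label)):
            m.measure_intensities(seg, np.zeros((6, 64, 64)))


class TestAutofluorescence:
    def test_constant_intensity_corrects_to_zero(self):
        corrected, baselines = m.correct_autofluorescence(np.full((50, 5), 3.3))
        assert np.allclose(corrected, 0.0) and np.allclose(baselines, 3.3)

    def test_corrected_clamped_between_zero_and_raw(self):
        rng = np.random.default_rng(1)
        raw = rng.random((500, 5)) * 50
        corrected, _ = m.correct_autofluorescence(raw)
        assert np.all(corrected >= 0) and np.all(corrected <= raw + 1e-12)

    def test_zero_baseline_leaves_raw(self):
        raw = np.tile(np.array([[10.0, 20.0, 30.0, 40.0, 50.0]]), (20, 1))
        corrected, _ = m.correct_autofluorescence(raw, baseline_percentile=0)
        # all cells identical: 0th percentile equals the value, so corrected = 0
        assert np.allclose(corrected, 0.0)
        raw2 = np.vstack([np.zeros((1, 5)), raw])
        corrected2, baselines2 = m.correct_autofluorescence(raw2, baseline_percentile=0)
        assert np.allclose(baselines2, 0.0) and np.allclose(corrected2, raw2)


class TestPositivity:
    def test_constant_values_give_zero_positives(self):
        assert m.call_positivity(np.full(100, 5.0)).sum() == 0

    def test_single_outlier_detected(self):
        values = np.zeros(100)
        values[-1] = 100.0
        flags = m.call_positivity(values)
        assert flags.sum() == 1 and flags[-1]

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(2)
        flags = m.call_positivity(rng.standard_normal(100_000))
        assert flags.mean() == pytest.approx(0.0228, abs=0.002)

    def test_fewer_than_two_cells_warns_all_false(self):
        with pytest.warns(UserWarning):
            assert not m.call_positivity(np.array([1.0])).any()


class TestNeighbourhood:
    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(3)
        n, radius = 500, 40.0
        pts = rng.random((n, 2)) * 300
        pos = rng.random((n, 5)) < 0.1
        pos_af = rng.random((n, 5)) < 0.05
        env = rng.random((n, 4)) * 10
        density, counts, counts_af, env_sd = m.neighbourhood_features(pts, pos, pos_af, env, radius)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        nb = d2 <= radius**2  # includes self
        for i in range(n):
            others = nb[i].copy()
            others[i] = False
            assert density[i] == others.sum()
            assert np.array_equal(counts[i], pos[others].sum(axis=0))
            assert np.array_equal(counts_af[i], pos_af[others].sum(axis=0))
            assert np.allclose(env_sd[i], env[nb[i]].std(axis=0, ddof=0))

    def test_isolated_cell_all_zero(self):
        pts = np.array([[0.0, 0.0], [500.0, 500.0]])
        density, counts, counts_af, env_sd = m.neighbourhood_features(
            pts, np.ones((2, 5), bool), np.ones((2, 5), bool), np.ones((2, 3)), 10.0
        )
        assert density[0] == 0 and counts[0].sum() == 0 and env_sd[0].sum() == 0

    def test_boundary_distance_inclusive(self):
        pts = np.array([[0.0, 0.0], [0.0, 30.0]])
        density, *_ = m.neighbourhood_features(
            pts, np.zeros((2, 5), bool), np.zeros((2, 5), bool), np.zeros((2, 1)), 30.0
        )
        assert density[0] == 1 and density[1] == 1

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            m.neighbourhood_features(np.zeros((1, 2)), np.zeros((1, 5)), np.zeros((1, 5)),
                                     np.zeros((1, 1)), 0.0)


class TestAssembly:
    def test_default_registry_table_width_68(self, strong_cohort):
        _, _, table = strong_cohort[0]
        assert table.df.shape[1] == 68
        assert list(table.df.columns) == m.FeatureRegistry.default().names

    def test_empty_cell_list_gives_empty_table_with_header(self, registry):
        table = assemble_features(
            [], {"mean": np.zeros((0, 6)), "mean25": np.zeros((0, 6)), "sd": np.zeros((0, 6))},
            np.zeros((0, 5)),
            {"density": np.zeros(0), "pos_count": np.zeros((0, 5)),
             "pos_count_af": np.zeros((0, 5)), "env_sd": np.zeros((0, len(ENV_SD_BASES)))},
            np.zeros((16, 16)), registry,
        )
        assert len(table) == 0 and list(table.df.columns) == registry.names

    def test_row_order_follows_input_order(self):
        rng = np.random.default_rng(4)
        rasters = np.zeros((6, 128, 128))
        rasters[:, :, :] = 1.0
        segs = []
        for k, (cy, cx) in enumerate([(20, 20), (60, 60), (100, 40)]):
            yy, xx = np.mgrid[cy - 3 : cy + 4, cx - 3 : cx + 4]
            segs.append(m.extract_morphology(np.column_stack([yy.ravel(), xx.ravel()]), label=k + 1))
        mask = np.zeros((128, 128))
        table_fwd = compute_feature_table(rasters, mask, segs)
        table_rev = compute_feature_table(rasters, mask, segs[::-1])
        merged = table_rev.df.loc[table_fwd.df.index]
        assert np.allclose(table_fwd.df.to_numpy(), merged.to_numpy())

    def test_centroid_outside_mask_rejected(self, registry):
        seg = m.extract_morphology(np.array([[40, 40]]))
        with pytest.raises(ValueError):
            assemble_features(
                [seg], {"mean": np.zeros((1, 6)), "mean25": np.zeros((1, 6)), "sd": np.zeros((1, 6))},
                np.zeros((1, 5)),
                {"density": np.zeros(1), "pos_count": np.zeros((1, 5)),
                 "pos_count_af": np.zeros((1, 5)), "env_sd": np.zeros((1, len(ENV_SD_BASES)))},
                np.zeros((16, 16)), registry,
            )
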