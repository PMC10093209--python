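"""Linear cancer-score models and feature normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mifscore as m
from mifscore.models.linear import LinearScoreModel, _wilks_lambda
from mifscore.models.normalize import Normalizer

from conftest import INFORMATIVE


@pytest.fixture(scope="module")
def selection_table():
    config = m.SimulationConfig(
        seed=21, n_cells_target=8000, informative_features={f: 3.0 for f in INFORMATIVE}
    )
    return m.generate_feature_table(config)


class TestNormalizer:
    def test_none_is_identity(self, selection_table):
        table, _ = selection_table
        out = Normalizer("none").fit_transform(table.df)
        assert out.equals(table.df)

    def test_zscore_standardises_training_slice(self, selection_table):
        table, _ = selection_table
        out = Normalizer("zscore").fit_transform(table.df)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_feature_specific_clips_and_passes_bounded(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"area": rng.random(5000) * 100, "eccentricity": rng.random(5000)}
        )
        norm = Normalizer("feature_specific").fit(df)
        probe = pd.DataFrame({"area": [-1e9, 1e9], "eccentricity": [0.25, 0.75]})
        out = norm.transform(probe)
        assert out["area"].tolist() == [0.0, 1.0]  # clipped at the percentile bounds
        assert out["eccentricity"].tolist() == [0.25, 0.75]  # pass-through

    def test_degenerate_feature_maps_to_zero_with_warning(self):
        df = pd.DataFrame({"area": np.full(100, 5.0)})
        norm = Normalizer("zscore").fit(df)
        with pytest.warns(UserWarning):
            out = norm.transform(df)
        assert (out["area"] == 0).all()

    def test_unfitted_transform_rejected(self):
        with pytest.raises(RuntimeError):
            Normalizer("zscore").transform(pd.DataFrame({"a": [1.0]}))


class TestICFSelection:
    def test_planted_features_selected(self, selection_table):
        table, labels = selection_table
        model = m.icf_select(table.df, labels)
        assert set(model.feature_names) == set(INFORMATIVE)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_five_features_all_selected(self, selection_table):
        table, labels = selection_table
        sub = table.df[["area", "density", "mean_DAPI", "circularity"]]
        model = m.icf_select(sub, labels)
        assert len(model.feature_names) == 4
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weights_proportional_to_abs_correlation(self):
        # two features engineered to |r| = 0.6 and 0.3 exactly (up to float error)
        rng = np.random.default_rng(5)
        n = 200_000
        labels = (rng.random(n) < 0.5).astype(int)
        y = (labels - labels.mean()) / labels.std(ddof=0)
        noise = rng.standard_normal((n, 2))
        noise -= np.outer(y, y @ noise / n)  # orthogonalise against the labels
        noise /= noise.std(axis=0, ddof=0)
        f1 = 0.6 * y + np.sqrt(1 - 0.36) * noise[:, 0]
        f2 = -0.3 * y + np.sqrt(1 - 0.09) * noise[:, 1]
        df = pd.DataFrame({"f1": f1, "f2": f2})
        model = m.icf_select(df, labels, n_select=2)
        assert model.weights[list(model.feature_names).index("f1")] == pytest.approx(2 / 3, abs=0.01)
        assert model.weights[list(model.feature_names).index("f2")] == pytest.approx(1 / 3, abs=0.01)
        assert model.invert[list(model.feature_names).index("f2")]

    def test_single_class_labels_rejected(self, selection_table):
        table, _ = selection_table
        with pytest.raises(ValueError):
            m.icf_select(table.df, np.zeros(len(table.df)))


class TestMANOVASelection:
    def test_informative_feature_selected_first(self, selection_table):
        table, labels = selection_table
        model = m.manova_select(table.df, labels)
        # exhaustive single-feature Wilks' lambda oracle
        lambdas = {
            name: _wilks_lambda(table.df[[name]].to_numpy(), labels)
            for name in table.df.columns
        }
        assert model.feature_names[0] == min(lambdas, key=lambdas.get)
        assert set(model.feature_names) == set(INFORMATIVE)

    def test_duplicate_of_selected_feature_not_chosen_next(self):
        rng = np.random.default_rng(6)
        n = 5000
        labels = (rng.random(n) < 0.5).astype(int)
        strong = rng.standard_normal(n) + 3.0 * labels
        weak = rng.standard_normal(n) + 0.8 * labels
        df = pd.DataFrame(
            {
                "strong": strong,
                "strong_copy": strong + 1e-3 * rng.standard_normal(n),
                "weak": weak,
            }
        )
        model = m.manova_select(df, labels, n_select=2)
        # either twin may win step 1 (they are statistically identical), but
        # step 2 must prefer the weaker independent feature over the duplicate
        assert model.feature_names[0] in ("strong", "strong_copy")
        assert model.feature_names[1] == "weak"
        # exhaustive check: adding the weak independent feature reduces lambda
        # more than adding the near-duplicate
        lam_copy = _wilks_lambda(df[["strong", "strong_copy"]].to_numpy(), labels)
        lam_weak = _wilks_lambda(df[["strong", "weak"]].to_numpy(), labels)
        assert lam_weak < lam_copy

    def test_five_features_total_returns_all(self, selection_table):
        table, labels = selection_table
        sub = table.df[INFORMATIVE]
        model = m.manova_select(sub, labels)
        assert set(model.feature_names) == set(INFORMATIVE)


class TestCombineScore:
    def _one_feature_model(self, invert: bool) -> LinearScoreModel:
        r = -0.5 if invert else 0.5
        return LinearScoreModel(["f"], np.array([r]), np.array([1.0]), {"f": (0.0, 1.0)})

    def test_single_positive_feature_passes_value(self):
        df = pd.DataFrame({"f": [0.7]})
        assert m.combine_score(df, self._one_feature_model(False))[0] == pytest.approx(0.7)

    def test_negative_correlation_inverts(self):
        df = pd.DataFrame({"f": [0.7]})
        assert m.combine_score(df, self._one_feature_model(True))[0] == pytest.approx(0.3)

    def test_matches_independent_weighted_sum_oracle(self):
        rng = np.random.default_rng(7)
        names = [f"f{i}" for i in range(5)]
        df = pd.DataFrame(rng.random((1000, 5)) * 10, columns=names)
        r = rng.uniform(-1, 1, 5)
        w = np.abs(r) / np.abs(r).sum()
        bounds = {n: (0.0, 10.0) for n in names}
        model = LinearScoreModel(names, r, w, bounds)
        score = m.combine_score(df, model)
        # independently coded oracle
        oracle = np.zeros(len(df))
        for i, n in enumerate(names):
            v = np.clip((df[n].to_numpy() - 0.0) / 10.0, 0, 1)
            oracle += w[i] * (1.0 - v if r[i] < 0 else v)
        assert np.max(np.abs(score - oracle)) < 1e-12
        assert score.min() >= 0.0 and score.max() <= 1.0

    def test_missing_feature_column_named(self):
        model = self._one_feature_model(False)
        with pytest.raises(KeyError, match="'f'"):
            m.combine_score(pd.DataFrame({"g": [1.0]}), model)


class TestClassify:
    def test_strict_threshold_boundary(self):
        calls = m.classify_scores(np.array([0.2, 0.5, 0.8]), 0.5)
        assert calls.tolist() == [False, False, True]

    def test_zero_threshold(self):
        calls = m.classify_scores(np.array([0.0, 0.01, 0.9]), 0.0)
        assert calls.tolist() == [False, True, True]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_adds_positives(self, scores):
        scores = np.array(scores)
        counts = [m.classify_scores(scores, t).sum() for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_out_of_range_threshold_warns(self):
        with pytest.warns(UserWarning):
            m.classify_scores(np.array([0.5]), 1.5)
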