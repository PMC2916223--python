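import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from her2ia.classify import (
    FEATURE_COLUMNS,
    Her2Category,
    Her2Classifier,
    fish_category,
    parse_category,
    select_training_set,
)
from her2ia.errors import ConfigError, ValidationError
from her2ia.features import SlideFeatures


def make_features(absorbance=0.5, continuity=50.0, immuno=50.0):
    return SlideFeatures(
        mean_membrane_absorbance=absorbance,
        pct_membrane_positive_pixels=immuno,
        pct_membrane_continuity=continuity,
        pct_immunopositive_pixels=immuno,
        n_cells=40,
    )


def gaussian_table(rng, means, cov, n_per_class):
    """Synthetic feature table with known class-conditional parameters."""
    frames = []
    for lbl, mu in means.items():
        x = rng.multivariate_normal(mu, cov, size=n_per_class)
        frames.append(
            pd.DataFrame(x, columns=list(FEATURE_COLUMNS)).assign(label=lbl)
        )
    return pd.concat(frames, ignore_index=True)


class TestCategories:
    @pytest.mark.parametrize(
        "label,expected",
        [("0/1+", Her2Category.NEG), ("0", Her2Category.NEG),
         ("1+", Her2Category.NEG), ("2+", Her2Category.EQUIVOCAL),
         ("3+", Her2Category.POSITIVE)],
    )
    def test_label_parsing_with_synonyms(self, label, expected):
        assert parse_category(label) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            parse_category("4+")

    @pytest.mark.parametrize(
        "ratio,expected",
        [(1.18, Her2Category.NEG), (1.97, Her2Category.EQUIVOCAL),
         (1.8, Her2Category.EQUIVOCAL), (2.2, Her2Category.EQUIVOCAL),
         (2.21, Her2Category.POSITIVE), (0.0, Her2Category.NEG)],
    )
    def test_fish_thresholds(self, ratio, expected):
        assert fish_category(ratio) == expected

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValidationError):
            fish_category(-0.5)


class TestTrainingSplit:
    def test_highest_random_number_split_sizes(self):
        cohorts = {
            "kit_a": [f"a{i}" for i in range(144)],
            "kit_b": [f"b{i}" for i in range(140)],
            "kit_c": [f"c{i}" for i in range(141)],
        }
        train, valid = select_training_set(cohorts, n=50, seed=1)
        assert len(train) == 150
        assert len(valid) == 275
        assert set(train) | set(valid) == {x for ids in cohorts.values() for x in ids}
        assert set(train) & set(valid) == set()

    def test_deterministic_given_seed(self):
        cohorts = {"a": list(range(60)), "b": list(range(100, 170))}
        assert select_training_set(cohorts, 20, seed=9) == select_training_set(
            cohorts, 20, seed=9
        )

    def test_cohort_too_small_rejected(self):
        with pytest.raises(ValidationError, match="fewer than"):
            select_training_set({"a": [1, 2, 3]}, n=5, seed=0)


class TestTraining:
    def test_separated_clusters_high_resubstitution_accuracy(self, rng):
        # three clusters, 6 SD apart, 50 per class
        means = {"0/1+": (0.0, 0.0), "2+": (6.0, 0.0), "3+": (6.0, 6.0)}
        table = gaussian_table(rng, means, np.eye(2), 50)
        model = Her2Classifier.fit(table)
        calls = model.classify_table(table.assign(pct_immunopositive_pixels=50.0))
        assert (calls["category"] == table["label"]).mean() >= 0.98

    def test_missing_class_rejected(self, rng):
        table = gaussian_table(rng, {"0/1+": (0, 0), "2+": (5, 5)}, np.eye(2), 20)
        with pytest.raises(ValidationError, match="3\\+"):
            Her2Classifier.fit(table)

    def test_parameter_recovery_at_n200(self, rng):
        means = {"0/1+": (0.0, 0.0), "2+": (3.0, 1.0), "3+": (6.0, 2.0)}
        cov = np.array([[1.0, 0.3], [0.3, 0.5]])
        table = gaussian_table(rng, means, cov, 200)
        model = Her2Classifier.fit(table)
        for lbl, mu in means.items():
            c = parse_category(lbl)
            true_std = (np.asarray(mu) - model.feature_mean) / model.feature_scale
            assert np.abs(model.means[c] - true_std).max() < 0.1
        assert np.allclose(model.priors, 1 / 3)

    def test_save_load_roundtrip(self, tmp_path, fitted_model):
        p = tmp_path / "model.yaml"
        fitted_model.save(p)
        loaded = Her2Classifier.load(p)
        assert np.allclose(loaded.priors, fitted_model.priors)
        assert np.allclose(loaded.means, fitted_model.means)
        assert np.allclose(loaded.covariances, fitted_model.covariances)
        f = make_features()
        assert loaded.classify(f).category == fitted_model.classify(f).category

    def test_summary_reports_parameters(self, fitted_model):
        s = fitted_model.summary()
        assert "prior" in s and "0/1+" in s and "3+" in s


class TestClassification:
    def test_low_positivity_override_dominates(self, fitted_model):
        f = make_features(absorbance=2.0, continuity=99.0, immuno=0.5)
        call = fitted_model.classify(f)
        assert call.category == Her2Category.NEG
        assert call.override_rule
        assert call.confidence_pct == 100.0

    @given(
        absorbance=st.floats(0, 3), continuity=st.floats(0, 100),
        immuno=st.floats(0, 0.999),
    )
    def test_override_for_any_feature_vector(
        self, fitted_model, absorbance, continuity, immuno
    ):
        call = fitted_model.classify(make_features(absorbance, continuity, immuno))
        assert call.category == Her2Category.NEG and call.override_rule

    def test_untrained_model_refuses(self):
        with pytest.raises(ConfigError):
            Her2Classifier().classify(make_features())

    def test_equidistant_two_class_confidence_is_fifty(self):
        # symmetric NEG/POSITIVE classes; EQUIVOCAL parked far away
        model = Her2Classifier(
            priors=np.array([0.4999, 0.0002, 0.4999]),
            means=np.array([[-1.0, 0.0], [50.0, 50.0], [1.0, 0.0]]),
            covariances=np.array([np.eye(2)] * 3),
            feature_mean=np.zeros(2),
            feature_scale=np.ones(2),
        )
        call = model.classify(make_features(absorbance=0.0, continuity=0.0))
        assert call.confidence_pct == pytest.approx(50.0, abs=0.1)

    def test_feature_at_class_mean_is_confident(self, rng):
        means = {"0/1+": (0.0, 0.0), "2+": (6.0, 0.0), "3+": (6.0, 6.0)}
        table = gaussian_table(rng, means, np.eye(2), 100)
        model = Her2Classifier.fit(table)
        call = model.classify(make_features(absorbance=6.0, continuity=6.0))
        assert call.category == Her2Category.POSITIVE
        assert call.confidence_pct >= 99.0

    def test_posteriors_sum_to_one(self, fitted_model, rng):
        for _ in range(20):
            x = rng.uniform([0, 0], [2, 100])
            p = fitted_model.posterior(x)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            call = fitted_model.classify(
                make_features(absorbance=x[0], continuity=x[1], immuno=50.0)
            )
            assert call.confidence_pct == pytest.approx(100 * p.max(), abs=1e-6)

    def test_ordinal_consistency_along_continuity(self, fitted_model):
        """Raising continuity at fixed absorbance never downgrades a
        positive call to negative without passing the equivocal category."""
        for absorbance in (0.3, 0.5, 0.7, 0.9):
            calls = [
                fitted_model.classify(
                    make_features(absorbance=absorbance, continuity=c, immuno=30.0)
                ).category
                for c in np.linspace(0, 100, 101)
            ]
            positive_seen = False
            for cur in calls:
                if cur == Her2Category.POSITIVE:
                    positive_seen = True
                elif cur == Her2Category.EQUIVOCAL:
                    positive_seen = False
                else:  # a negative call after POSITIVE must have passed 2+
                    assert not positive_seen
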