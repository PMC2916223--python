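import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from her2ia.classify import Her2Category
from her2ia.errors import ValidationError
from her2ia.stats import (
    ReferenceRanges,
    cohens_kappa,
    confusion_matrix,
    control_drift_check,
    diagnostic_accuracy,
    fish_concordance,
    landis_koch_label,
    roc_auc,
)

tables = st.lists(
    st.lists(st.integers(0, 20), min_size=3, max_size=3), min_size=3, max_size=3
).map(np.array).filter(lambda t: t.sum() > 0)


def auc_oracle(scores, truth):
    """Exhaustive pair counting: concordant + half of tied pairs."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    num = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return num / (len(pos) * len(neg))


class TestKappa:
    def test_identical_calls_are_perfect(self):
        calls = [Her2Category.NEG] * 5 + [Her2Category.POSITIVE] * 5
        cm = confusion_matrix(calls, calls)
        assert cm.concordance_pct == 100.0
        assert cm.kappa == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            confusion_matrix([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_matrix(["2+"], ["2+", "3+"])

    def test_outer_product_table_kappa_exactly_zero(self):
        # marginals (20, 10) x (15, 15): independence => kappa = 0
        row = np.array([20, 10, 0])
        col = np.array([15, 15, 0])
        table = np.outer(row, col) / 30.0
        assert cohens_kappa(table) == pytest.approx(0.0, abs=1e-12)

    @given(t=tables)
    def test_transpose_invariance(self, t):
        try:
            k = cohens_kappa(t)
        except ValidationError:
            return
        assert cohens_kappa(t.T) == pytest.approx(k, abs=1e-12)

    @given(t=tables, perm=st.permutations([0, 1, 2]))
    def test_simultaneous_permutation_invariance(self, t, perm):
        try:
            k = cohens_kappa(t)
        except ValidationError:
            return
        p = list(perm)
        assert cohens_kappa(t[np.ix_(p, p)]) == pytest.approx(k, abs=1e-12)

    @given(t=tables)
    def test_agrees_with_sklearn(self, t):
        from sklearn.metrics import cohen_kappa_score

        a, b = [], []
        for i in range(3):
            for j in range(3):
                a.extend([i] * int(t[i, j]))
                b.extend([j] * int(t[i, j]))
        try:
            ours = cohens_kappa(t)
        except ValidationError:
            return
        theirs = cohen_kappa_score(a, b, labels=[0, 1, 2])
        if math.isnan(theirs):
            return
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestLandisKoch:
    @pytest.mark.parametrize(
        "kappa,label",
        [(0.81, "almost perfect"), (0.805, "almost perfect"), (1.0, "almost perfect"),
         (0.80, "substantial"), (0.5, "moderate"), (0.3, "fair"),
         (0.1, "slight"), (0.0, "poor"), (-0.4, "poor")],
    )
    def test_bins(self, kappa, label):
        assert landis_koch_label(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            landis_koch_label(1.2)


class TestDiagnosticAccuracy:
    def test_all_equivocal_calls_undefined(self):
        calls = [Her2Category.EQUIVOCAL] * 4
        fish = [Her2Category.POSITIVE, Her2Category.NEG] * 2
        acc = diagnostic_accuracy(calls, fish)
        assert not acc.sensitivity_defined and not acc.specificity_defined

    def test_accepts_raw_ratios(self):
        calls = ["3+", "0/1+", "3+", "0/1+"]
        ratios = [3.1, 1.2, 2.5, 4.0]
        acc = diagnostic_accuracy(calls, ratios)
        assert acc.sensitivity_pct == pytest.approx(100 * 2 / 3)
        assert acc.specificity_pct == pytest.approx(100.0)

    def test_fish_equivocal_cases_dropped(self):
        calls = ["3+", "0/1+", "3+"]
        ratios = [3.0, 1.0, 2.0]  # last is FISH-equivocal
        acc = diagnostic_accuracy(calls, ratios)
        assert acc.n_fish_equivocal_excluded == 1
        assert acc.n_informative == 2

    def test_perfect_calls_give_perfect_concordance(self):
        calls = ["3+", "3+", "0/1+", "0/1+"]
        fish = [Her2Category.POSITIVE] * 2 + [Her2Category.NEG] * 2
        res = fish_concordance(calls, fish)
        assert res.pct == 100.0
        assert res.pct_rounded == 100


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_constant_scores(self):
        assert roc_auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_tied_pair_matches_enumeration(self):
        scores, truth = [1, 2, 2, 4], [0, 0, 1, 1]
        assert roc_auc(scores, truth) == pytest.approx(auc_oracle(scores, truth))
        scores, truth = [1, 2, 3, 4], [0, 0, 1, 1]
        assert roc_auc(scores, truth) == pytest.approx(auc_oracle(scores, truth))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2], [1, 1])

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 5), st.booleans()), min_size=2, max_size=12
        ).filter(lambda d: len({t for _, t in d}) == 2)
    )
    def test_matches_pair_counting_oracle(self, data):
        scores = [s for s, _ in data]
        truth = [t for _, t in data]
        assert roc_auc(scores, truth) == pytest.approx(
            auc_oracle(scores, truth), abs=1e-12
        )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60)
        truth = rng.random(60) < 0.4
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        assert roc_auc(scores, truth) == pytest.approx(
            roc_auc_score(truth, scores), abs=1e-12
        )


class TestControlDrift:
    def make_reference(self):
        ref_batches = pd.DataFrame(
            {"mean_membrane_absorbance": [0.60, 0.62, 0.58, 0.61, 0.59],
             "pct_membrane_continuity": [90.0, 91.0, 89.5, 90.5, 89.0]}
        )
        return ReferenceRanges.from_batches(ref_batches)

    def test_batch_at_reference_mean_passes(self):
        ref = self.make_reference()
        batch = pd.DataFrame({"mean_membrane_absorbance": [0.60],
                              "pct_membrane_continuity": [90.0]})
        (report,) = control_drift_check(batch, ref)
        assert report.passed and report.flags == []

    def test_four_sd_excursion_flagged_with_feature_name(self):
        ref = self.make_reference()
        val = float(ref.mean["mean_membrane_absorbance"]
                    + 4 * ref.sd["mean_membrane_absorbance"])
        batch = pd.DataFrame({"mean_membrane_absorbance": [val],
                              "pct_membrane_continuity": [90.0]})
        (report,) = control_drift_check(batch, ref)
        assert not report.passed
        assert report.flags[0].feature == "mean_membrane_absorbance"

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            control_drift_check(pd.DataFrame({"x": [1.0]}), None)
        with pytest.raises(ValidationError):
            ReferenceRanges.from_batches(pd.DataFrame({"x": [1.0, 2.0]}))

    def test_injected_intensity_drop_first_flagged_at_drift_batch(self, cdef):
        """20% staining-intensity drop at batch 5 of a simulated control series."""
        from her2ia.pipeline import analyze_arrays
        from her2ia.synthslide import SyntheticSlideSpec, generate_slide

        rows = []
        for b in range(9):
            od = 0.7 if b < 5 else 0.7 * 0.8
            spec = SyntheticSlideSpec(n_cells=25, seed=500 + b,
                                      continuity_mean=1.0, dab_od_mean=od,
                                      dab_od_sd=0.04)
            img, ann, _ = generate_slide(spec, cdef)
            f = analyze_arrays(img, ann, cdef).features
            rows.append({"mean_membrane_absorbance": f.mean_membrane_absorbance})
        batches = pd.DataFrame(rows)
        ref = ReferenceRanges.from_batches(batches.iloc[:4])
        reports = control_drift_check(batches.iloc[4:], ref)
        flagged = [r.batch for r in reports if not r.passed]
        assert flagged and flagged[0] == 5
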