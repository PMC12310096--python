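import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trochlea.geometry import KneeRecord
from trochlea.synthetic import CohortSpec, generate_cohort
from trochlea.thresholding import (
    DejourClassifier,
    NoSplitError,
    SingleSplitClassifier,
    ThresholdRule,
    best_split,
    derive_thresholds,
    gini,
)

from conftest import make_record


def brute_force_split(values, labels):
    """Independent minimizer: weighted Gini of every '>= c' split, computed
    from first principles; returns (weighted_impurity, cutpoint) with the
    smallest cutpoint among ties."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    n = len(values)
    best = (np.inf, None)
    for c in sorted(set(values))[1:]:
        left = values < c
        out = 0.0
        for side in (left, ~left):
            m = side.sum()
            p = labels[side].mean()
            out += m / n * (1 - p**2 - (1 - p) ** 2)
        if out < best[0] - 1e-12:
            best = (out, c)
    return best


class TestGini:
    @pytest.mark.parametrize("counts,expected", [((10, 0), 0.0), ((5, 5), 0.5), ((4, 1), 0.32)])
    def test_two_class_values(self, counts, expected):
        assert gini(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini((0, 0))


class TestBestSplit:
    def test_separable_classes_find_boundary(self):
        rule = best_split([150, 151, 152, 160, 161, 162], [0, 0, 0, 1, 1, 1])
        assert (rule.direction, rule.cutpoint) == ("ge", 160)
        assert rule.impurity_decrease == pytest.approx(0.5)
        assert not rule.uninformative

    def test_tie_broken_to_smallest_cutpoint(self):
        values = [148, 150, 152, 154, 153, 157, 159, 161]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        rule = best_split(values, labels)
        w, cut = brute_force_split(values, labels)
        assert w == pytest.approx(0.2)
        assert rule.cutpoint == cut == 153

    def test_interleaved_classes_flagged_uninformative(self):
        # classes perfectly balanced at every value: no split helps
        rule = best_split([1, 1, 2, 2, 3, 3], [1, 0, 1, 0, 1, 0])
        assert rule.impurity_decrease == pytest.approx(0.0, abs=1e-9)
        assert rule.uninformative

    def test_direction_follows_case_enrichment(self):
        # cases below the cut -> 'lt' rule (the LTI situation)
        rule = best_split([10, 11, 12, 18, 19, 20], [1, 1, 1, 0, 0, 0])
        assert rule.direction == "lt" and rule.cutpoint == 18

    def test_single_class_rejected(self):
        with pytest.raises(NoSplitError):
            best_split([1, 2, 3], [1, 1, 1])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            best_split([1.0, np.nan, 3.0], [0, 1, 1])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(130, 185), st.booleans()), min_size=4, max_size=50
        )
    )
    def test_matches_brute_force_oracle(self, data):
        values = [v for v, _ in data]
        labels = [l for _, l in data]
        if all(labels) or not any(labels) or len(set(values)) < 2:
            return
        rule = best_split(values, labels)
        w, cut = brute_force_split(values, labels)
        assert rule.cutpoint == cut

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(shift=st.integers(-40, 40))
    def test_shift_equivariance(self, shift):
        values = [148, 150, 152, 154, 153, 157, 159, 161]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        base = best_split(values, labels)
        shifted = best_split([v + shift for v in values], labels)
        assert shifted.cutpoint == base.cutpoint + shift
        assert shifted.direction == base.direction

    def test_negation_flips_direction(self):
        values = [150.0, 151, 152, 160, 161, 162]
        labels = [0, 0, 0, 1, 1, 1]
        assert best_split(values, labels).direction == "ge"
        assert best_split([-v for v in values], labels).direction == "lt"


class TestDeriveThresholds:
    def test_fully_separated_cohort(self):
        recs = [make_record(145, 20, 1, group="control") for _ in range(5)] + [
            make_record(165, 8, 8, group="OPI") for _ in range(5)
        ]
        rules = derive_thresholds(recs)
        assert rules["sulcus_angle"].cutpoint == 165 and rules["sulcus_angle"].direction == "ge"
        assert rules["lti"].cutpoint == 20 and rules["lti"].direction == "lt"
        assert rules["bump"].cutpoint == 8 and rules["bump"].direction == "ge"
        assert all(r.impurity_decrease > 0.49 for r in rules.values())

    def test_convex_knees_excluded_and_counted(self):
        recs = [make_record(145, 20, 1, group="control") for _ in range(5)]
        recs += [make_record(165, 8, 8, group="OPI") for _ in range(5)]
        recs += [make_record(None, None, 8, group="OPI") for _ in range(3)]
        rules = derive_thresholds(recs)
        assert rules["sulcus_angle"].n_excluded_unmeasurable == 3
        assert rules["sulcus_angle"].n_used == 10
        assert rules["bump"].n_excluded_unmeasurable == 0
        assert rules["bump"].n_used == 13

    def test_default_cohort_recovers_published_cutpoints(self):
        cohort = generate_cohort(CohortSpec(seed=20240101))
        rules = derive_thresholds(cohort)
        assert abs(rules["sulcus_angle"].cutpoint - 157) <= 5
        assert abs(rules["lti"].cutpoint - 14) <= 4
        assert abs(rules["bump"].cutpoint - 5) <= 2

    def test_shuffled_labels_are_uninformative(self):
        rng = np.random.default_rng(5)
        cohort = generate_cohort(CohortSpec(seed=7))
        groups = [r.group for r in cohort]
        rng.shuffle(groups)
        for r, g in zip(cohort, groups):
            r.group = g
        rules = derive_thresholds(cohort)
        for rule in rules.values():
            assert rule.impurity_decrease < 0.03

    def test_unlabeled_record_rejected(self):
        with pytest.raises(ValueError):
            derive_thresholds([make_record(group="unknown"), make_record(group="OPI")])


class TestEstimators:
    def test_single_split_classifier_fit_predict(self):
        X = np.array([[150], [151], [152], [160], [161], [162]])
        y = [0, 0, 0, 1, 1, 1]
        clf = SingleSplitClassifier().fit(X, y)
        assert clf.cutpoint_ == 160 and clf.direction_ == "ge"
        assert clf.predict([[159], [160]]).tolist() == [False, True]
        assert clf.get_params() == {"impurity": "gini"}

    def test_single_split_in_sklearn_cv(self):
        from sklearn.model_selection import cross_val_score

        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(149, 6, 60), rng.normal(160, 7, 60)])[:, None]
        y = np.repeat([False, True], 60)
        scores = cross_val_score(SingleSplitClassifier(), X, y, cv=3)
        assert scores.mean() > 0.7

    def test_dejour_classifier_published_cutpoints(self):
        clf = DejourClassifier().fit([])
        recs = [
            make_record(149, 17, 3),
            make_record(160, 11, 3),
            make_record(None, None, 4),
            make_record(163, 10, 7),
        ]
        assert clf.predict(recs).tolist() == [0, 1, 2, 3]
        assert clf.predict_dysplastic(recs).tolist() == [False, True, True, True]

    def test_dejour_classifier_refits_cutpoints_from_cohort(self):
        cohort = generate_cohort(CohortSpec(seed=99))
        clf = DejourClassifier(refit_cutpoints=True).fit(cohort)
        assert abs(clf.sulcus_cut_ - 157) <= 5
        assert abs(clf.lti_cut_ - 14) <= 4
        assert set(clf.predict(cohort)) <= {0, 1, 2, 3}
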