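"""Discrete-time survival encoding, likelihood, curves, cohort splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecgrisk as er
from ecgrisk.survival import SurvivalRecord, SurvivalTargets

YEARLY = er.IntervalGrid(np.arange(6) * 365.25)


class TestEncodeTargets:
    def test_death_mid_grid(self):
        # death at 2.5 y on a yearly 5-y grid
        t = er.encode_targets(SurvivalRecord("a", 2.5 * 365.25, 1), YEARLY)
        np.testing.assert_array_equal(t.y[0], [0, 0, 1, 0, 0])
        np.testing.assert_array_equal(t.mask[0], [1, 1, 1, 0, 0])

    def test_early_censoring_contributes_nothing(self):
        t = er.encode_targets(SurvivalRecord("a", 0.2 * 365.25, 0), YEARLY)
        assert t.y.sum() == 0 and t.mask.sum() == 0

    def test_death_single_interval_grid(self):
        g = er.IntervalGrid([0.0, 100.0])
        t = er.encode_targets(SurvivalRecord("a", 50.0, 1), g)
        np.testing.assert_array_equal(t.y[0], [1])
        np.testing.assert_array_equal(t.mask[0], [1])

    def test_censoring_at_interval_end_counts_full_interval(self):
        t = er.encode_targets(SurvivalRecord("a", 2 * 365.25, 0), YEARLY)
        np.testing.assert_array_equal(t.mask[0], [1, 1, 0, 0, 0])

    def test_event_beyond_horizon_treated_as_censored(self):
        t = er.encode_targets(SurvivalRecord("a", 10 * 365.25, 1), YEARLY)
        assert t.y.sum() == 0
        np.testing.assert_array_equal(t.mask[0], np.ones(5))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 3000.0), st.sampled_from([0, 1]))
    def test_mask_is_prefix_and_y_inside_mask(self, time, event):
        t = er.encode_targets(SurvivalRecord("a", time, event), YEARLY)
        m = t.mask[0]
        assert np.all(np.diff(m) <= 0)  # prefix: once 0, stays 0
        assert t.y.sum() <= 1
        assert np.all(t.y[0] <= m)


class TestDiscreteSurvivalLoss:
    def test_hand_computed_value(self):
        # h = (0.2, 0.3), death in interval 2: -ln(0.8) - ln(0.3)
        t = SurvivalTargets(np.array([[0.0, 1.0]]), np.array([[1.0, 1.0]]))
        loss = er.discrete_survival_loss(np.array([[0.2, 0.3]]), t)
        assert loss == pytest.approx(-np.log(0.8) - np.log(0.3), abs=1e-9)
        assert loss == pytest.approx(1.4271, abs=5e-4)

    def test_reduces_to_binary_cross_entropy_at_k1(self, rng):
        h = rng.uniform(0.05, 0.95, size=(20, 1))
        y = rng.integers(0, 2, size=(20, 1)).astype(float)
        t = SurvivalTargets(y, np.ones_like(y))
        bce = -(y * np.log(h) + (1 - y) * np.log(1 - h)).mean()
        assert er.discrete_survival_loss(h, t) == pytest.approx(bce, rel=1e-9)

    def test_perfect_prediction_limit(self):
        t = SurvivalTargets(np.array([[0.0, 1.0]]), np.array([[1.0, 1.0]]))
        h = np.array([[1e-9, 1.0 - 1e-9]])
        assert er.discrete_survival_loss(h, t) < 1e-5

    def test_boundary_hazards_clipped_not_infinite(self):
        t = SurvivalTargets(np.array([[1.0]]), np.array([[1.0]]))
        assert np.isfinite(er.discrete_survival_loss(np.array([[0.0]]), t))

    def test_total_equals_sum_of_per_record_losses(self, rng):
        # brute-force per-record oracle
        n, k = 17, 6
        h = rng.uniform(0.05, 0.95, size=(n, k))
        y = np.zeros((n, k))
        m = np.zeros((n, k))
        for i in range(n):
            j = rng.integers(0, k + 1)
            m[i, :j] = 1
            if j > 0 and rng.uniform() < 0.5:
                y[i, j - 1] = 1
        t = SurvivalTargets(y, m)
        per = np.empty(n)
        for i in range(n):
            acc = 0.0
            for j in range(k):
                if m[i, j]:
                    acc -= y[i, j] * np.log(h[i, j]) + (1 - y[i, j]) * np.log(1 - h[i, j])
            per[i] = acc
        assert er.discrete_survival_loss(h, t) == pytest.approx(per.mean(), rel=1e-12)
        np.testing.assert_allclose(er.discrete_survival_loss(h, t, reduce=False), per)

    def test_negative_loss_exponentiates_to_likelihood(self):
        # single record, death in interval 2 of 3 with hazards h:
        # exp(-loss) == (1-h1) * h2 under the discrete model
        h = np.array([[0.1, 0.4, 0.2]])
        t = SurvivalTargets(np.array([[0.0, 1.0, 0.0]]), np.array([[1.0, 1.0, 0.0]]))
        lik = np.exp(-er.discrete_survival_loss(h, t))
        assert lik == pytest.approx(0.9 * 0.4, rel=1e-9)


class TestHazardsToSurvival:
    def test_hand_computed_curve_and_risk(self):
        s, risk = er.hazards_to_survival(np.array([0.2, 0.3]))
        np.testing.assert_allclose(s, [0.8, 0.56])
        assert risk == pytest.approx(-np.log(0.56), rel=1e-9)

    def test_zero_hazard_survival_one(self):
        s, risk = er.hazards_to_survival(np.zeros(4))
        np.testing.assert_array_equal(s, np.ones(4))
        assert risk == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_survival_non_increasing(self, seed):
        h = np.random.default_rng(seed).uniform(0, 1, size=(3, 8))
        s, _ = er.hazards_to_survival(h)
        assert np.all(np.diff(s, axis=1) <= 1e-12)

    def test_risk_ranking_equals_final_survival_ranking(self, rng):
        h = rng.uniform(0.01, 0.6, size=(30, 10))
        s, risk = er.hazards_to_survival(h)
        assert np.array_equal(np.argsort(risk), np.argsort(-s[:, -1]))


class TestPrepareCohort:
    @staticmethod
    def _records(n, rng, frac_short=0.0):
        recs = []
        for i in range(n):
            if rng.uniform() < frac_short:
                recs.append(SurvivalRecord(f"s{i}", rng.uniform(0, 29), 0))
            else:
                recs.append(SurvivalRecord(f"s{i}", rng.uniform(40, 3000),
                                           int(rng.uniform() < 0.3)))
        return recs

    def test_short_censored_followup_excluded(self, rng):
        recs = [SurvivalRecord("keep_event", 10.0, 1),
                SurvivalRecord("drop", 10.0, 0)] + self._records(30, rng)
        splits = er.prepare_cohort(recs, seed=0)
        assert 0 in splits.kept  # a day-10 death is still informative
        assert 1 not in splits.kept  # censored day 10: 30-day status unknown

    def test_split_ratio_50_10_40(self, rng):
        recs = self._records(100, rng)
        splits = er.prepare_cohort(recs, seed=0)
        assert len(splits.train) + len(splits.val) + len(splits.test) == 100
        assert abs(len(splits.train) - 50) <= 2
        assert abs(len(splits.val) - 10) <= 2
        assert abs(len(splits.test) - 40) <= 2

    def test_subjects_never_span_splits(self, rng):
        # two records per subject
        recs = []
        for i in range(40):
            t = rng.uniform(40, 3000)
            recs.append(SurvivalRecord(f"s{i}", t, 0))
            recs.append(SurvivalRecord(f"s{i}", t + 1, 0))
        splits = er.prepare_cohort(recs, seed=1)
        for part in (splits.train, splits.val, splits.test):
            ids = {recs[i].subject_id for i in part}
            for other in (splits.train, splits.val, splits.test):
                if other is not part:
                    assert ids.isdisjoint({recs[i].subject_id for i in other})

    def test_deterministic_given_seed(self, rng):
        recs = self._records(60, rng)
        a = er.prepare_cohort(recs, seed=5)
        b = er.prepare_cohort(recs, seed=5)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.test, b.test)

    def test_tiny_cohort_rejected(self):
        recs = [SurvivalRecord("a", 100.0, 0), SurvivalRecord("b", 100.0, 0)]
        with pytest.raises(ValueError, match="subjects"):
            er.prepare_cohort(recs, seed=0)


class TestIntervalGrid:
    def test_half_year_default(self):
        g = er.IntervalGrid.half_years(10)
        assert g.n_intervals == 10
        assert g.horizon == pytest.approx(5 * 365.25)

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            er.IntervalGrid([0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            er.IntervalGrid([1.0, 2.0])
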