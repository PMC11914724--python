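"""Fidelity metrics and the censoring-aware concordance index."""

import numpy as np
import pytest

import ecgrisk as er
from ecgrisk.digitize import DigitizedECG
from ecgrisk.metrics import MetricResult, lead_fidelity


def _as_digitized(samples, mask=None):
    samples = np.atleast_2d(samples)
    if mask is None:
        mask = np.ones_like(samples, dtype=np.int8)
    names = er.LEAD_NAMES[: samples.shape[0]]
    return DigitizedECG(samples, mask, fs=400.0, lead_names=names)


class TestFidelityMetrics:
    def test_identical_signals_perfect(self, rng):
        x = rng.normal(size=(12, 400))
        ref = er.ECGSignal(x, 400.0)
        rep = er.fidelity_metrics(ref, _as_digitized(x.copy()))
        np.testing.assert_allclose(rep.r_values, 1.0)
        assert rep.mean_mae == 0.0

    def test_constant_offset_preserves_r(self, rng):
        x = rng.normal(size=(12, 400))
        ref = er.ECGSignal(x, 400.0)
        rep = er.fidelity_metrics(ref, _as_digitized(x + 0.05))
        np.testing.assert_allclose(rep.r_values, 1.0, atol=1e-12)
        assert rep.mean_mae == pytest.approx(0.05)

    def test_negated_signal_anticorrelated(self, rng):
        x = rng.normal(size=(12, 400))
        rep = er.fidelity_metrics(er.ECGSignal(x, 400.0), _as_digitized(-x))
        np.testing.assert_allclose(rep.r_values, -1.0, atol=1e-12)

    def test_constant_lead_excluded_and_counted(self, rng):
        x = rng.normal(size=(12, 400))
        rec = x.copy()
        rec[3] = 0.7  # zero-variance recovery: r undefined there
        rep = er.fidelity_metrics(er.ECGSignal(x, 400.0), _as_digitized(rec))
        assert rep.n_excluded_leads == 1
        assert rep.r_values.size == 11

    def test_comparison_restricted_to_mask(self, rng):
        x = rng.normal(size=(1, 400))
        rec = x.copy()
        rec[0, 200:] = 99.0  # garbage outside the mask must not matter
        mask = np.ones_like(x, dtype=np.int8)
        mask[0, 200:] = 0
        rep = er.fidelity_metrics(er.ECGSignal(x, 400.0, ("I",)), _as_digitized(rec, mask))
        assert rep.mean_mae == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lead_fidelity(np.zeros(5), np.zeros(6))


class TestConcordanceIndex:
    def test_perfect_ordering(self):
        res = er.concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1], n_bootstrap=10)
        assert res.estimate == 1.0

    def test_all_tied_risks(self):
        res = er.concordance_index([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1],
                                   n_bootstrap=10)
        assert res.estimate == 0.5

    def test_agrees_with_pair_enumeration_oracle(self, rng):
        n = 50
        risk = rng.normal(size=n)
        time = rng.uniform(0, 100, size=n)
        event = rng.integers(0, 2, size=n)
        event[0] = 1  # ensure at least one comparable pair
        conc = comp = 0.0
        for i in range(n):
            for j in range(n):
                if time[i] < time[j] and event[i] == 1:
                    comp += 1
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        conc += 0.5
        res = er.concordance_index(risk, time, event, n_bootstrap=10)
        assert res.estimate == pytest.approx(conc / comp, abs=1e-12)

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines.utils")
        n = 80
        risk = rng.normal(size=n)
        time = rng.uniform(0, 100, size=n)  # continuous: no ties
        event = rng.integers(0, 2, size=n)
        event[:5] = 1
        ours = er.concordance_index(risk, time, event, n_bootstrap=10).estimate
        theirs = lifelines.concordance_index(time, -risk, event)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            er.concordance_index([1, 2], [5, 5], [0, 0], n_bootstrap=10)

    def test_ci_brackets_estimate(self, rng):
        n = 60
        res = er.concordance_index(rng.normal(size=n), rng.uniform(1, 9, n),
                                   rng.integers(0, 2, n), n_bootstrap=100, seed=3)
        assert res.ci_lower <= res.estimate <= res.ci_upper

    def test_bootstrap_ci_covers_known_concordance(self, rng):
        # risk = -time + noise gives a stable population concordance; the
        # 95% CI should cover the large-sample value in most replicates
        big_t = rng.uniform(0, 100, size=4000)
        big_r = -big_t + rng.normal(0, 30, size=4000)
        pop = er.concordance_index(big_r, big_t, np.ones(4000, dtype=int),
                                   n_bootstrap=2).estimate
        hits = 0
        for rep in range(50):
            t = rng.uniform(0, 100, size=80)
            r = -t + rng.normal(0, 30, size=80)
            res = er.concordance_index(r, t, np.ones(80, dtype=int),
                                       n_bootstrap=100, seed=rep)
            hits += res.ci_lower <= pop <= res.ci_upper
        assert hits >= 45  # loose coverage sanity check (>=90%)

    def test_metric_result_invariant(self):
        with pytest.raises(ValueError):
            MetricResult(0.9, 0.95, 0.99, 10, 0)


class TestRoundtripBenchmark:
    def test_small_benchmark_runs_and_reports(self):
        rep = er.roundtrip_benchmark(n=2, seed=42)
        assert rep.n_records == 2
        assert rep.r_values.size == 24
        assert rep.n_failed_records == 0
        assert rep.median_r > 0.9

    def test_deterministic_given_seed(self):
        a = er.roundtrip_benchmark(n=1, seed=9)
        b = er.roundtrip_benchmark(n=1, seed=9)
        np.testing.assert_array_equal(a.r_values, b.r_values)
        np.testing.assert_array_equal(a.mae_values, b.mae_values)

    def test_grid_off_close_to_grid_on(self):
        on = er.roundtrip_benchmark(n=3, seed=6)
        off = er.roundtrip_benchmark(n=3, seed=6, style=er.RenderStyle(grid=False))
        assert abs(on.median_r - off.median_r) < 0.02

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            er.roundtrip_benchmark(n=0)
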