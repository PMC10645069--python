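import math

import numpy as np
import pytest
from scipy import stats

from repliscope import metrics
from repliscope.dataset import StatisticsReport
from repliscope.effects import EffectEstimate
from repliscope.errors import DomainError, ScaleMismatchError

from conftest import make_pair


def est(value, se, scale="smd"):
    return EffectEstimate(
        estimate=value, se=se, scale=scale, p_value=0.5, n_total=100, source="t_between"
    )


class TestPredictionInterval:
    def test_symmetric_unit_case(self):
        lo, hi = metrics.prediction_interval(est(0.0, 1.0), 1.0, 0.95)
        expected = stats.norm.ppf(0.975) * math.sqrt(2.0)
        assert lo == pytest.approx(-expected, abs=1e-9)
        assert hi == pytest.approx(expected, abs=1e-9)

    def test_zero_replication_se_limit(self):
        lo, hi = metrics.prediction_interval(est(0.3, 0.1), 0.0, 0.95)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(0.3 - z * 0.1)
        assert hi == pytest.approx(0.3 + z * 0.1)

    def test_bad_level_rejected(self):
        with pytest.raises(DomainError):
            metrics.prediction_interval(est(0, 1), 1.0, 1.5)


class TestPOrig:
    def test_identical_estimates(self):
        assert metrics.p_orig(est(0.4, 0.1), est(0.4, 0.2)) == 1.0

    def test_quantile_case(self):
        se_o, se_r = 0.15, 0.25
        delta = 1.96 * math.sqrt(se_o**2 + se_r**2)
        p = metrics.p_orig(est(0.0, se_o), est(delta, se_r), tau=0.0)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_strictly_increasing_in_tau(self):
        o, r = est(0.8, 0.1), est(0.1, 0.12)
        values = [metrics.p_orig(o, r, tau) for tau in np.linspace(0, 0.21, 8)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_symmetric_and_sign_flip_invariant(self):
        o, r = est(0.7, 0.11), est(0.2, 0.23)
        assert metrics.p_orig(o, r) == pytest.approx(metrics.p_orig(r, o), abs=1e-15)
        assert metrics.p_orig(o, r) == pytest.approx(
            metrics.p_orig(est(-0.7, 0.11), est(-0.2, 0.23)), abs=1e-15
        )

    def test_scale_mismatch_rejected(self):
        with pytest.raises(ScaleMismatchError):
            metrics.p_orig(est(0.4, 0.1), est(0.4, 0.1, scale="log_odds"))

    def test_nonzero_tau_requires_smd(self):
        o = est(0.4, 0.1, scale="log_odds")
        r = est(0.2, 0.1, scale="log_odds")
        assert metrics.p_orig(o, r, tau=0.0) > 0
        with pytest.raises(ScaleMismatchError):
            metrics.p_orig(o, r, tau=0.21)


class TestConsistency:
    def test_boundary_pair_rescued_by_tau(self):
        se_o = se_r = 0.1
        delta = 2.2 * math.sqrt(se_o**2 + se_r**2)  # significant at tau=0
        o, r = est(0.0, se_o), est(delta, se_r)
        assert metrics.p_orig(o, r, 0.0) < 0.05
        assert delta < 1.96 * math.sqrt(0.21**2 + se_o**2 + se_r**2)
        assert metrics.consistency_at_tau(o, r, tau=0.21)

    def test_identical_consistent_at_every_tau(self):
        o = r = est(0.5, 0.1)
        for tau in (0.0, 0.1, 0.21, 1.0):
            assert metrics.consistency_at_tau(o, r, tau=tau)

    def test_cohort_fraction_monotone_in_tau(self, rng):
        pairs = [
            (est(float(rng.normal(0.5, 0.4)), 0.12), est(float(rng.normal(0.2, 0.4)), 0.15))
            for _ in range(200)
        ]
        at_zero = sum(metrics.p_orig(o, r, 0.0) >= 0.05 for o, r in pairs)
        at_tau = sum(metrics.consistency_at_tau(o, r, 0.21) for o, r in pairs)
        assert at_tau >= at_zero


class TestDuality:
    def test_pi_membership_iff_p_orig_above_alpha(self, rng):
        """Exact duality on 1,000 random pairs: replication inside the 95%
        PI <=> p_orig(tau=0) >= 0.05 (the same z statistic both ways)."""
        for _ in range(1000):
            o = est(float(rng.normal(0, 1)), float(rng.uniform(0.02, 1)))
            r = est(float(rng.normal(0, 1)), float(rng.uniform(0.02, 1)))
            lo, hi = metrics.prediction_interval(o, r.se, 0.95)
            inside = lo <= r.estimate <= hi
            assert inside == (metrics.p_orig(o, r, 0.0) >= 0.05)


class TestScoreToOrdinal:
    @pytest.mark.parametrize(
        "score,level", [(0.0, 1), (0.25, 2), (0.5, 3), (0.75, 4), (1.0, 5)]
    )
    def test_grid_mapping(self, score, level):
        assert metrics.score_to_ordinal(score) == level

    def test_off_grid_rejected(self):
        with pytest.raises(DomainError):
            metrics.score_to_ordinal(0.4)


class TestComputePairMetrics:
    def test_no_statistics_still_gets_ordinal(self):
        pair = make_pair(
            original_stats=StatisticsReport(test_type="none"),
            replication_stats=StatisticsReport(test_type="none"),
        )
        m = metrics.compute_pair_metrics(pair)
        assert not m.available
        assert m.ordinal_score == 4
        assert m.p_orig is None

    def test_exact_replica_large_n(self):
        stats_report = StatisticsReport(test_type="t_between", statistic=5.0, n1=5000, n2=5000)
        pair = make_pair(original_stats=stats_report, replication_stats=stats_report)
        m = metrics.compute_pair_metrics(pair)
        assert m.available and m.in_interval
        assert m.p_orig == pytest.approx(1.0)

    def test_null_replication_tiny_se(self):
        pair = make_pair(
            original_stats=StatisticsReport(test_type="t_between", statistic=50.0, n1=5000, n2=5000),
            replication_stats=StatisticsReport(test_type="t_between", statistic=0.0, n1=5000, n2=5000),
        )
        m = metrics.compute_pair_metrics(pair)
        assert m.available and not m.in_interval
        assert m.p_orig < 1e-6

    def test_scale_mismatch_marks_unavailable(self):
        pair = make_pair(
            replication_stats=StatisticsReport(
                test_type="proportions", success1=10, total1=20, success2=5, total2=20
            )
        )
        m = metrics.compute_pair_metrics(pair)
        assert not m.available

    def test_non_smd_shared_scale_has_no_tau_flag(self):
        report = StatisticsReport(
            test_type="proportions", success1=12, total1=20, success2=6, total2=20
        )
        pair = make_pair(original_stats=report, replication_stats=report)
        m = metrics.compute_pair_metrics(pair)
        assert m.available
        assert m.consistent_at_tau is None  # tau defined in SMD units only


class TestCohortSummary:
    def test_counts_and_rates(self, synthetic_pairs):
        pairs, _ = synthetic_pairs
        per_pair = [metrics.compute_pair_metrics(p) for p in pairs]
        summary = metrics.cohort_summary(per_pair)
        assert summary["n_total"] == len(pairs)
        assert summary["n_with_metrics"] <= summary["n_total"]
        assert summary["n_smd"] <= summary["n_with_metrics"]
        assert 0 <= summary["rate_in_interval"] <= 1
        assert 0 < summary["median_p_orig"] <= 1

    def test_coverage_calibration_small(self):
        from repliscope.synth import coverage_experiment

        out = coverage_experiment(2000, tau=0.0, seed=7)
        assert 0.93 <= out["coverage"] <= 0.97
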