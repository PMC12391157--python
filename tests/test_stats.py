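import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pahemo.stats import (
    bh_adjust,
    dichotomize_by_median_time,
    exclude_interscan_pvr,
    fit_cox,
    fit_linear_outcome,
    km_curve,
    roc_optimal_cutoff,
)
from pahemo.synthetic import CohortSpec, make_synthetic_cohort


class TestLinearFit:
    def test_recovers_generating_coefficient(self):
        true = -4.74
        spec = CohortSpec(
            n_patients=500,
            linear_effects={"wss_steady_avg": true},
            noise_sd=10.0,
            seed=42,
        )
        cohort, _ = make_synthetic_cohort(spec)
        res = fit_linear_outcome(cohort, "RVEDVi", "wss_steady_avg")
        assert abs(res.effect_estimate - true) <= 2 * res.std_error

    def test_null_rejection_rate_near_nominal(self):
        # a predictor with no effect should reject at ~alpha = 0.05
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            spec = CohortSpec(n_patients=60, noise_sd=10.0, seed=3000 + rep)
            cohort, _ = make_synthetic_cohort(spec)
            res = fit_linear_outcome(cohort, "RVEDVi", "osi_avg")
            rejections += res.unadjusted_p < 0.05
        rate = rejections / n_rep
        assert 0.01 <= rate <= 0.10

    def test_collinear_design_names_columns(self):
        spec = CohortSpec(n_patients=100, seed=1)
        cohort, _ = make_synthetic_cohort(spec)
        cohort["dup"] = cohort["age_at_cmr1"]
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_outcome(cohort, "RVEDVi", "dup")

    def test_constant_predictor_rejected(self):
        spec = CohortSpec(n_patients=50, seed=2)
        cohort, _ = make_synthetic_cohort(spec)
        cohort["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_linear_outcome(cohort, "RVEDVi", "flat")


class TestBHAdjust:
    def test_hand_worked_example(self):
        # min over j >= i of p(j) * m / j
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_preserves_order_of_evidence(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, 25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_reference_implementation_on_random_vectors(self):
        # cross-check against statsmodels' BH on 1,000 random p-vectors
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(1e-6, 1.0, m)
            ours = bh_adjust(p)
            _, theirs, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_false_discovery_rate_controlled_under_global_null(self):
        # all-null batches: probability of any BH discovery <= q = 0.05
        rng = np.random.default_rng(11)
        any_discovery = 0
        n_rep = 200
        for _ in range(n_rep):
            p = rng.uniform(0, 1, 36)
            any_discovery += (bh_adjust(np.clip(p, 1e-12, 1)) < 0.05).any()
        assert any_discovery / n_rep <= 0.08

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCox:
    def test_recovers_generating_log_hazard(self):
        true = 0.7
        spec = CohortSpec(
            n_patients=500,
            log_hazards={"osi_avg": true / 0.03},  # per-unit on the OSI scale
            censoring_rate=0.3,
            seed=8,
        )
        _, surv = make_synthetic_cohort(spec)
        res = fit_cox(surv, "osi_avg")
        assert abs(res.coefficient - true / 0.03) <= 2 * res.std_error

    def test_normalized_fit_is_reparameterization(self):
        spec = CohortSpec(
            n_patients=300, log_hazards={"wss_steady_avg": -0.3}, seed=9
        )
        _, surv = make_synthetic_cohort(spec)
        raw = fit_cox(surv, "wss_steady_avg", normalize=False)
        per_sd = fit_cox(surv, "wss_steady_avg", normalize=True)
        assert per_sd.coefficient == pytest.approx(
            raw.coefficient * raw.predictor_sd, rel=1e-6
        )
        assert per_sd.normalized and not raw.normalized

    def test_confidence_interval_brackets_hazard_ratio(self):
        spec = CohortSpec(n_patients=200, seed=10)
        _, surv = make_synthetic_cohort(spec)
        res = fit_cox(surv, "wss_steady_avg")
        assert res.ci_low <= res.hazard_ratio <= res.ci_high
        assert res.ci_low > 0

    def test_zero_events_rejected(self):
        spec = CohortSpec(n_patients=50, seed=12)
        _, surv = make_synthetic_cohort(spec)
        surv["event"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_cox(surv, "wss_steady_avg")


class TestDichotomization:
    def test_hand_worked_labels(self):
        records = pd.DataFrame(
            {
                "time_to_event": [100, 200, 300, 250, 150],
                "event": [1, 1, 1, 0, 0],
            }
        )
        # events at 100, 200, 300: median event time 200
        labels = dichotomize_by_median_time(records)
        assert labels.loc[0] == 1 and labels.loc[1] == 1
        assert labels.loc[2] == 0  # event after the median: survived past it
        assert labels.loc[3] == 0  # censored beyond the median
        assert 4 not in labels.index  # censored before the median: unknown

    def test_all_censored_rejected(self):
        records = pd.DataFrame({"time_to_event": [10, 20], "event": [0, 0]})
        with pytest.raises(ValueError):
            dichotomize_by_median_time(records)


class TestROCCutoff:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        cut, sens, spec, direction = roc_optimal_cutoff(scores, labels)
        assert sens + spec == pytest.approx(2.0)
        assert 3.0 < cut < 10.0

    def test_direction_flips_for_protective_scores(self):
        # low score predicts the event (as with protective wall shear)
        scores = np.array([10.0, 11.0, 12.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        cut, sens, spec, direction = roc_optimal_cutoff(scores, labels)
        assert direction == "<="
        assert sens + spec == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = rng.integers(6, 40)
            scores = np.round(rng.normal(size=n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            cut, sens, spec, direction = roc_optimal_cutoff(scores, labels)
            # oracle: scan every threshold on a fine grid, both directions
            grid = np.concatenate(
                [np.unique(scores) - 1e-9, np.unique(scores) + 1e-9]
            )
            pos = labels == 1
            best = -np.inf
            for c in grid:
                for ge in (True, False):
                    pred = scores >= c if ge else scores <= c
                    j = (pred & pos).sum() / pos.sum() + (
                        (~pred & ~pos).sum() / (~pos).sum()
                    )
                    best = max(best, j)
            assert sens + spec == pytest.approx(best, abs=1e-12)

    def test_tie_returns_smallest_cutoff(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        cut, sens, spec, direction = roc_optimal_cutoff(scores, labels)
        candidates = [1.5, 2.5, 3.5]
        ties = []
        pos = labels == 1
        for c in candidates:
            pred = scores <= c
            ties.append(
                ((pred & pos).sum() / 2 + ((~pred) & ~pos).sum() / 2, c)
            )
        best_j = max(t[0] for t in ties)
        smallest = min(c for j, c in ties if j == best_j)
        assert cut == pytest.approx(smallest)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_optimal_cutoff([1.0, 2.0], [1, 1])


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        records = pd.DataFrame(
            {"time_to_event": [5.0, 8.0, 9.0], "event": [0, 0, 0]}
        )
        curves = km_curve(records, np.zeros(3, dtype=int))
        assert np.all(curves["0"]["survival"] == 1.0)

    def test_hand_product_limit_example(self):
        # 5 subjects: events at t=1 and t=3, censored at t=2, 4, 5
        records = pd.DataFrame(
            {"time_to_event": [1.0, 3.0, 2.0, 4.0, 5.0], "event": [1, 1, 0, 0, 0]}
        )
        curves = km_curve(records, np.zeros(5, dtype=int))
        df = curves["0"].set_index("time")["survival"]
        assert df.loc[1.0] == pytest.approx(0.8)
        assert df.loc[3.0] == pytest.approx(0.8 * (1 - 1 / 3), rel=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_survival_is_monotone_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        records = pd.DataFrame(
            {
                "time_to_event": rng.exponential(10, n) + 0.1,
                "event": rng.integers(0, 2, n),
            }
        )
        curves = km_curve(records, np.zeros(n, dtype=int))
        s = curves["0"]["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))


class TestExclusions:
    def test_interscan_pvr_filtered_with_audit(self):
        cohort = pd.DataFrame(
            {"RVEDVi": [1.0, 2.0, 3.0], "pvr_between_scans": [0, 1, 0]}
        )
        out, audit = exclude_interscan_pvr(cohort)
        assert len(out) == 2
        assert audit["excluded"] == 1
        assert audit["excluded_index"] == [1]
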