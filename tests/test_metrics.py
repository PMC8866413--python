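"""Evaluation battery: DeLong AUC, reclassification/NRI, IDI, calibration
deciles, percentile hazard ratios, subgroup AUCs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import coxrisk as cr
from coxrisk.exceptions import CoxRiskError, SchemaError
from coxrisk.metrics import (
    NRIResult,
    ReclassificationTable,
    km_by_band,
    km_incidence,
)
from conftest import brute_force_auc


class TestDelongAUC:
    def test_perfect_separation_gives_one(self):
        event = np.array([0, 0, 0, 1, 1], dtype=float)
        risk = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert cr.auc_delong(risk, event).estimate == 1.0

    def test_all_ties_give_half(self):
        event = np.array([0, 1, 0, 1], dtype=float)
        risk = np.full(4, 0.2)
        assert cr.auc_delong(risk, event).estimate == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        event = (rng.random(n) < 0.4).astype(float)
        event[:2] = [0.0, 1.0]  # both classes guaranteed
        risk = np.round(rng.random(n), 2)  # force some ties
        rep = cr.auc_delong(risk, event)
        assert rep.estimate == pytest.approx(brute_force_auc(risk, event),
                                             abs=1e-12)
        assert rep.ci_low <= rep.estimate <= rep.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(SchemaError):
            cr.auc_delong(np.array([0.1, 0.2]), np.array([1.0, 1.0]))


class TestDelongComparison:
    def test_identical_scores_give_zero_delta_and_p_one(self, toy_scores):
        old, _, event = toy_scores
        rep = cr.auc_compare(old, old, event)
        assert rep.estimate == 0.0
        assert rep.p_value == 1.0

    def test_monotone_transform_gives_zero_delta(self, toy_scores):
        old, _, event = toy_scores
        rep = cr.auc_compare(old, np.log(old / (1 - old)), event)
        assert rep.estimate == pytest.approx(0.0, abs=1e-15)

    def test_delta_equals_difference_of_pair_count_aucs(self, toy_scores):
        old, new, event = toy_scores
        rep = cr.auc_compare(new, old, event)
        expected = brute_force_auc(new, event) - brute_force_auc(old, event)
        assert rep.estimate == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            cr.auc_compare(np.ones(3), np.ones(4), np.array([0, 1, 0], float))


class TestReclassification:
    def test_identical_models_move_nobody(self, toy_scores):
        old, _, event = toy_scores
        table = cr.reclassification(old, old, event, 0.075)
        assert table.case_up == table.case_down == 0
        assert table.noncase_up == table.noncase_down == 0

    def test_six_person_hand_cross_tab(self):
        # cases: (0.05->0.10) up, (0.10->0.05) down, (0.10->0.12) both high
        # non-cases: (0.02->0.03) both low, (0.06->0.09) up, (0.09->0.02) down
        old = np.array([0.05, 0.10, 0.10, 0.02, 0.06, 0.09])
        new = np.array([0.10, 0.05, 0.12, 0.03, 0.09, 0.02])
        event = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        t = cr.reclassification(old, new, event, 0.075)
        assert (t.case_up, t.case_down, t.case_both_high, t.case_both_low) == \
            (1, 1, 1, 0)
        assert (t.noncase_up, t.noncase_down, t.noncase_both_high,
                t.noncase_both_low) == (1, 1, 0, 1)

    def test_threshold_boundary_uses_closed_lower_bound(self):
        old = np.array([0.074, 0.075])
        new = np.array([0.075, 0.074])
        event = np.array([1.0, 0.0])
        t = cr.reclassification(old, new, event, 0.075)
        assert t.case_up == 1       # reached exactly the threshold
        assert t.noncase_down == 1  # fell just below it

    def test_tiny_threshold_puts_everyone_both_high(self, toy_scores):
        old, new, event = toy_scores
        t = cr.reclassification(old, new, event, 1e-9)
        assert t.case_both_high == t.n_cases
        assert t.noncase_both_high == t.n_noncases

    def test_frame_layout_percentages_sum_to_100(self, toy_scores):
        old, new, event = toy_scores
        frame = cr.reclassification(old, new, event, 0.075).to_frame()
        pct_cols = [c for c in frame.columns if c.endswith("_pct")]
        np.testing.assert_allclose(frame[pct_cols].sum(axis=1), 100.0)


def _random_table(rng):
    c = rng.integers(0, 50, size=4)
    n = rng.integers(0, 500, size=4)
    if c.sum() == 0:
        c[0] = 1
    if n.sum() == 0:
        n[0] = 1
    return ReclassificationTable(
        threshold=0.075,
        case_up=int(c[0]), case_down=int(c[1]),
        case_both_high=int(c[2]), case_both_low=int(c[3]),
        noncase_up=int(n[0]), noncase_down=int(n[1]),
        noncase_both_high=int(n[2]), noncase_both_low=int(n[3]),
    )


class TestCategoricalNRI:
    def test_symmetric_table_gives_zero(self):
        t = ReclassificationTable(
            threshold=0.075, case_up=5, case_down=5, case_both_high=3,
            case_both_low=10, noncase_up=7, noncase_down=7,
            noncase_both_high=2, noncase_both_low=30,
        )
        res = cr.categorical_nri(t)
        assert res.event_nri == res.nonevent_nri == res.overall_nri == 0.0

    def test_component_arithmetic_on_known_counts(self):
        # 428 of 4469 cases up, 221 down -> event NRI 100*207/4469
        t = ReclassificationTable(
            threshold=0.075, case_up=428, case_down=221, case_both_high=320,
            case_both_low=3500, noncase_up=5463, noncase_down=3864,
            noncase_both_high=3110, noncase_both_low=225_781,
        )
        res = cr.categorical_nri(t)
        assert res.event_nri == pytest.approx(100 * 207 / 4469)
        assert res.nonevent_nri == pytest.approx(100 * -1599 / 238_218)
        assert res.overall_nri == res.event_nri + res.nonevent_nri

    def test_antisymmetry_under_model_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = _random_table(rng)
            swapped = ReclassificationTable(
                threshold=t.threshold,
                case_up=t.case_down, case_down=t.case_up,
                case_both_high=t.case_both_high, case_both_low=t.case_both_low,
                noncase_up=t.noncase_down, noncase_down=t.noncase_up,
                noncase_both_high=t.noncase_both_high,
                noncase_both_low=t.noncase_both_low,
            )
            a, b = cr.categorical_nri(t), cr.categorical_nri(swapped)
            assert a.event_nri == pytest.approx(-b.event_nri)
            assert a.nonevent_nri == pytest.approx(-b.nonevent_nri)
            assert a.overall_nri == pytest.approx(-b.overall_nri)

    def test_zero_denominator_rejected(self):
        t = ReclassificationTable(
            threshold=0.075, case_up=0, case_down=0, case_both_high=0,
            case_both_low=0, noncase_up=1, noncase_down=0,
            noncase_both_high=0, noncase_both_low=1,
        )
        with pytest.raises(SchemaError):
            cr.categorical_nri(t)

    def test_overall_must_equal_sum_of_components(self):
        with pytest.raises(CoxRiskError):
            NRIResult(event_nri=1.0, nonevent_nri=1.0, overall_nri=3.0)


class TestBootstrapNRI:
    def test_degenerate_data_gives_zero_width_ci(self):
        # every case moves up, every non-case stays: all resamples identical
        old = np.array([0.05] * 10 + [0.02] * 20)
        new = np.array([0.10] * 10 + [0.02] * 20)
        event = np.array([1.0] * 10 + [0.0] * 20)
        res = cr.nri_bootstrap_ci(old, new, event, 0.075, n_reps=50, seed=0)
        assert res.event_ci == (100.0, 100.0)
        assert res.nonevent_ci == (0.0, 0.0)
        assert res.overall_ci == (100.0, 100.0)

    def test_same_seed_reproduces_cis(self, toy_scores):
        old, new, event = toy_scores
        a = cr.nri_bootstrap_ci(old, new, event, 0.1, n_reps=100, seed=42)
        b = cr.nri_bootstrap_ci(old, new, event, 0.1, n_reps=100, seed=42)
        assert a == b

    def test_point_estimates_come_from_full_sample(self, toy_scores):
        old, new, event = toy_scores
        res = cr.nri_bootstrap_ci(old, new, event, 0.1, n_reps=20, seed=3)
        point = cr.categorical_nri(cr.reclassification(old, new, event, 0.1))
        assert res.event_nri == point.event_nri
        assert res.overall_nri == point.overall_nri

    def test_unstratified_mode_redraws_caseless_resamples(self):
        old = np.array([0.05, 0.02, 0.02, 0.02])
        new = np.array([0.10, 0.02, 0.02, 0.02])
        event = np.array([1.0, 0.0, 0.0, 0.0])
        res = cr.nri_bootstrap_ci(old, new, event, 0.075, n_reps=200, seed=1,
                                  stratified=False)
        assert res.n_redrawn > 0  # caseless draws happen and are redrawn
        assert res.n_bootstrap == 200


class TestContinuousNRIandIDI:
    def test_identical_models_give_zero(self, toy_scores):
        old, _, event = toy_scores
        assert cr.continuous_nri(old, old, event).estimate == 0.0
        assert cr.idi(old, old, event).estimate == 0.0

    def test_uniform_shift_cancels(self, toy_scores):
        old, _, event = toy_scores
        shifted = old + 1e-3
        assert cr.continuous_nri(old, shifted, event).estimate == \
            pytest.approx(0.0)
        assert cr.idi(old, shifted, event).estimate == pytest.approx(0.0)

    def test_ten_person_hand_count(self):
        # cases: up, up, down, tie  -> (3up? no: 2 up, 1 down, 1 tie)/4
        old = np.array([0.1, 0.2, 0.3, 0.4, 0.1, 0.1, 0.2, 0.2, 0.3, 0.3])
        new = np.array([0.2, 0.3, 0.2, 0.4, 0.2, 0.05, 0.2, 0.1, 0.4, 0.3])
        event = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=float)
        rep = cr.continuous_nri(old, new, event)
        # cases: +1 +1 -1 0 -> mean 0.25; non-cases: +1 -1 0 -1 +1 0 -> mean 0
        assert rep.estimate == pytest.approx(100 * 0.25)

    def test_idi_perfect_new_model_constant_old(self):
        event = np.array([1, 1, 0, 0], dtype=float)
        new = np.array([1.0, 1.0, 0.0, 0.0])
        old = np.full(4, 0.3)
        assert cr.idi(old, new, event).estimate == pytest.approx(1.0)

    def test_idi_equals_hand_computed_slope_difference(self):
        old = np.array([0.2, 0.4, 0.1, 0.3])
        new = np.array([0.5, 0.7, 0.1, 0.2])
        event = np.array([1, 1, 0, 0], dtype=float)
        slope_new = (0.5 + 0.7) / 2 - (0.1 + 0.2) / 2
        slope_old = (0.2 + 0.4) / 2 - (0.1 + 0.3) / 2
        assert cr.idi(old, new, event).estimate == pytest.approx(
            slope_new - slope_old)

    def test_permutation_invariance(self, toy_scores):
        old, new, event = toy_scores
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(old))
        assert cr.continuous_nri(old[perm], new[perm], event[perm]).estimate \
            == pytest.approx(cr.continuous_nri(old, new, event).estimate)
        assert cr.idi(old[perm], new[perm], event[perm]).estimate == \
            pytest.approx(cr.idi(old, new, event).estimate)


class TestCalibrationDeciles:
    def test_zero_risk_all_censored_gives_zero_observed(self):
        n = 100
        table = cr.calibration_deciles(
            np.linspace(0, 1e-6, n), np.zeros(n), np.full(n, 10.0), 10.0)
        assert (table["observed_incidence"] == 0.0).all()

    def test_mean_predicted_nondecreasing_across_bins(self, toy_scores):
        old, _, event = toy_scores
        followup = np.full(len(old), 10.0)
        table = cr.calibration_deciles(old, event, followup, 10.0)
        assert table["mean_predicted"].is_monotonic_increasing

    def test_km_equals_raw_proportion_without_censoring(self):
        rng = np.random.default_rng(4)
        n = 2000
        risk = rng.uniform(0, 0.5, n)
        event = (rng.random(n) < risk).astype(float)
        # everyone followed the full horizon; events at random times within
        followup = np.where(event == 1.0, rng.uniform(0.1, 9.9, n), 10.0)
        table = cr.calibration_deciles(risk, event, followup, 10.0)
        for _, row in table.iterrows():
            assert row["observed_incidence"] == pytest.approx(
                row["events"] / row["n"], abs=1e-12)

    def test_heavy_ties_reduce_bins_with_note(self):
        risk = np.array([0.1] * 50 + [0.9] * 50)
        event = np.array([0.0] * 50 + [1.0] * 50)
        table = cr.calibration_deciles(risk, event, np.full(100, 10.0), 10.0)
        assert len(table) == 2
        assert table.attrs["note"].startswith("reduced_bins")


class TestPercentileBands:
    def test_band_sizes_on_1000(self):
        rng = np.random.default_rng(11)
        score = rng.standard_normal(1000)
        event = (rng.random(1000) < 0.1).astype(float)
        followup = np.full(1000, 10.0)
        reports = cr.percentile_hazard_ratios(score, event, followup)
        sizes = {r.subgroup: r.n for r in reports}
        assert sizes == {"25-75pct": 500, "0-25pct": 250, "75-95pct": 200,
                         "95-100pct": 50}

    def test_null_score_hazard_ratios_near_one(self):
        rng = np.random.default_rng(12)
        n = 20_000
        score = rng.standard_normal(n)
        t = rng.exponential(50.0, n)
        followup = np.minimum(t, 10.0)
        event = (t <= 10.0).astype(float)
        reports = cr.percentile_hazard_ratios(score, event, followup)
        for rep in reports:
            if rep.note == "reference band":
                continue
            assert rep.ci_low <= 1.0 <= rep.ci_high

    def test_top5_hazard_ratio_matches_truncated_normal_expectation(self):
        """Score = PRS with log-HR beta per SD: the band HR approximates the
        ratio of E[e^{beta X}] over truncated-normal bands (rare events)."""
        beta = math.log(2.0)

        def band_mean(a, b):
            # E[e^{bX} | a < X < b] for X ~ N(0,1)
            num = stats.norm.cdf(b - beta) - stats.norm.cdf(a - beta)
            den = stats.norm.cdf(b) - stats.norm.cdf(a)
            return math.exp(beta**2 / 2) * num / den

        analytic = band_mean(stats.norm.ppf(0.95), np.inf) / band_mean(
            stats.norm.ppf(0.25), stats.norm.ppf(0.75))
        cfg = cr.GeneratorConfig(
            n_individuals=100_000, disease="CHD", seed=23,
            prs_effect=beta, baseline_weibull=(1.3, 147.0), censor_rate=0.0,
        )
        df = cr.generate_cohort(cfg)
        reports = cr.percentile_hazard_ratios(
            df["prs"].to_numpy(), df["event"].to_numpy(),
            df["followup_years"].to_numpy())
        top = next(r for r in reports if r.subgroup == "95-100pct")
        assert top.ci_low <= analytic <= top.ci_high

    def test_km_by_band_incidences_ordered_for_informative_score(self):
        cfg = cr.GeneratorConfig(
            n_individuals=30_000, disease="CHD", seed=24,
            prs_effect=math.log(2.0), baseline_weibull=(1.3, 147.0),
        )
        df = cr.generate_cohort(cfg)
        km = km_by_band(df["prs"].to_numpy(), df["event"].to_numpy(),
                        df["followup_years"].to_numpy(), 10.0)
        inc = km.set_index("band")["km_incidence"]
        assert inc["95-100pct"] > inc["25-75pct"] > inc["0-25pct"]

    def test_bands_must_partition_and_not_be_empty(self):
        score = np.arange(100, dtype=float)
        event = np.tile([0.0, 1.0], 50)
        followup = np.full(100, 10.0)
        with pytest.raises(SchemaError):
            cr.percentile_hazard_ratios(score, event, followup,
                                        bands=((0, 30), (40, 100)),
                                        reference=(40, 100))


class TestSubgroups:
    def _cohort(self):
        rng = np.random.default_rng(14)
        n = 6000
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        x = rng.standard_normal(n)
        # stronger signal in women
        beta = np.where(sex == "female", 1.5, 0.5)
        p = 1 / (1 + np.exp(-(beta * x - 2.0)))
        event = (rng.random(n) < p).astype(float)
        return pd.DataFrame({
            "id": np.arange(n).astype(str), "sex": sex,
            "age_at_baseline": rng.uniform(40, 70, n),
            "event": event, "risk": x,
        })

    def test_trivial_split_equals_global_auc(self):
        df = self._cohort()
        reports = cr.subgroup_metrics(
            df["risk"], df, {"all": np.ones(len(df), bool)})
        global_auc = cr.auc_delong(df["risk"].to_numpy(),
                                   df["event"].to_numpy())
        assert reports[0].estimate == pytest.approx(global_auc.estimate)

    def test_disjoint_exhaustive_split_ns_sum(self):
        df = self._cohort()
        from coxrisk.metrics import default_subgroups
        reports = cr.subgroup_metrics(df["risk"], df, default_subgroups(df))
        ns = {r.subgroup: r.n for r in reports}
        assert ns["men"] + ns["women"] == len(df)
        assert ns["age<55"] + ns["age>=55"] == len(df)

    def test_sex_specific_effect_orders_aucs(self):
        df = self._cohort()
        reports = {r.subgroup: r for r in cr.subgroup_metrics(
            df["risk"], df,
            {"men": (df["sex"] == "male").to_numpy(),
             "women": (df["sex"] == "female").to_numpy()})}
        assert reports["women"].estimate > reports["men"].estimate

    def test_single_class_subgroup_reported_not_raised(self):
        df = self._cohort()
        mask = np.zeros(len(df), bool)
        mask[np.flatnonzero(df["event"] == 0.0)[:10]] = True
        reports = cr.subgroup_metrics(df["risk"], df, {"weird": mask})
        assert math.isnan(reports[0].estimate)
        assert "not estimable" in reports[0].note


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(0, 1000), min_size=8, max_size=8),
)
def test_nri_identity_holds_for_any_table(counts):
    """overall = event + nonevent exactly, for arbitrary count tables."""
    c = counts[:4]
    n = counts[4:]
    if sum(c) == 0:
        c[0] = 1
    if sum(n) == 0:
        n[0] = 1
    t = ReclassificationTable(
        threshold=0.5, case_up=c[0], case_down=c[1], case_both_high=c[2],
        case_both_low=c[3], noncase_up=n[0], noncase_down=n[1],
        noncase_both_high=n[2], noncase_both_low=n[3],
    )
    res = cr.categorical_nri(t)
    assert res.overall_nri == res.event_nri + res.nonevent_nri
    assert -100.0 <= res.event_nri <= 100.0
    assert -100.0 <= res.nonevent_nri <= 100.0


def test_km_incidence_matches_hand_km():
    # 4 subjects: events at 2 and 5, censored at 3 and 10
    followup = np.array([2.0, 3.0, 5.0, 10.0])
    event = np.array([1.0, 0.0, 1.0, 0.0])
    inc, _ = km_incidence(followup, event, 10.0)
    # S(10) = (1 - 1/4) * (1 - 1/2) = 0.375
    assert inc == pytest.approx(1 - 0.375)
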