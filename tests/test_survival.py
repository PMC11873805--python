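import numpy as np
import pandas as pd
import pytest

from foxa1class import (
    annotate_castration_state,
    build_survival_records,
    fit_class_vs_wt,
    infer_vital_status,
    km_coordinates,
)


def events(days, kinds=None, **cols):
    df = pd.DataFrame({"date": days})
    df["kind"] = kinds if kinds is not None else "claim"
    for k, v in cols.items():
        df[k] = v
    df.insert(0, "patient_id", "P1")
    return df


class TestVitalStatusInference:
    def test_long_gap_is_death_at_last_claim(self):
        ev, terminal = infer_vital_status(events([10, 60]), data_cutoff_date=200)
        assert (ev, terminal) == (1, 60)

    def test_gap_of_exactly_100_days_is_censoring(self):
        ev, terminal = infer_vital_status(events([0, 100]), data_cutoff_date=200)
        assert (ev, terminal) == (0, 100)

    def test_gap_of_101_days_is_death(self):
        ev, _ = infer_vital_status(events([0, 99]), data_cutoff_date=200)
        assert ev == 1

    def test_short_gap_censors_at_last_contact(self):
        ev, terminal = infer_vital_status(events([0, 150]), data_cutoff_date=200)
        assert (ev, terminal) == (0, 150)

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError):
            infer_vital_status(events([]), data_cutoff_date=100)

    def test_cutoff_before_last_claim_is_an_error(self):
        with pytest.raises(ValueError):
            infer_vital_status(events([50]), data_cutoff_date=10)

    @pytest.mark.parametrize("gap_days", [50, 100, 150, 400])
    def test_raising_gap_never_converts_censored_to_event(self, gap_days):
        base, _ = infer_vital_status(events([0, 60]), 200, gap_days=gap_days)
        wider, _ = infer_vital_status(events([0, 60]), 200, gap_days=gap_days + 50)
        assert wider <= base


class TestCastrationState:
    def starts(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "date", "kind", "drug", "drug_category"])

    def test_within_90_days_is_hormone_sensitive(self):
        t = self.starts([("P1", 0, "treatment_start", "leuprolide", "first_line_ADT"),
                         ("P1", 30, "treatment_start", "enzalutamide", "second_gen_ARSI")])
        out = annotate_castration_state(t)
        assert out["castration_state"].tolist() == ["hormone_sensitive"] * 2

    def test_day_90_boundary_is_strict(self):
        t = self.starts([("P1", 0, "treatment_start", "leuprolide", "first_line_ADT"),
                         ("P1", 90, "treatment_start", "enzalutamide", "second_gen_ARSI"),
                         ("P1", 91, "treatment_start", "docetaxel", "taxane")])
        out = annotate_castration_state(t)
        assert out["castration_state"].tolist() == [
            "hormone_sensitive", "hormone_sensitive", "castration_resistant",
        ]

    def test_no_adt_reference_is_unknown(self):
        t = self.starts([("P1", 10, "treatment_start", "docetaxel", "taxane")])
        assert annotate_castration_state(t)["castration_state"].item() == "unknown"


def toy_claims():
    rows = [
        # P1: ARSI twice (day 10 then 400), claims stop day 500 (death)
        ("P1", 0, "claim", "", ""),
        ("P1", 10, "treatment_start", "enzalutamide", "second_gen_ARSI"),
        ("P1", 400, "treatment_start", "abiraterone", "second_gen_ARSI"),
        ("P1", 500, "claim", "", ""),
        # P2: never treated
        ("P2", 5, "claim", "", ""),
        ("P2", 995, "claim", "", ""),
        # P3: treated on the day of its last claim -> non-positive time
        ("P3", 100, "treatment_start", "docetaxel", "taxane"),
    ]
    return pd.DataFrame(rows, columns=["patient_id", "date", "kind", "drug", "drug_category"])


class TestBuildRecords:
    labels = pd.DataFrame({"patient_id": ["P1", "P2", "P3"], "class": ["2", "WT", "WT"]})

    def test_first_instance_indexing_and_inferred_death(self):
        rec = build_survival_records(self.labels, toy_claims(), "second_gen_ARSI",
                                     data_cutoff_date=1000)
        assert rec["patient_id"].tolist() == ["P1"]
        assert rec["index_date"].item() == 10
        assert rec["time_days"].item() == 490
        assert rec["event"].item() == 1  # gap 500 days > 100

    def test_untreated_patient_has_no_record(self):
        rec = build_survival_records(self.labels, toy_claims(), "any",
                                     data_cutoff_date=1000)
        assert "P2" not in set(rec["patient_id"])

    def test_non_positive_time_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            rec = build_survival_records(self.labels, toy_claims(), "taxane",
                                         data_cutoff_date=1000)
        assert len(rec) == 0
        assert "dropped" in caplog.text


def two_arm_records(times_a, events_a, times_b, events_b):
    return pd.DataFrame(
        {
            "time_days": list(times_a) + list(times_b),
            "event": list(events_a) + list(events_b),
            "class": ["2"] * len(times_a) + ["WT"] * len(times_b),
        }
    )


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Hand enumeration of the 2x2 risk tables at each event time."""
    all_times = sorted({t for t, e in zip(list(times_a) + list(times_b),
                                          list(events_a) + list(events_b)) if e})
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n1 = sum(ta >= t for ta in times_a)
        n0 = sum(tb >= t for tb in times_b)
        n = n1 + n0
        d1 = sum(ta == t and ea for ta, ea in zip(times_a, events_a))
        d0 = sum(tb == t and eb for tb, eb in zip(times_b, events_b))
        d = d1 + d0
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestCoxAndLogrank:
    def test_logrank_matches_hand_enumeration_on_four_patient_toy(self):
        rec = two_arm_records([1, 2], [1, 1], [3, 4], [1, 1])
        est = fit_class_vs_wt(rec, "2")
        expected = logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1])
        assert expected == pytest.approx(49 / 17)
        from lifelines.statistics import logrank_test

        lr = logrank_test([1, 2], [3, 4], event_observed_A=[1, 1], event_observed_B=[1, 1])
        assert lr.test_statistic == pytest.approx(expected, rel=1e-6)
        assert 0 < est.p_logrank < 1

    def test_identical_event_time_multisets_give_hr_one(self):
        times = [5, 8, 13, 21, 34, 55]
        rec = two_arm_records(times, [1] * 6, times, [1] * 6)
        est = fit_class_vs_wt(rec, "2")
        assert est.hr == pytest.approx(1.0, abs=1e-6)
        assert est.ci_low <= est.hr <= est.ci_high

    def test_relabeling_arms_inverts_hr(self):
        rng = np.random.default_rng(3)
        rec = two_arm_records(rng.exponential(10, 30), [1] * 30,
                              rng.exponential(20, 30), [1] * 30)
        fwd = fit_class_vs_wt(rec, "2", reference="WT")
        rev = fit_class_vs_wt(rec, "WT", reference="2")
        assert fwd.hr == pytest.approx(1 / rev.hr, rel=1e-6)

    def test_zero_event_arm_flagged_non_convergent(self):
        rec = two_arm_records([1, 2, 3], [0, 0, 0], [4, 5, 6], [1, 1, 1])
        est = fit_class_vs_wt(rec, "2")
        assert not est.converged and np.isnan(est.hr)

    def test_parameter_recovery_true_hr_2(self):
        """Estimated HR within 3 SE of a generating HR of 2."""
        rng = np.random.default_rng(12)
        n = 2500
        arm = rng.random(n) < 0.2
        t = rng.exponential(1.0 / np.where(arm, 2.0, 1.0), n)
        rec = pd.DataFrame({"time_days": t, "event": 1, "class": np.where(arm, "2", "WT")})
        est = fit_class_vs_wt(rec, "2")
        se = (np.log(est.ci_high) - np.log(est.hr)) / 1.96
        assert abs(np.log(est.hr) - np.log(2.0)) < 3 * se


def test_km_coordinates_are_monotone_per_class():
    rec = two_arm_records([1, 2, 3, 4], [1, 1, 0, 1], [2, 3, 5, 8], [1, 0, 1, 1])
    km = km_coordinates(rec)
    for _, grp in km.groupby("class"):
        surv = grp.sort_values("time_days")["survival"].to_numpy()
        assert (np.diff(surv) <= 1e-12).all() and surv[0] == 1.0
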