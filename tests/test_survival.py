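"""Left-truncated survival records, Kaplan-Meier and Cox PH against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from organ_age import survival, synthetic
from organ_age.config import (
    ConfigurationError,
    DataError,
    HazardConfig,
    OutcomeHazard,
)


def _records(rows):
    """rows: (subject_id, entry, exit, event, covariate z)"""
    return pd.DataFrame(rows, columns=["subject_id", "entry_age", "exit_age",
                                       "event", "z"])


def km_by_hand(records):
    """Independent product-limit oracle with explicit risk-set enumeration."""
    event_ages = sorted(records.loc[records["event"] == 1, "exit_age"].unique())
    surv, out = 1.0, []
    for t in event_ages:
        at_risk = ((records["entry_age"] < t) & (records["exit_age"] >= t)).sum()
        d = ((records["exit_age"] == t) & (records["event"] == 1)).sum()
        surv *= 1.0 - d / at_risk
        out.append((t, surv))
    return out


class TestBuildRecords:
    def _cohort(self):
        return pd.DataFrame({
            "subject_id": ["A", "B", "C", "D", "E"],
            "sex": ["female", "male", "male", "female", "male"],
            "ca_at_imaging": [60.0, 62.0, 64.0, 66.0, 61.0],
            "bmi": [25.0, 27.0, 30.0, 24.0, 26.0],
            "retrieval_age": [68.0, 70.0, 72.0, 74.0, 69.0],
            "age_ckd": [55.0, 65.0, np.nan, np.nan, np.nan],
            "death_age": [np.nan, np.nan, 70.0, np.nan, 67.0],
        })

    def test_prevalent_case_excluded(self):
        rec = survival.build_records(self._cohort(), "ckd")
        assert "A" not in set(rec["subject_id"])  # diagnosed at 55 < imaging 60

    def test_incident_case_is_an_event_at_diagnosis_age(self):
        rec = survival.build_records(self._cohort(), "ckd").set_index("subject_id")
        assert rec.loc["B", "event"] == 1
        assert rec.loc["B", "exit_age"] == pytest.approx(65.0)

    def test_other_cause_death_censors(self):
        rec = survival.build_records(self._cohort(), "ckd").set_index("subject_id")
        assert rec.loc["C", "event"] == 0
        assert rec.loc["C", "exit_age"] == pytest.approx(70.0)

    def test_no_events_when_outcome_absent_everywhere(self):
        cohort = self._cohort()
        cohort["age_ckd"] = np.nan
        rec = survival.build_records(cohort, "ckd")
        assert (rec["event"] == 0).all()

    def test_death_outcome_counts_all_observed_deaths(self):
        rec = survival.build_records(self._cohort(), "death").set_index("subject_id")
        assert rec.loc["C", "event"] == 1 and rec.loc["E", "event"] == 1
        assert rec.loc["D", "event"] == 0

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ConfigurationError):
            survival.build_records(self._cohort(), "gout")


class TestKaplanMeier:
    def test_no_events_gives_constant_one(self):
        rec = _records([("a", 50, 60, 0, 0), ("b", 52, 64, 0, 0)])
        km = survival.km_estimate(rec)
        assert (km["survival"] == 1.0).all()

    def test_left_truncated_fixture_matches_hand_enumeration(self):
        rec = _records([
            ("a", 50, 55, 1, 0), ("b", 52, 57, 1, 0), ("c", 54, 55, 1, 0),
            ("d", 56, 60, 0, 0), ("e", 49, 58, 1, 0), ("f", 53, 61, 0, 0)])
        oracle = km_by_hand(rec)  # [(55, 0.6), (57, 0.45), (58, 0.3)]
        assert oracle == [(55, pytest.approx(0.6)), (57, pytest.approx(0.45)),
                          (58, pytest.approx(0.3))]
        km = survival.km_estimate(rec).set_index("age")["survival"]
        for age, value in oracle:
            assert km.loc[age] == pytest.approx(value, abs=1e-12)

    def test_simultaneous_events_drop_curve_to_zero(self):
        rec = _records([("a", 50, 58, 1, 0), ("b", 51, 58, 1, 0),
                        ("c", 49, 58, 1, 0)])
        km = survival.km_estimate(rec)
        assert km["survival"].iloc[-1] == pytest.approx(0.0)

    def test_equal_entries_reduce_to_classical_estimator(self, rng):
        n = 80
        exit_age = 60 + rng.exponential(5, n)
        event = (rng.random(n) < 0.6).astype(int)
        rec = pd.DataFrame({"subject_id": range(n), "entry_age": 50.0,
                            "exit_age": exit_age, "event": event})
        km = survival.km_estimate(rec).set_index("age")["survival"]
        for age, value in km_by_hand(rec):
            assert km.loc[age] == pytest.approx(value, abs=1e-12)

    def test_empty_records_rejected(self):
        with pytest.raises(DataError):
            survival.km_estimate(_records([]))


class TestCox:
    def test_staggered_entry_toy_matches_partial_likelihood_score_root(self):
        """Hand-enumerated risk sets give an analytic partial likelihood:
        l(b) = b - log(e^b + 1) - log(1 + e^{2b}); its score root is the MLE."""
        rec = _records([
            ("s1", 40, 42, 1, 1.0),   # risk set {s1, s2}
            ("s2", 40, 44, 1, 0.0),   # risk set {s2, s3}
            ("s3", 43, 45, 0, 2.0)])

        def score(b):
            return (1.0 - np.exp(b) / (np.exp(b) + 1.0)
                    - 2.0 * np.exp(2 * b) / (1.0 + np.exp(2 * b)))

        root = optimize.brentq(score, -5.0, 5.0)
        fit = survival.cox_fit(rec, ["z"])
        assert fit.beta["z"] == pytest.approx(root, abs=1e-5)

    def test_affine_time_shift_leaves_estimate_unchanged(self, rng):
        n = 300
        z = rng.normal(size=n)
        exit_age = 60 + rng.exponential(np.exp(-0.3 * z) * 5)
        rec = pd.DataFrame({"subject_id": range(n), "entry_age": 55.0,
                            "exit_age": exit_age, "event": 1, "z": z})
        shifted = rec.assign(entry_age=rec["entry_age"] + 7.0,
                             exit_age=rec["exit_age"] + 7.0)
        a = survival.cox_fit(rec, ["z"]).beta["z"]
        b = survival.cox_fit(shifted, ["z"]).beta["z"]
        assert a == pytest.approx(b, abs=1e-8)

    def test_doubling_covariate_halves_beta(self, rng):
        n = 300
        z = rng.normal(size=n)
        exit_age = 60 + rng.exponential(np.exp(-0.3 * z) * 5)
        rec = pd.DataFrame({"subject_id": range(n), "entry_age": 55.0,
                            "exit_age": exit_age, "event": 1, "z": z})
        beta = survival.cox_fit(rec, ["z"]).beta["z"]
        beta2 = survival.cox_fit(rec.assign(z=2 * z), ["z"]).beta["z"]
        assert beta2 == pytest.approx(beta / 2.0, abs=1e-8)

    def test_ordinal_group_coding_estimates_per_step_hazard(self):
        cohort = synthetic.generate_cohort(3000, hazards=HazardConfig(outcomes={
            "disease": OutcomeHazard(0.15, 0.3, "brain", 0.0, onset_age=60.0)}),
            seed=51)
        rec = survival.build_records(cohort, "disease")
        pag = cohort.set_index("subject_id").loc[rec["subject_id"], "pag_brain"]
        rec["group"] = np.where(pag > 2.5, 2, np.where(pag < -2.5, 0, 1))
        fit = survival.cox_fit(rec, ["group"])
        assert fit.hr["group"] > 1.3  # graded risk across 0/1/2

    def test_constant_covariate_rejected(self):
        rec = _records([("a", 50, 55, 1, 1.0), ("b", 50, 56, 1, 1.0),
                        ("c", 50, 57, 1, 1.0)])
        with pytest.raises(DataError):
            survival.cox_fit(rec, ["z"])

    def test_needs_two_events(self):
        rec = _records([("a", 50, 55, 1, 1.0), ("b", 50, 56, 0, 0.0)])
        with pytest.raises(DataError):
            survival.cox_fit(rec, ["z"])


class TestLikelihoodRatio:
    def _fitted_pair(self, seed, log_hr):
        cohort = synthetic.generate_cohort(400, hazards=HazardConfig(outcomes={
            "disease": OutcomeHazard(0.15, log_hr, "brain", 0.0, onset_age=60.0)}),
            seed=seed)
        rec = survival.build_records(cohort, "disease")
        rec["pag"] = cohort.set_index("subject_id").loc[
            rec["subject_id"], "pag_brain"].to_numpy()
        full = survival.cox_fit(rec, ["pag", "ca", "sex", "bmi"])
        reduced = survival.cox_fit(rec, ["ca", "sex", "bmi"])
        return full, reduced

    def test_identical_models_give_null_result(self):
        full, _ = self._fitted_pair(1, 0.2)
        out = survival.lr_test(full, full)
        assert out["chi2"] == 0.0
        assert out["p"] == 1.0

    def test_non_nested_models_rejected(self):
        full, reduced = self._fitted_pair(2, 0.2)
        with pytest.raises(ConfigurationError):
            survival.lr_test(reduced, full)

    def test_strong_effect_detected(self):
        cohort = synthetic.generate_cohort(2000, hazards=HazardConfig(outcomes={
            "disease": OutcomeHazard(0.15, 0.25, "brain", 0.0, onset_age=60.0)}),
            seed=3)
        rec = survival.build_records(cohort, "disease")
        rec["pag"] = cohort.set_index("subject_id").loc[
            rec["subject_id"], "pag_brain"].to_numpy()
        full = survival.cox_fit(rec, ["pag", "ca", "sex", "bmi"])
        reduced = survival.cox_fit(rec, ["ca", "sex", "bmi"])
        assert survival.lr_test(full, reduced)["p"] < 1e-4

    def test_null_p_values_are_uniform(self):
        seeds = np.random.SeedSequence(17).generate_state(100) % (2**31)
        ps = []
        for s in seeds:
            full, reduced = self._fitted_pair(int(s), 0.0)
            ps.append(survival.lr_test(full, reduced)["p"])
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01


class TestHazardRatioScale:
    @pytest.mark.parametrize("hr, pct", [(1.0, 0.0), (1.13, 13.0), (0.9, -10.0)])
    def test_percent_per_year_conversion(self, hr, pct):
        fit = survival.CoxFit(beta={"pag": np.log(hr)}, hr={"pag": hr},
                              ci95={"pag": (hr * 0.9, hr * 1.1)},
                              se={"pag": 0.01}, p={"pag": 0.5}, loglik=-10.0,
                              n=100, n_events=20, covariates=("pag",))
        assert survival.hr_per_year(fit, "pag") == pytest.approx(pct)

    def test_unknown_covariate_rejected(self):
        fit = survival.CoxFit(beta={}, hr={}, ci95={}, se={}, p={}, loglik=0.0,
                              n=0, n_events=0, covariates=())
        with pytest.raises(ConfigurationError):
            survival.hr_per_year(fit, "pag")
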