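"""Monte-Carlo cohorts, empirical hazards, and the event-rate HR estimator."""

import math

import numpy as np
import pandas as pd
import pytest

from haploselect import (
    CohortConfig,
    DomainError,
    HaplotypeDistribution,
    HazardSet,
    Scenario,
    crossing_ages,
    empirical_hazard,
    load_preset,
    marginal_hazards,
    read_cohort,
    sample_cohort,
    whole_window_hr,
    write_cohort,
)


def flat_scenario(rate=0.05):
    return Scenario(
        "flat",
        HaplotypeDistribution(0.3, 0.3, 0.2, 0.2),
        HazardSet(rate, rate, rate, rate),
    )


def proportional_scenario(mu_carrier=0.05, mu_noncarrier=0.07):
    """Carrier and non-carrier classes each have one constant hazard."""
    return Scenario(
        "proportional",
        HaplotypeDistribution(0.35, 0.25, 0.25, 0.15),
        HazardSet(mu_noncarrier, mu_carrier, mu_noncarrier, mu_carrier),
    )


def test_sampling_is_deterministic_given_seed():
    s = load_preset("B")
    cfg = CohortConfig(n=5000, seed=99, censor_age=60.0)
    a = sample_cohort(s, cfg)
    b = sample_cohort(s, cfg)
    pd.testing.assert_frame_equal(a, b)
    c = sample_cohort(s, CohortConfig(n=5000, seed=100, censor_age=60.0))
    assert not a["exit_age"].equals(c["exit_age"])


def test_haplotype_proportions_within_binomial_error():
    s = load_preset("A")
    n = 50_000
    rec = sample_cohort(s, CohortConfig(n=n, seed=0, censor_age=60.0))
    counts = rec["haplotype"].value_counts()
    for hap, p in zip(("00", "10", "01", "11"), s.dist0.as_tuple()):
        k = counts.get(hap, 0)
        if p == 0.0:
            assert k == 0
        else:
            assert abs(k / n - p) <= 3.0 * math.sqrt(p * (1 - p) / n)


def test_mean_lifespan_matches_exponential_oracle():
    mu = 0.05
    n = 100_000
    rec = sample_cohort(flat_scenario(mu), CohortConfig(n=n, seed=1, censor_age=1e9))
    assert rec["event"].all()
    lifespans = rec["exit_age"] - rec["entry_age"]
    se = (1.0 / mu) / math.sqrt(n)
    assert abs(lifespans.mean() - 1.0 / mu) <= 3.0 * se


def test_censoring_truncates_exit_ages():
    rec = sample_cohort(flat_scenario(), CohortConfig(n=2000, seed=2, censor_age=20.0))
    censored = rec[rec["event"] == 0]
    assert len(censored) > 0
    assert (censored["exit_age"] == 20.0).all()
    assert (rec["exit_age"] <= 20.0).all()


def test_cohort_roundtrip_preserves_haplotype_codes(tmp_path):
    rec = sample_cohort(load_preset("C"), CohortConfig(n=500, seed=3, censor_age=50.0))
    path = tmp_path / "cohort.csv"
    write_cohort(rec, path)
    assert path.read_text().splitlines()[0] == "id,haplotype,entry_age,exit_age,event"
    back = read_cohort(path)
    assert set(back["haplotype"]) <= {"00", "10", "01", "11"}
    pd.testing.assert_frame_equal(
        back, rec, check_dtype=False, check_exact=False, rtol=1e-15
    )


def test_empirical_hazard_single_record():
    rec = pd.DataFrame(
        {"id": [0], "haplotype": ["10"], "entry_age": [0.0],
         "exit_age": [7.0], "event": [1]}
    )
    eh = empirical_hazard(rec, bins=[0.0, 5.0, 10.0], locus=1)
    carrier = eh[eh["group"] == "carrier"].set_index("age_lo")
    assert carrier.loc[5.0, "rate"] == pytest.approx(1.0 / 2.0)
    assert carrier.loc[0.0, "deaths"] == 0
    noncarrier = eh[eh["group"] == "noncarrier"]
    assert noncarrier["rate"].isna().all()  # zero exposure -> missing


def test_empirical_hazard_rejects_bad_bins():
    rec = sample_cohort(flat_scenario(), CohortConfig(n=10, seed=4, censor_age=20.0))
    with pytest.raises(DomainError):
        empirical_hazard(rec, bins=[10.0, 5.0], locus=1)
    with pytest.raises(DomainError):
        empirical_hazard(rec.iloc[:0], bins=[0.0, 5.0], locus=1)


def test_empirical_hazard_matches_analytic_trajectory():
    s = load_preset("A")
    rec = sample_cohort(s, CohortConfig(n=200_000, seed=0, censor_age=40.0))
    eh = empirical_hazard(rec, bins=np.arange(0.0, 41.0, 5.0), locus=1)
    for _, row in eh.iterrows():
        mid = 0.5 * (row.age_lo + row.age_hi)
        mu_c, mu_n = marginal_hazards(s, mid, 1)
        analytic = mu_c if row.group == "carrier" else mu_n
        assert row.deaths > 0
        se = math.sqrt(row.deaths) / row.person_years
        assert abs(row.rate - analytic) <= 3.0 * se


def test_equal_rate_groups_are_indistinguishable():
    rec = sample_cohort(flat_scenario(), CohortConfig(n=50_000, seed=5, censor_age=40.0))
    eh = empirical_hazard(rec, bins=np.arange(0.0, 41.0, 10.0), locus=1)
    piv = eh.pivot(index="age_lo", columns="group", values=["rate", "deaths", "person_years"])
    for age_lo, row in piv.iterrows():
        se = math.sqrt(
            row[("deaths", "carrier")] / row[("person_years", "carrier")] ** 2
            + row[("deaths", "noncarrier")] / row[("person_years", "noncarrier")] ** 2
        )
        assert abs(row[("rate", "carrier")] - row[("rate", "noncarrier")]) <= 3.0 * se


def test_whole_window_hr_null_case():
    rec = sample_cohort(flat_scenario(), CohortConfig(n=50_000, seed=6, censor_age=40.0))
    est = whole_window_hr(rec, locus=1)
    assert est.finite
    assert abs(est.log_hr) <= 3.0 * est.se


def test_whole_window_hr_recovers_true_rate_ratio():
    s = proportional_scenario(0.05, 0.07)
    rec = sample_cohort(s, CohortConfig(n=100_000, seed=7, censor_age=60.0))
    est = whole_window_hr(rec, locus=1)
    assert abs(est.log_hr - math.log(5.0 / 7.0)) <= 3.0 * est.se


def test_whole_window_hr_agrees_with_cox_fit():
    lifelines = pytest.importorskip("lifelines")
    s = proportional_scenario(0.05, 0.07)
    rec = sample_cohort(s, CohortConfig(n=20_000, seed=8, censor_age=60.0))
    carrier = rec["haplotype"].isin(("10", "11")).astype(float)
    df = pd.DataFrame(
        {"T": rec["exit_age"] - rec["entry_age"], "E": rec["event"], "carrier": carrier}
    )
    cph = lifelines.CoxPHFitter().fit(df, duration_col="T", event_col="E")
    cox_log_hr = cph.params_["carrier"]
    est = whole_window_hr(rec, locus=1)
    assert est.log_hr == pytest.approx(cox_log_hr, abs=3.0 * est.se)


def test_vulnerability_signal_detected():
    rec = sample_cohort(
        load_preset("B"), CohortConfig(n=100_000, seed=9, censor_age=30.0)
    )
    est = whole_window_hr(rec, locus=1)
    assert est.log_hr > 0
    assert est.log_hr > 3.0 * est.se


def test_crossing_attenuates_whole_window_estimate():
    n, censor = 200_000, 60.0
    est_b = whole_window_hr(
        sample_cohort(load_preset("B"), CohortConfig(n=n, seed=10, censor_age=censor))
    )
    for name, seed in (("C", 11), ("D", 12)):
        est = whole_window_hr(
            sample_cohort(load_preset(name), CohortConfig(n=n, seed=seed, censor_age=censor))
        )
        assert abs(est.log_hr) < abs(est_b.log_hr)


def test_flip_flop_early_late_signs():
    # n sized so the weakest window effect (late window of D, expected
    # |log RR| ~ 0.011 from the deterministic model) exceeds 4 SE
    n = 2_000_000
    for name, seed in (("C", 13), ("D", 14)):
        s = load_preset(name)
        (cross,) = crossing_ages(s)
        rec = sample_cohort(s, CohortConfig(n=n, seed=seed, censor_age=60.0))
        early = whole_window_hr(rec, window=(s.t0, cross))
        late = whole_window_hr(rec, window=(cross, 60.0))
        whole = whole_window_hr(rec)
        assert early.log_hr * late.log_hr < 0
        assert min(early.log_hr, late.log_hr) < whole.log_hr < max(early.log_hr, late.log_hr)


def test_zero_event_group_flagged():
    rec = pd.DataFrame(
        {
            "id": [0, 1],
            "haplotype": ["10", "00"],
            "entry_age": [0.0, 0.0],
            "exit_age": [10.0, 8.0],
            "event": [0, 1],
        }
    )
    est = whole_window_hr(rec, locus=1)
    assert not est.finite
    assert math.isinf(est.log_hr)


def test_window_requires_positive_persontime():
    rec = sample_cohort(flat_scenario(), CohortConfig(n=100, seed=15, censor_age=20.0))
    with pytest.raises(DomainError):
        whole_window_hr(rec, window=(30.0, 40.0))
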