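import numpy as np
import pandas as pd
import pytest

from codqc import (
    AgeStructure, DefectConfig, InputError, MortalitySchedule,
    default_cause_model, degrade, fraction_65_plus, generate_dataset,
    generate_population, generate_true_deaths, largest_remainder,
    run_assessment,
)
from codqc.data_io import age_midpoint, age_ladder


def test_largest_remainder_conserves_and_tracks_quotas():
    out = largest_remainder([1, 1, 1], 10)
    assert out.sum() == 10 and set(out) <= {3, 4}
    out = largest_remainder([0.3, 0.7], 7)
    assert list(out) == [2, 5]
    assert largest_remainder([0, 0], 5).sum() == 0
    rng = np.random.default_rng(0)
    for _ in range(50):
        w = rng.uniform(0, 1, 20)
        n = int(rng.integers(0, 1000))
        out = largest_remainder(w, n)
        assert out.sum() == n
        assert np.all(np.abs(out - w / w.sum() * n) <= 1.0)


def test_population_structure_and_determinism():
    pop = generate_population(100_000, AgeStructure(rho=0.05), seed=1)
    assert pop.total == 100_000
    male = pop.filter(sex="male").set_index("age_group")["count"]
    ladder = age_ladder(include_unknown=False)
    counts = [male[b] for b in ladder if b not in ("<1",)]
    assert all(b <= a for a, b in zip(counts, counts[1:]))  # young pyramid
    again = generate_population(100_000, AgeStructure(rho=0.05), seed=99)
    pd.testing.assert_frame_equal(pop.data, again.data)  # construction exact
    with pytest.raises(InputError):
        generate_population(0)


def test_fraction_65_plus_matches_closed_form():
    structure = AgeStructure(rho=0.03)
    pop = generate_population(2_000_000, structure)
    df = pop.data
    old = df["age_group"].map(lambda b: b not in ("<1", "1-4")
                              and float(b.rstrip("+").split("-")[0]) >= 65)
    realized = df.loc[old, "count"].sum() / pop.total
    expected = fraction_65_plus(structure)
    w = [np.exp(-structure.rho * age_midpoint(b))
         for b in age_ladder(include_unknown=False)]
    w_old = [np.exp(-structure.rho * age_midpoint(b))
             for b in age_ladder(include_unknown=False)
             if b not in ("<1", "1-4")
             and float(b.rstrip("+").split("-")[0]) >= 65]
    assert expected == pytest.approx(sum(w_old) / sum(w), abs=1e-9)
    assert realized == pytest.approx(expected, abs=1e-5)  # apportion rounding


def test_deterministic_deaths_equal_rounded_expectation():
    pop = generate_population(500_000)
    schedule = MortalitySchedule()
    deaths, truth = generate_true_deaths(pop, schedule, mode="deterministic")
    by_band = deaths.data.groupby(["sex", "age_group"])["count"].sum()
    for rec in pop.data.itertuples(index=False):
        expected = round(rec.count * schedule.rate(rec.age_group, rec.sex))
        assert by_band.get((rec.sex, rec.age_group), 0) == expected


def test_pure_gompertz_band_rates_are_exactly_log_linear():
    """With lam=0 the log band rates against midpoints form a line of
    slope beta, so the slope estimate is exact in expectation."""
    from codqc import age_specific_rates, log_linearity_check
    schedule = MortalitySchedule(lam=0.0, alpha=2e-5, beta=0.1)
    pop = generate_population(8_000_000)
    deaths, _ = generate_true_deaths(pop, schedule, mode="deterministic")
    rates = age_specific_rates(deaths, pop)
    fit = log_linearity_check(rates, sex="male", min_age=30)
    assert fit.slope == pytest.approx(0.1, rel=0.01)
    assert fit.r_squared > 0.999


def test_poisson_mode_band_means_match_expectation():
    pop = generate_population(200_000)
    schedule = MortalitySchedule()
    totals = []
    expected_total = sum(rec.count * schedule.rate(rec.age_group, rec.sex)
                         for rec in pop.data.itertuples(index=False))
    n_seeds = 200
    for seed in range(n_seeds):
        deaths, _ = generate_true_deaths(pop, schedule, seed=seed,
                                         mode="poisson")
        totals.append(deaths.total)
    se = np.sqrt(expected_total / n_seeds)  # Poisson variance = mean
    assert abs(np.mean(totals) - expected_total) < 3 * se


def test_degrade_identity_when_all_defects_zero():
    deaths, pop, comp, truth = generate_dataset(seed=2, size=300_000)
    degraded, _ = degrade(deaths, DefectConfig(), seed=2)
    pd.testing.assert_frame_equal(deaths.data, degraded.data)


def test_deterministic_thinning_hits_exact_totals():
    pop = generate_population(400_000)
    deaths, truth = generate_true_deaths(pop)
    degraded, _ = degrade(deaths, DefectConfig(completeness=0.7), seed=0)
    u5 = ["<1", "1-4"]
    for mask_vals, label in ((u5, "under5"), (None, "adult")):
        d0 = deaths.data
        d1 = degraded.data
        if mask_vals is None:
            t0 = d0.loc[~d0["age_group"].isin(u5), "count"].sum()
            t1 = d1.loc[~d1["age_group"].isin(u5), "count"].sum()
        else:
            t0 = d0.loc[d0["age_group"].isin(u5), "count"].sum()
            t1 = d1.loc[d1["age_group"].isin(u5), "count"].sum()
        assert t1 == round(t0 * 0.7)


def test_child_differential_thinning():
    pop = generate_population(400_000)
    deaths, truth = generate_true_deaths(pop)
    cfg = DefectConfig(completeness=0.9, completeness_under5=0.6)
    degraded, _ = degrade(deaths, cfg, seed=0)
    u5 = degraded.data["age_group"].isin(["<1", "1-4"])
    u5_before = deaths.data["age_group"].isin(["<1", "1-4"])
    assert degraded.data.loc[u5, "count"].sum() == round(
        0.6 * deaths.data.loc[u5_before, "count"].sum())


def test_garbage_mix_realized_fractions(metadata):
    from codqc import typology_distributions
    mix = (0.10, 0.05, 0.03, 0.02)
    deaths, pop, comp, truth = generate_dataset(
        seed=3, size=600_000, defects=DefectConfig(garbage=mix))
    sev = typology_distributions(deaths, metadata)["by_severity"]
    realized = sev.set_index("severity_level")["fraction_of_all_deaths"]
    for level, frac in zip((1, 2, 3, 4), mix):
        assert realized[level] == pytest.approx(frac, abs=0.002)


def test_garbage_mix_poisson_over_seeds(metadata):
    from codqc import typology_distributions
    mix = (0.10, 0.0, 0.0, 0.05)
    realized = []
    for seed in range(20):
        deaths, *_ = generate_dataset(seed=seed, size=150_000,
                                      defects=DefectConfig(garbage=mix),
                                      mode="poisson")
        sev = typology_distributions(deaths, metadata)["by_severity"]
        fr = sev.set_index("severity_level")["fraction_of_all_deaths"]
        realized.append((fr[1], fr[4]))
    means = np.mean(realized, axis=0)
    assert means[0] == pytest.approx(0.10, abs=0.01)
    assert means[1] == pytest.approx(0.05, abs=0.01)


def test_determinism_same_seed_byte_identical():
    a = generate_dataset(seed=42, size=200_000, mode="poisson",
                         defects=DefectConfig(completeness=0.8,
                                              garbage=(0.05, 0, 0, 0)))
    b = generate_dataset(seed=42, size=200_000, mode="poisson",
                         defects=DefectConfig(completeness=0.8,
                                              garbage=(0.05, 0, 0, 0)))
    pd.testing.assert_frame_equal(a[0].data, b[0].data)
    pd.testing.assert_frame_equal(a[1].data, b[1].data)
    assert a[3].to_json() == b[3].to_json()
    c = generate_dataset(seed=43, size=200_000, mode="poisson",
                         defects=DefectConfig(completeness=0.8,
                                              garbage=(0.05, 0, 0, 0)))
    assert not a[0].data.equals(c[0].data)


def test_comparators_from_truth_are_self_consistent(perfect_fixture):
    deaths, pop, comp, truth = perfect_fixture
    trend_years = list(comp.cdr_trend.index)
    assert trend_years[0] == truth.year - 15
    assert trend_years[-1] == truth.year + 15
    assert comp.cdr_trend[truth.year] == pytest.approx(truth.true_cdr)
    assert comp.u5mr_estimate == pytest.approx(truth.true_q5)
    assert sum(comp.broad_group_envelope.values()) == pytest.approx(1.0,
                                                                    abs=1e-9)
    env = comp.broad_group_envelope
    for g, v in truth.true_group_fractions.items():
        assert env[g] == pytest.approx(v, abs=1e-9)


def test_reference_cause_list_has_192_unique_codes():
    model = default_cause_model()
    ref = model.reference_cause_list
    assert len(ref) == 192 and len(set(ref)) == 192
    for g in ("group1", "group2", "group3"):
        assert len(model.group_codes[g]) > 0


def test_full_pipeline_recovery_deterministic(metadata):
    """The assessment recovers every injected defect level."""
    cfg = DefectConfig(completeness=0.8, garbage=(0.06, 0.03, 0.02, 0.01),
                       missing_age=0.04, missing_sex=0.01, implausible=0.02)
    deaths, pop, comp, truth = generate_dataset(seed=9, defects=cfg)
    rep = run_assessment(deaths, pop, comp, {"metadata": metadata})
    comps = rep.steps["step10"]["components"]
    assert comps["completeness"] == pytest.approx(0.8, abs=0.005)
    assert comps["agesex"] == pytest.approx(0.95, abs=0.005)
    assert comps["plausibility"] == pytest.approx(0.98, abs=0.005)
    f1, f2, f3, f4 = 0.06, 0.03, 0.02, 0.01
    assert comps["garbage"] == pytest.approx(
        1 - (2 * (f1 + f2 + f3) + f4) / 2, abs=0.005)
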