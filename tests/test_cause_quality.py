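import numpy as np
import pytest

from codqc import (
    BINS, DefectConfig, broad_group_distribution, classify_code,
    epi_transition_measure, extract_packages, generate_dataset, leading_causes,
    redistribute_garbage, typology_distributions, usability_distribution,
)
from codqc.data_io import comparators_from_dict

from conftest import make_deaths


@pytest.mark.parametrize("code, attr, expected", [
    ("A41", "severity_level", 1),     # septicaemia
    ("I10", "severity_level", 2),     # essential hypertension
    ("C80", "severity_level", 3),     # unspecified cancer
    ("I64", "severity_level", 4),     # unspecified stroke
    ("R99", "icd_error_category", 1),  # ill-defined
    ("I219", "usability", "usable"),
    ("I219", "broad_group", "group2"),
    ("W13", "broad_group", "group3"),
])
def test_classification_defaults(metadata, code, attr, expected):
    assert getattr(classify_code(code, metadata), attr) == expected


def test_classify_missing_code_is_insufficiently_specified(metadata):
    cls = classify_code("missing", metadata)
    assert cls.usability == "insufficiently_specified"
    assert cls.severity_level == 3


def test_usability_distribution_halves(metadata):
    deaths = make_deaths([("male", "50-54", "I21", 50),
                          ("female", "60-64", "R99", 50)])
    dist = usability_distribution(deaths, metadata)
    assert dist.fractions["usable"] == 0.5
    assert dist.fractions["unusable"] == 0.5
    all_usable = make_deaths([("male", "50-54", "I21", 10)])
    assert usability_distribution(all_usable, metadata).fractions["usable"] == 1.0


def test_broad_group_distribution_and_age_conservation(metadata):
    deaths = make_deaths([("male", "<1", "A09", 30),
                          ("male", "20-24", "V02", 20),
                          ("female", "70-74", "I64", 10),
                          ("female", "unknown", "I21", 5)])
    dist = broad_group_distribution(deaths, metadata, by_age=True)
    assert dist.counts["group1"] == 30
    assert dist.counts["group3"] == 20
    assert dist.counts["insufficiently_specified"] == 10
    assert sum(dist.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    # age table conserves the overall totals, unknown age included
    assert dist.by_age.to_numpy().sum() == deaths.total
    for b in BINS:
        assert dist.by_age[b].sum() == dist.counts[b]


def _envelope_comp(g1, g2, g3):
    return comparators_from_dict({
        "cdr_trend": [{"year": 2000, "cdr": 8.0}, {"year": 2030, "cdr": 8.0}],
        "u5mr_estimate": {"year": 2015, "value": 0.04},
        "broad_group_envelope": {"group1": g1, "group2": g2, "group3": g3},
        "reference_cause_list": ["A00"],
    })


def test_epi_transition_measure(metadata):
    comp = _envelope_comp(0.3, 0.6, 0.1)
    deaths = make_deaths([("male", "50-54", "A09", 40),   # group1
                          ("male", "50-54", "I21", 40)])  # group2
    dist = broad_group_distribution(deaths, metadata)
    res = epi_transition_measure(dist, comp)
    assert res["measure"] == 0.5
    assert res["expected"] == pytest.approx(1 / 3)
    assert res["delta"] == pytest.approx(0.5 - 1 / 3)
    only_g2 = broad_group_distribution(
        make_deaths([("male", "50-54", "I21", 10)]), metadata)
    assert epi_transition_measure(only_g2, comp)["measure"] == 0.0


def test_epi_transition_undefined_without_usable_groups(metadata):
    dist = broad_group_distribution(
        make_deaths([("male", "50-54", "R99", 10)]), metadata)
    res = epi_transition_measure(dist, _envelope_comp(0.3, 0.6, 0.1))
    assert res["measure"] is None and "undefined" in res["note"]


def test_typology_histograms(metadata):
    deaths = make_deaths([("male", "60-64", "R99", 100),
                          ("male", "60-64", "I21", 100)])
    hists = typology_distributions(deaths, metadata)
    cat = hists["by_category"].set_index("icd_error_category")["deaths"]
    assert cat[1] == 100 and cat[2:].sum() == 0
    sev = hists["by_severity"].set_index("severity_level")
    assert sev.loc[1, "deaths"] == 100
    assert sev.loc[1, "fraction_of_all_deaths"] == 0.5
    clean = typology_distributions(
        make_deaths([("male", "60-64", "I21", 5)]), metadata)
    assert clean["by_category"]["deaths"].sum() == 0
    assert clean["by_severity"]["deaths"].sum() == 0


def test_sepsis_package_ranking(metadata):
    """The four sepsis members rank by count with the worked frequencies."""
    deaths = make_deaths([("male", "70-74", "A41", 6547),
                          ("male", "70-74", "D65", 242),
                          ("female", "75-79", "R02", 10),
                          ("female", "75-79", "A40", 5),
                          ("male", "70-74", "I21", 1000)])
    packages = extract_packages(deaths, metadata)
    sepsis = next(p for p in packages if p.package == "sepsis")
    assert sepsis.rank == 1 and sepsis.total == 6804
    assert list(sepsis.members["icd_code"]) == ["A41", "D65", "R02", "A40"]
    assert list(sepsis.members["deaths"]) == [6547, 242, 10, 5]
    assert list(sepsis.members["rank"]) == [1, 2, 3, 4]


def test_package_tie_breaks_lexicographically(metadata):
    deaths = make_deaths([("male", "70-74", "D65", 10),
                          ("male", "70-74", "A41", 10)])
    sepsis = extract_packages(deaths, metadata)[0]
    assert list(sepsis.members["icd_code"]) == ["A41", "D65"]
    single = extract_packages(
        make_deaths([("male", "70-74", "I10", 3)]), metadata)
    assert len(single) == 1 and len(single[0].members) == 1


def test_redistribution_proportional_within_stratum(metadata):
    """100 I10 deaths (target group2 only) go entirely to group2; garbage
    with all-group targets follows the stratum's usable 30:70 split."""
    deaths = make_deaths([("male", "50-54", "A09", 30),   # group1 usable
                          ("male", "50-54", "I21", 70),   # group2 usable
                          ("male", "50-54", "R99", 100)])  # targets all groups
    dist, audit = redistribute_garbage(deaths, metadata)
    assert dist.counts["group1"] == pytest.approx(60.0)
    assert dist.counts["group2"] == pytest.approx(140.0)
    assert dist.counts["unusable"] == 0.0
    assert sum(dist.counts.values()) == pytest.approx(deaths.total, abs=1e-9)
    assert set(audit["basis"]) == {"stratum"}


def test_redistribution_fallbacks(metadata):
    # no usable deaths anywhere -> equal split over the target groups
    deaths = make_deaths([("male", "50-54", "R99", 90)])
    dist, audit = redistribute_garbage(deaths, metadata)
    assert dist.counts["group1"] == pytest.approx(30.0)
    assert set(audit["basis"]) == {"equal_split"}
    # usable deaths only in another stratum -> whole-dataset distribution
    deaths = make_deaths([("male", "50-54", "R99", 10),
                          ("female", "60-64", "I21", 40)])
    dist, audit = redistribute_garbage(deaths, metadata)
    assert set(audit["basis"]) == {"overall"}
    assert dist.counts["group2"] == pytest.approx(50.0)


def test_redistribution_idempotent_on_garbage_free_input(metadata):
    deaths = make_deaths([("male", "50-54", "I21", 40),
                          ("female", "<1", "A09", 10)])
    dist, audit = redistribute_garbage(deaths, metadata)
    assert audit.empty
    assert dist.counts["group2"] == 40 and dist.counts["group1"] == 10


def test_redistribution_recovers_preinjection_mix(metadata):
    """Recoding usable deaths to garbage and then redistributing restores
    the broad-group fractions of the uninjected data."""
    deaths, pop, comp, truth = generate_dataset(
        seed=13, size=400_000,
        defects=DefectConfig(garbage=(0.08, 0.04, 0.02, 0.02)))
    before = truth.true_group_fractions
    dist, _ = redistribute_garbage(deaths, metadata)
    total = sum(dist.counts[g] for g in ("group1", "group2", "group3"))
    for g in ("group1", "group2", "group3"):
        assert dist.counts[g] / total == pytest.approx(before[g], abs=0.02)


def test_leading_causes_flags_and_ordering(metadata):
    deaths = make_deaths([("male", "70-74", "A41", 500),   # severity 1 garbage
                          ("male", "70-74", "I64", 300),   # severity 4 garbage
                          ("male", "70-74", "I21", 400),
                          ("male", "70-74", "I219", 50)])  # same I21 category
    table = leading_causes(deaths, metadata, n=20)
    assert table["rank"].tolist() == [1, 2, 3]
    top = table.iloc[0]
    assert top["category_label"].endswith("sepsis") and top["flag"] == "red"
    assert table.iloc[1]["category_label"] == "I21"  # 400 + 50 aggregated
    assert table.iloc[1]["flag"] == "none"
    assert table.iloc[2]["flag"] == "orange"  # unspecified stroke, severity 4


def test_leading_causes_no_flags_when_all_usable(metadata):
    table = leading_causes(make_deaths([("male", "50-54", "I21", 10),
                                        ("male", "50-54", "C50", 5)]),
                           metadata, n=20)
    assert (table["flag"] == "none").all()
    assert len(table) == 2  # n larger than distinct categories -> full list


def test_every_death_lands_in_exactly_one_bin(metadata, perfect_fixture):
    deaths = perfect_fixture[0]
    dist = broad_group_distribution(deaths, metadata)
    assert sum(dist.counts.values()) == pytest.approx(deaths.total, abs=1e-9)
    usab = usability_distribution(deaths, metadata)
    assert sum(usab.counts.values()) == pytest.approx(deaths.total, abs=1e-9)
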