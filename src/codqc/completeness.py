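"""Death-registration completeness (two estimators plus a weighted summary).

The comparator method divides the observed crude death rate by an
externally estimated CDR for the same year (interpolated linearly along
the reference trend). The empirical method predicts the expected CDR
from the input data alone — child mortality, population ageing and
child-registration completeness — through a log-linear model whose
packaged coefficients are illustrative placeholders and should be
replaced with a fitted set for real-world use. Both estimates are capped
at one; the raw ratio is retained because over-registration relative to
the reference is itself diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ComparatorSet, DeathTable, InputError, PopulationTable, age_lower_bound

__all__ = [
    "CompletenessResult",
    "DEFAULT_EMPIRICAL_COEFFICIENTS",
    "completeness_from_comparator",
    "completeness_empirical",
    "weighted_completeness",
    "percent_aged_65_plus",
]

#: Illustrative log-linear coefficients for the empirical completeness
#: model: ln(expected CDR) = c0 + c1 ln(5q0) + c2 (% aged 65+) + c3 c_child.
#: Placeholders only — replace with coefficients fitted to reference data.
DEFAULT_EMPIRICAL_COEFFICIENTS = {"c0": 1.10, "c1": 0.15, "c2": 0.030, "c3": -0.05}


@dataclass(frozen=True)
class CompletenessResult:
    completeness: float      # capped at 1
    raw_ratio: float         # observed / expected CDR, uncapped
    cdr_observed: float      # per 1000
    cdr_expected: float      # per 1000
    method: str
    notes: tuple[str, ...] = ()


def completeness_from_comparator(cdr_observed: float, comparator: ComparatorSet,
                                 year: int) -> CompletenessResult:
    """Completeness as observed CDR over the reference-trend CDR.

    The expected CDR is linearly interpolated in ``year`` along the
    comparator trend; outside the trend the terminal value is used with a
    warning note. A ratio above one is capped with an over-complete note.
    """
    trend = comparator.cdr_trend
    years = np.asarray(trend.index, dtype=float)
    values = np.asarray(trend.values, dtype=float)
    notes = []
    if year < years[0] or year > years[-1]:
        notes.append(f"year {year} outside comparator trend "
                     f"[{int(years[0])}, {int(years[-1])}]; terminal value used")
    expected = float(np.interp(year, years, values))
    if expected <= 0:
        raise InputError("expected CDR from comparator trend is non-positive")
    ratio = cdr_observed / expected
    if ratio > 1:
        notes.append("observed CDR exceeds the comparator trend (over-complete "
                     "or reference too low); capped at 1")
    return CompletenessResult(
        completeness=min(1.0, ratio), raw_ratio=ratio,
        cdr_observed=cdr_observed, cdr_expected=expected,
        method="comparator", notes=tuple(notes),
    )


def percent_aged_65_plus(population: PopulationTable) -> float:
    """Percentage (0-100) of the population aged 65 and over."""
    df = population.data
    mask = [age_lower_bound(a) >= 65 for a in df["age_group"]]
    return 100.0 * float(df.loc[mask, "count"].sum()) / population.total


def completeness_empirical(deaths: DeathTable, population: PopulationTable,
                           child_completeness: float,
                           coefficients: dict | None = None) -> CompletenessResult:
    """Completeness from the input data alone (no external CDR trend).

    Predicts the CDR expected under full registration from the observed
    under-five mortality, the share of the population aged 65+, and the
    completeness of child death registration::

        CDR_pred = exp(c0 + c1 ln(5q0_obs) + c2 pct65 + c3 c_child)

    then takes observed/predicted, capped at one. 5q0_obs here is the
    uncorrected observed value recomputed from the under-five rows.
    """
    coef = dict(DEFAULT_EMPIRICAL_COEFFICIENTS)
    coef.update(coefficients or {})

    d = deaths.data
    p = population.data
    d0 = float(d.loc[d["age_group"] == "<1", "count"].sum())
    d1 = float(d.loc[d["age_group"] == "1-4", "count"].sum())
    p0 = float(p.loc[p["age_group"] == "<1", "count"].sum())
    p1 = float(p.loc[p["age_group"] == "1-4", "count"].sum())
    if p0 <= 0 or p1 <= 0:
        raise InputError("empirical model needs under-5 population rows")
    m0 = d0 / p0
    m1 = d1 / p1
    q1 = m0 / (1.0 + 0.7 * m0)
    q4 = 4.0 * m1 / (1.0 + 2.6 * m1)
    q5_obs = 1.0 - (1.0 - q1) * (1.0 - q4)
    if q5_obs <= 0:
        raise InputError("model undefined: observed 5q0 is zero")

    pct65 = percent_aged_65_plus(population)
    predicted = float(np.exp(coef["c0"] + coef["c1"] * np.log(q5_obs)
                             + coef["c2"] * pct65
                             + coef["c3"] * child_completeness))
    cdr_obs = 1000.0 * deaths.total / population.total
    ratio = cdr_obs / predicted
    notes = [f"coefficients: {coef}"]
    if ratio > 1:
        notes.append("observed CDR exceeds model prediction; capped at 1")
    return CompletenessResult(
        completeness=min(1.0, ratio), raw_ratio=ratio,
        cdr_observed=cdr_obs, cdr_expected=predicted,
        method="empirical", notes=tuple(notes),
    )


def weighted_completeness(c_under5: float, c_adult: float,
                          deaths_under5_hat: float,
                          deaths_5plus_hat: float) -> float:
    """Single completeness figure weighted by estimated deaths per age block.

    ``deaths_*_hat`` are the *estimated* (envelope) numbers of deaths in
    the under-five and five-plus blocks, e.g. from the comparator source.
    """
    total = deaths_under5_hat + deaths_5plus_hat
    if total <= 0:
        raise InputError("estimated death envelope is zero")
    return (c_under5 * deaths_under5_hat + c_adult * deaths_5plus_hat) / total
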