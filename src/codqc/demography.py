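"""Age/sex structure, mortality rates, consistency checks, child mortality.

Implements the all-cause demographic diagnostics:

* age/sex tabulations of deaths and population (pyramid tables);
* the crude death rate;
* age-specific death rates m_x and the log-linearity (Gompertz-Makeham)
  check on ln(m_x) above a configurable age floor;
* the excess-female-mortality screen;
* under-five mortality: 1q0, 4q1 and 5q0 from m0/m1 via the standard
  rate-to-probability conversion with separation factors, the neonatal
  split when detail is available, and completeness of child death
  registration against an external 5q0 estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    UNKNOWN, MALE, FEMALE, NEONATAL_COLUMNS,
    ComparatorSet, DeathTable, InputError, PopulationTable,
    age_lower_bound, age_midpoint,
)

__all__ = [
    "tabulate_age_sex",
    "crude_death_rate",
    "age_specific_rates",
    "LogLinearityResult",
    "log_linearity_check",
    "SexPatternResult",
    "sex_pattern_check",
    "ChildMortalityResult",
    "child_mortality",
]


def tabulate_age_sex(table) -> pd.DataFrame:
    """Counts and within-sex percentages by age group (pyramid table).

    Works for both death and population tables; an ``unknown`` age row is
    kept as its own line. Percentages sum to 100 within each sex panel.
    """
    if table.total <= 0:
        raise InputError("cannot tabulate an empty table")
    df = (table.data.groupby(["sex", "age_group"], as_index=False, sort=False)
          ["count"].sum())
    order = {lab: i for i, lab in enumerate(table.ladder)}
    df = df.sort_values(["sex", "age_group"],
                        key=lambda s: s.map(order) if s.name == "age_group" else s,
                        kind="mergesort").reset_index(drop=True)
    totals = df.groupby("sex")["count"].transform("sum")
    df["percent"] = 100.0 * df["count"] / totals
    return df


def crude_death_rate(deaths: DeathTable, population: PopulationTable) -> float:
    """Crude death rate per 1000: 1000 * total deaths / total population.

    Unknown-age and unknown-sex deaths stay in the numerator — the CDR
    measures registration volume, not an age-specific risk.
    """
    p = population.total
    if p <= 0:
        raise InputError("total population is zero")
    return 1000.0 * deaths.total / p


def age_specific_rates(deaths: DeathTable, population: PopulationTable,
                       open_interval_offset: float = 2.5) -> pd.DataFrame:
    """Death rates m_x per (sex, age group).

    Unknown-age/sex deaths are excluded from numerators (rates describe
    the reported data; nothing is redistributed before the checks). Bands
    with zero population but nonzero deaths are flagged as anomalies
    rather than divided; ``log_rate`` is defined only where m_x > 0.
    """
    d = (deaths.known_age_sex().groupby(["sex", "age_group"])["count"]
         .sum())
    p = population.data.groupby(["sex", "age_group"])["count"].sum()
    ladder = [a for a in population.ladder if a != UNKNOWN]
    rows = []
    for sex in (MALE, FEMALE):
        for age in ladder:
            dx = float(d.get((sex, age), 0.0))
            px = float(p.get((sex, age), 0.0))
            if px > 0:
                m = dx / px
                flag = ""
            else:
                m = np.nan
                flag = "zero_population" if dx > 0 else "empty"
            rows.append({
                "sex": sex, "age_group": age,
                "midpoint": age_midpoint(age, open_interval_offset),
                "deaths": dx, "population": px, "rate": m,
                "log_rate": np.log(m) if px > 0 and m > 0 else np.nan,
                "flag": flag,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LogLinearityResult:
    sex: str
    slope: float
    intercept: float
    r_squared: float
    n_bands: int
    non_monotone: tuple[str, ...]  # bands whose rate drops below the previous


def log_linearity_check(rates: pd.DataFrame, sex: str | None = None,
                        min_age: float = 30.0) -> LogLinearityResult:
    """Fit ln(m_x) on age midpoints above ``min_age`` by least squares.

    Adult death rates rise roughly exponentially with age (the
    Gompertz-Makeham regularity), so the log rates should be close to a
    straight line; a low R-squared or a band whose rate falls below its
    younger neighbour points at age misreporting. Requires at least four
    bands with positive rates at or above ``min_age``.
    """
    df = rates if sex is None else rates[rates["sex"] == sex]
    df = df[[age_lower_bound(a) >= min_age for a in df["age_group"]]]
    if sex is None and df["sex"].nunique() > 1:
        # combined-sex fit: pool deaths and exposures per band
        df = (df.groupby(["age_group", "midpoint"], as_index=False)
              [["deaths", "population"]].sum())
        df["rate"] = np.where(df["population"] > 0,
                              df["deaths"] / df["population"], np.nan)
        df["log_rate"] = np.where(df["rate"] > 0, np.log(df["rate"]), np.nan)
    df = df.sort_values("midpoint")
    usable = df[np.isfinite(df["log_rate"])]
    if len(usable) < 4:
        raise InputError("insufficient_data: need >=4 positive-rate bands "
                         f"at or above age {min_age}")
    fit = stats.linregress(usable["midpoint"], usable["log_rate"])
    drops = tuple(
        str(df["age_group"].iloc[i])
        for i in range(1, len(df))
        if np.isfinite(df["rate"].iloc[i]) and np.isfinite(df["rate"].iloc[i - 1])
        and df["rate"].iloc[i] < df["rate"].iloc[i - 1]
    )
    return LogLinearityResult(
        sex=sex or "both", slope=float(fit.slope),
        intercept=float(fit.intercept), r_squared=float(fit.rvalue ** 2),
        n_bands=len(usable), non_monotone=drops,
    )


@dataclass(frozen=True)
class SexPatternResult:
    flagged: tuple[str, ...]        # age >= 5 bands with female rate > male
    under5_female_excess: tuple[str, ...]  # reported separately, not flagged
    ratios: pd.DataFrame = field(compare=False, default=None)


def sex_pattern_check(rates: pd.DataFrame, tolerance: float = 0.0) -> SexPatternResult:
    """Flag age bands where the female death rate exceeds the male rate.

    Excess female mortality is rare at any age; above age five it is
    flagged outright, while the under-five bands (where small numbers and
    genuine biology blur the signal) are reported separately. ``tolerance``
    is a relative margin: flag when m_f > m_m * (1 + tolerance).
    """
    wide = rates.pivot_table(index=["age_group", "midpoint"], columns="sex",
                             values="rate").reset_index().sort_values("midpoint")
    if MALE not in wide.columns or FEMALE not in wide.columns:
        raise InputError("sex_pattern_check needs rates for both sexes")
    excess = (np.isfinite(wide[FEMALE]) & np.isfinite(wide[MALE])
              & (wide[FEMALE] > wide[MALE] * (1.0 + tolerance)))
    under5 = np.array([age_lower_bound(a) < 5 for a in wide["age_group"]])
    wide["ratio_f_to_m"] = wide[FEMALE] / wide[MALE]
    return SexPatternResult(
        flagged=tuple(wide.loc[excess & ~under5, "age_group"]),
        under5_female_excess=tuple(wide.loc[excess & under5, "age_group"]),
        ratios=wide[["age_group", "midpoint", MALE, FEMALE, "ratio_f_to_m"]],
    )


@dataclass(frozen=True)
class ChildMortalityResult:
    q1_0: float          # 1q0, probability of dying before age 1
    q4_1: float          # 4q1, probability of dying between 1 and 5
    q5_0: float          # 5q0 = 1 - (1-1q0)(1-4q1)
    comparator_q5_0: float
    child_completeness: float   # min(1, observed 5q0 / comparator 5q0)
    raw_ratio: float
    neonatal_split: "dict[str, float] | None"  # fractions of under-5 deaths


def child_mortality(deaths: DeathTable, population: PopulationTable,
                    comparator: ComparatorSet,
                    a0: float = 0.3, a1: float = 1.4) -> ChildMortalityResult:
    """Under-five mortality from the input data, against the external 5q0.

    Converts the observed rates m0 (under 1) and m1 (ages 1-4) into
    probabilities with the standard separation factors a0, a1::

        1q0 = m0 / (1 + (1 - a0) m0)
        4q1 = 4 m1 / (1 + (4 - a1) m1)

    and combines them multiplicatively into 5q0. Child-registration
    completeness is the observed-to-estimated 5q0 ratio, capped at one.
    When neonatal detail is present on the ``<1`` rows, the early/late/
    post-neonatal and 1-4 fractions of all under-five deaths are reported.
    """
    d = deaths.data
    p = population.data
    d0 = float(d.loc[d["age_group"] == "<1", "count"].sum())
    d1 = float(d.loc[d["age_group"] == "1-4", "count"].sum())
    p0 = float(p.loc[p["age_group"] == "<1", "count"].sum())
    p1 = float(p.loc[p["age_group"] == "1-4", "count"].sum())
    if p0 <= 0 or p1 <= 0:
        raise InputError("missing under-5 population rows")
    if "<1" not in set(d["age_group"]) or "1-4" not in set(d["age_group"]):
        raise InputError("missing under-5 death rows")
    if comparator.u5mr_estimate <= 0:
        raise InputError("comparator 5q0 must be positive")

    m0, m1 = d0 / p0, d1 / p1
    q1 = m0 / (1.0 + (1.0 - a0) * m0)
    q4 = 4.0 * m1 / (1.0 + (4.0 - a1) * m1)
    q5 = 1.0 - (1.0 - q1) * (1.0 - q4)
    ratio = q5 / comparator.u5mr_estimate

    split = None
    if all(c in d.columns for c in NEONATAL_COLUMNS) and (d0 + d1) > 0:
        infant = d[d["age_group"] == "<1"]
        u5 = d0 + d1
        early = float(infant["early_neonatal"].sum())
        late = float(infant["late_neonatal"].sum())
        post = float(infant["post_neonatal"].sum())
        split = {"early_neonatal": early / u5, "late_neonatal": late / u5,
                 "post_neonatal": post / u5, "1-4": d1 / u5}
    return ChildMortalityResult(
        q1_0=q1, q4_1=q4, q5_0=q5,
        comparator_q5_0=comparator.u5mr_estimate,
        child_completeness=min(1.0, ratio), raw_ratio=ratio,
        neonatal_split=split,
    )
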