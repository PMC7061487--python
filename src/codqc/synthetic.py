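"""Synthetic death/population/comparator fixtures with known truth.

The generator builds a population on the standard age ladder, draws
deaths from a Gompertz-Makeham hazard (lambda + alpha e^{beta x}) above
age five with separate child rates m0/m1, assigns causes from
age-profiled mixtures over the three broad groups mapped onto a
192-cause reference list, and then *degrades* the perfect dataset along
the five quality dimensions the assessment measures: incomplete
registration, garbage coding by severity level, missing age/sex, and
biologically implausible records. Every choice is written to a
:class:`TruthLog` so recovery tests have an exact reference; a
deterministic expected-value mode exists alongside the Poisson mode so
that recovery can be tested exactly.

The generator emulates the *statistical* shape of national mortality
data, not any real country's profile.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    FEMALE, MALE, UNKNOWN, NEONATAL_COLUMNS,
    ComparatorSet, DeathTable, InputError, PopulationTable,
    age_ladder, age_midpoint,
)

__all__ = [
    "AgeStructure",
    "MortalitySchedule",
    "CauseModel",
    "DefectConfig",
    "TruthLog",
    "default_cause_model",
    "largest_remainder",
    "generate_population",
    "fraction_65_plus",
    "generate_true_deaths",
    "degrade",
    "make_comparators",
    "generate_dataset",
]


def largest_remainder(weights, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``.

    Floors the exact quotas and hands the remaining units to the largest
    fractional parts (ties to the lower index), so the result always sums
    to ``total`` and each cell is within one unit of its exact quota.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise InputError("negative weights")
    total = int(round(total))
    if total < 0:
        raise InputError("negative total")
    if w.sum() <= 0 or total == 0:
        return np.zeros(len(w), dtype=int)
    quota = w / w.sum() * total
    out = np.floor(quota).astype(int)
    short = total - int(out.sum())
    if short > 0:
        frac = quota - out
        order = np.lexsort((np.arange(len(w)), -frac))
        out[order[:short]] += 1
    return out


@dataclass(frozen=True)
class AgeStructure:
    """One-parameter age pyramid: band weight proportional to e^{-rho x}.

    Larger ``rho`` gives a younger (steeper) pyramid; at the default
    rho = 0.02 roughly one person in ten is aged 65+.
    """

    rho: float = 0.02
    male_share: float = 0.5

    def __post_init__(self):
        if self.rho <= 0 or not 0 < self.male_share < 1:
            raise InputError("invalid age-structure parameters")


@dataclass(frozen=True)
class MortalitySchedule:
    """Gompertz-Makeham hazard above age five, flat child rates below.

    m(x) = lam + alpha e^{beta x} per person-year at band midpoint x;
    m0 and m1 are the under-1 and 1-4 rates. Male rates are the base
    times ``sex_ratio``, female rates the base divided by it, so male
    mortality exceeds female mortality at every age.
    """

    lam: float = 2.0e-4
    alpha: float = 2.0e-5
    beta: float = 0.095
    m0: float = 0.025
    m1: float = 0.0015
    sex_ratio: float = 1.15

    def __post_init__(self):
        if min(self.alpha, self.beta, self.m0, self.m1) <= 0 or self.lam < 0:
            raise InputError("schedule rates must be positive")

    def base_rate(self, age_group: str) -> float:
        if age_group == "<1":
            return self.m0
        if age_group == "1-4":
            return self.m1
        return self.lam + self.alpha * np.exp(self.beta * age_midpoint(age_group))

    def rate(self, age_group: str, sex: str) -> float:
        base = self.base_rate(age_group)
        return base * self.sex_ratio if sex == MALE else base / self.sex_ratio


def default_cause_model() -> "CauseModel":
    """The bundled 192-cause model over the three broad groups.

    60 communicable/maternal/nutritional causes (group1), 100
    non-communicable (group2), 32 injury causes (group3), each
    represented by a distinct 3-character ICD-10 category; cause weights
    are uniform within a group. None of the codes is sex- or
    age-restricted, so undegraded data passes every plausibility rule.
    """
    def rng_codes(letter, lo, hi):
        return [f"{letter}{i:02d}" for i in range(lo, hi + 1)]

    group1 = rng_codes("A", 0, 39) + rng_codes("B", 5, 24)
    group2 = (rng_codes("C", 0, 49) + rng_codes("E", 10, 14)
              + rng_codes("F", 1, 5) + rng_codes("I", 20, 25)
              + rng_codes("I", 60, 63) + rng_codes("J", 40, 44)
              + rng_codes("K", 70, 74) + rng_codes("N", 0, 19))
    group3 = rng_codes("V", 1, 9) + rng_codes("W", 0, 19) + rng_codes("X", 60, 62)
    profile = {}
    for band in age_ladder(include_unknown=False):
        lo = 0.0 if band == "<1" else float(band.rstrip("+").split("-")[0])
        if band == "<1":
            mix = (0.80, 0.18, 0.02)
        elif band == "1-4":
            mix = (0.70, 0.25, 0.05)
        elif lo < 15:
            mix = (0.45, 0.35, 0.20)
        elif lo < 30:
            mix = (0.15, 0.25, 0.60)
        elif lo < 45:
            mix = (0.15, 0.55, 0.30)
        elif lo < 65:
            mix = (0.10, 0.80, 0.10)
        else:
            mix = (0.06, 0.92, 0.02)
        profile[band] = mix
    return CauseModel(group_codes={"group1": tuple(group1),
                                   "group2": tuple(group2),
                                   "group3": tuple(group3)},
                      age_profile=profile)


@dataclass(frozen=True)
class CauseModel:
    """Cause mixture: codes per broad group and group shares per age band."""

    group_codes: dict[str, tuple[str, ...]]
    age_profile: dict[str, tuple[float, float, float]]

    @property
    def reference_cause_list(self) -> tuple[str, ...]:
        return tuple(c for g in ("group1", "group2", "group3")
                     for c in self.group_codes[g])

    def cause_weights(self, band: str) -> tuple[list[str], np.ndarray]:
        mix = self.age_profile[band]
        codes, weights = [], []
        for share, group in zip(mix, ("group1", "group2", "group3")):
            members = self.group_codes[group]
            codes.extend(members)
            weights.extend([share / len(members)] * len(members))
        return codes, np.asarray(weights)


@dataclass(frozen=True)
class DefectConfig:
    """Quality defects applied to a perfect dataset, in a fixed order.

    1. thinning to ``completeness`` (under-five rows use
       ``completeness_under5`` when given — child deaths are typically
       the most under-counted);
    2. recoding of a fraction of the remaining deaths to garbage, by
       severity level (``garbage`` = fractions for levels 1..4);
    3. blanking of age (``missing_age``) and sex (``missing_sex``);
    4. recoding of a fraction to biologically implausible age/sex-cause
       combinations (``implausible``).

    All fractions are of the death total at the moment the step runs.
    """

    completeness: float = 1.0
    completeness_under5: float | None = None
    garbage: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    missing_age: float = 0.0
    missing_sex: float = 0.0
    implausible: float = 0.0

    def __post_init__(self):
        fracs = [self.completeness, *self.garbage, self.missing_age,
                 self.missing_sex, self.implausible]
        if self.completeness_under5 is not None:
            fracs.append(self.completeness_under5)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise InputError("defect fractions must lie in [0, 1]")
        if sum(self.garbage) > 1.0:
            raise InputError("garbage fractions sum to more than 1")


#: Representative garbage code injected for each severity level, with the
#: broad groups it can plausibly arise from (its redistribution targets in
#: the default metadata). Garbage is recoded *from* deaths in those groups
#: so that redistribution with the true targets can undo the injection.
GARBAGE_REPRESENTATIVES = {1: "A41", 2: "I10", 3: "C80", 4: "I64"}
GARBAGE_SOURCE_GROUPS = {1: ("group1", "group2", "group3"),
                         2: ("group2",), 3: ("group2",), 4: ("group2",)}

#: Fractions of under-1 deaths by neonatal period (early, late, post).
NEONATAL_FRACTIONS = (0.35, 0.15, 0.50)


@dataclass
class TruthLog:
    """Everything needed to score a synthetic dataset against its truth."""

    seed: int
    mode: str
    year: int
    structure: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    population_total: int = 0
    true_death_total: int = 0
    true_cdr: float = 0.0            # per 1000, from the realized true deaths
    true_q5: float = 0.0             # 5q0 from realized child rates (a0=.3, a1=1.4)
    true_group_fractions: dict = field(default_factory=dict)
    reference_cause_list: tuple = ()
    defects: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def log(self, event: str, **detail) -> None:
        self.events.append({"event": event, **detail})

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["reference_cause_list"] = list(self.reference_cause_list)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def generate_population(size: int, structure: AgeStructure = AgeStructure(),
                        seed: int = 0, year: int = 2015) -> PopulationTable:
    """Deterministic population of ``size`` people on the age ladder.

    Band weights follow e^{-rho x}; people are apportioned by largest
    remainder over the sex-by-band cells, so the table is byte-identical
    for identical parameters (the seed is accepted for interface
    symmetry but the construction is exact).
    """
    if size <= 0:
        raise InputError("population size must be positive")
    bands = age_ladder(include_unknown=False)
    w = np.array([np.exp(-structure.rho * age_midpoint(b)) for b in bands])
    cells = []
    weights = []
    for sex, share in ((MALE, structure.male_share),
                       (FEMALE, 1.0 - structure.male_share)):
        for band, wb in zip(bands, w):
            cells.append((sex, band))
            weights.append(share * wb)
    counts = largest_remainder(weights, size)
    rows = [{"year": year, "sex": s, "age_group": b, "count": int(c)}
            for (s, b), c in zip(cells, counts)]
    return PopulationTable(pd.DataFrame(rows))


def fraction_65_plus(structure: AgeStructure, open_age: int = 85) -> float:
    """Closed-form share of the population aged 65+ under the structure model."""
    bands = age_ladder(open_age, include_unknown=False)
    w = np.array([np.exp(-structure.rho * age_midpoint(b)) for b in bands])
    old = np.array([b != "<1" and b != "1-4"
                    and float(b.rstrip("+").split("-")[0]) >= 65 for b in bands])
    return float(w[old].sum() / w.sum())


def generate_true_deaths(population: PopulationTable,
                         schedule: MortalitySchedule = MortalitySchedule(),
                         cause_model: CauseModel | None = None,
                         seed: int = 0, mode: str = "deterministic",
                         neonatal_detail: bool = True
                         ) -> tuple[DeathTable, TruthLog]:
    """Draw fully-registered, perfectly-coded deaths from the schedule.

    In ``deterministic`` mode each band's death count is the rounded
    expectation P_x m_x and causes are apportioned by largest remainder;
    in ``poisson`` mode counts are Poisson draws and causes multinomial.
    """
    if mode not in ("deterministic", "poisson"):
        raise InputError(f"unknown mode {mode!r}")
    cause_model = cause_model or default_cause_model()
    rng = np.random.default_rng(seed)
    pop = population.data
    year = int(pop["year"].iloc[0])

    rows = []
    band_deaths: dict[tuple[str, str], int] = {}
    for rec in pop.itertuples(index=False):
        m = schedule.rate(rec.age_group, rec.sex)
        expected = rec.count * m
        d = (int(round(expected)) if mode == "deterministic"
             else int(rng.poisson(expected)))
        band_deaths[(rec.sex, rec.age_group)] = d
        if d == 0:
            continue
        codes, weights = cause_model.cause_weights(rec.age_group)
        if mode == "deterministic":
            alloc = largest_remainder(weights, d)
        else:
            alloc = rng.multinomial(d, weights / weights.sum())
        for code, k in zip(codes, alloc):
            if k > 0:
                rows.append({"year": year, "sex": rec.sex,
                             "age_group": rec.age_group, "icd_code": code,
                             "count": int(k)})
    df = pd.DataFrame(rows)
    if neonatal_detail and not df.empty:
        df = _apply_neonatal_detail(df)
    deaths = DeathTable(df, ladder=population.ladder)

    truth = TruthLog(seed=seed, mode=mode, year=year,
                     structure={}, schedule=dataclasses.asdict(schedule),
                     population_total=int(population.total),
                     reference_cause_list=cause_model.reference_cause_list)
    _record_truth(truth, deaths, population)
    truth.log("generate_true_deaths", mode=mode, total=int(deaths.total))
    return deaths, truth


def _apply_neonatal_detail(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in NEONATAL_COLUMNS:
        df[col] = 0.0
    mask = df["age_group"] == "<1"
    fr = list(NEONATAL_FRACTIONS)
    for idx in df.index[mask]:
        split = largest_remainder(fr, int(df.at[idx, "count"]))
        for col, v in zip(NEONATAL_COLUMNS, split):
            df.at[idx, col] = float(v)
    return df


def _record_truth(truth: TruthLog, deaths: DeathTable,
                  population: PopulationTable,
                  cause_model: CauseModel | None = None) -> None:
    d, p = deaths.data, population.data
    truth.true_death_total = int(deaths.total)
    truth.true_cdr = 1000.0 * deaths.total / population.total
    d0 = float(d.loc[d["age_group"] == "<1", "count"].sum())
    d1 = float(d.loc[d["age_group"] == "1-4", "count"].sum())
    p0 = float(p.loc[p["age_group"] == "<1", "count"].sum())
    p1 = float(p.loc[p["age_group"] == "1-4", "count"].sum())
    m0, m1 = d0 / p0, d1 / p1
    q1 = m0 / (1.0 + 0.7 * m0)
    q4 = 4.0 * m1 / (1.0 + 2.6 * m1)
    truth.true_q5 = 1.0 - (1.0 - q1) * (1.0 - q4)
    model = cause_model or default_cause_model()
    code_group = {c: g for g, codes in model.group_codes.items() for c in codes}
    by_group = {"group1": 0.0, "group2": 0.0, "group3": 0.0}
    for rec in d.itertuples(index=False):
        g = code_group.get(rec.icd_code[:3])
        if g:
            by_group[g] += rec.count
    tot = sum(by_group.values()) or 1.0
    truth.true_group_fractions = {g: v / tot for g, v in by_group.items()}


def _remove_from_rows(df: pd.DataFrame, mask: np.ndarray, target: float,
                      mode: str, rng) -> np.ndarray:
    """How many deaths to take from each masked row (array over all rows).

    ``target`` is the expected total removal; deterministic mode hits
    round(target) exactly by largest remainder, Poisson mode draws
    per-death Bernoulli removals at probability target / eligible mass.
    """
    take = np.zeros(len(df), dtype=int)
    counts = df.loc[mask, "count"].to_numpy()
    eligible = counts.sum()
    if eligible <= 0 or target <= 0:
        return take
    if mode == "deterministic":
        goal = min(int(round(target)), int(eligible))
        take[np.where(mask)[0]] = largest_remainder(counts, goal)
    else:
        p = min(1.0, target / eligible)
        take[np.where(mask)[0]] = rng.binomial(counts.astype(int), p)
    return take


def degrade(deaths: DeathTable, defects: DefectConfig, seed: int = 0,
            mode: str = "deterministic",
            truth: TruthLog | None = None) -> tuple[DeathTable, TruthLog]:
    """Apply quality defects to a perfect death table, in the fixed order
    thinning -> garbage recoding -> age/sex blanking -> implausible
    injection. Deterministic mode hits each target count exactly (up to
    rounding); Poisson mode thins and recodes binomially. Garbage and
    implausible steps *recode* existing deaths, so after thinning the
    total is preserved.
    """
    if mode not in ("deterministic", "poisson"):
        raise InputError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed + 1)
    df = deaths.data.copy().reset_index(drop=True)
    if truth is None:
        truth = TruthLog(seed=seed, mode=mode, year=int(df["year"].iloc[0]))
    truth.defects = dataclasses.asdict(defects)

    def total() -> int:
        return int(df["count"].sum())

    # 1. thinning by (age-differential) completeness
    under5 = df["age_group"].isin(["<1", "1-4"]).to_numpy()
    for mask, c in ((under5, defects.completeness_under5
                     if defects.completeness_under5 is not None
                     else defects.completeness),
                    (~under5, defects.completeness)):
        if c < 1.0 and mask.any():
            block = int(df.loc[mask, "count"].sum())
            take = _remove_from_rows(df, mask, block * (1.0 - c), mode, rng)
            df["count"] = df["count"] - take
            truth.log("thinning", completeness=c, removed=int(take.sum()))

    # 2. garbage recoding by severity level, taken from deaths whose true
    #    broad group is a plausible origin of the injected code
    model = default_cause_model()
    code_group = {c: g for g, codes in model.group_codes.items() for c in codes}
    for level, frac in zip((1, 2, 3, 4), defects.garbage):
        if frac <= 0:
            continue
        tgt_code = GARBAGE_REPRESENTATIVES[level]
        sources = set(GARBAGE_SOURCE_GROUPS[level])
        recodable = ((df["count"] > 0)
                     & df["icd_code"].str[:3].map(
                         lambda c: code_group.get(c) in sources)).to_numpy()
        take = _remove_from_rows(df, recodable, total() * frac, mode, rng)
        df["count"] = df["count"] - take
        moved = df.loc[take > 0, ["year", "sex", "age_group"]].copy()
        moved["icd_code"] = tgt_code
        moved["count"] = take[take > 0]
        df = pd.concat([df, moved], ignore_index=True)
        truth.log("garbage_recode", severity=level, code=tgt_code,
                  recoded=int(take.sum()))

    # 3. blanking age, then sex (never both on the same death)
    for column, value, frac in (("age_group", UNKNOWN, defects.missing_age),
                                ("sex", UNKNOWN, defects.missing_sex)):
        if frac <= 0:
            continue
        eligible = ((df["count"] > 0) & (df["age_group"] != UNKNOWN)
                    & (df["sex"] != UNKNOWN)).to_numpy()
        take = _remove_from_rows(df, eligible, total() * frac, mode, rng)
        df["count"] = df["count"] - take
        moved = df.loc[take > 0, ["year", "sex", "age_group", "icd_code"]].copy()
        moved[column] = value
        moved["count"] = take[take > 0]
        df = pd.concat([df, moved], ignore_index=True)
        truth.log("blank_" + column, fraction=frac, blanked=int(take.sum()))

    # 4. implausible injection: recode adult male deaths to a maternal cause
    if defects.implausible > 0:
        eligible = ((df["count"] > 0) & (df["sex"] == MALE)
                    & (df["age_group"] != UNKNOWN)
                    & (~df["age_group"].isin(["<1", "1-4", "5-9"]))).to_numpy()
        take = _remove_from_rows(df, eligible, total() * defects.implausible,
                                 mode, rng)
        df["count"] = df["count"] - take
        moved = df.loc[take > 0, ["year", "sex", "age_group"]].copy()
        moved["icd_code"] = "O85"
        moved["count"] = take[take > 0]
        df = pd.concat([df, moved], ignore_index=True)
        truth.log("implausible", fraction=defects.implausible,
                  injected=int(take.sum()))

    df = df[df["count"] > 0].reset_index(drop=True)
    has_detail = all(c in df.columns for c in NEONATAL_COLUMNS)
    if has_detail:
        df = df.drop(columns=list(NEONATAL_COLUMNS))
        df = _apply_neonatal_detail(df)
    degraded = DeathTable(df, ladder=deaths.ladder)
    truth.log("degrade_done", total=int(degraded.total))
    return degraded, truth


def make_comparators(truth: TruthLog, trend_halfwidth: int = 15,
                     trend_step: int = 5, drift: float = -0.004
                     ) -> ComparatorSet:
    """Comparator set computed from the undegraded truth.

    The CDR trend is a straight line through the true CDR at the data
    year (relative slope ``drift`` per year, mimicking slow mortality
    decline), the 5q0 estimate and broad-group envelope are the realized
    true values, and the reference cause list is the generator's 192
    causes — so a perfect dataset scores completeness and plausibility
    of exactly one against its own comparators.
    """
    if truth.true_cdr <= 0:
        raise InputError("truth log has no realized CDR")
    years = range(truth.year - trend_halfwidth, truth.year + trend_halfwidth + 1,
                  trend_step)
    trend = [{"year": y, "cdr": truth.true_cdr * (1.0 + drift * (y - truth.year))}
             for y in years]
    env = dict(truth.true_group_fractions)
    s = sum(env.values())
    env = {k: v / s for k, v in env.items()}
    return ComparatorSet(
        cdr_trend=pd.Series({r["year"]: r["cdr"] for r in trend}).sort_index(),
        u5mr_estimate=truth.true_q5, u5mr_year=truth.year,
        broad_group_envelope=env,
        reference_cause_list=truth.reference_cause_list,
    )


def generate_dataset(seed: int = 0, size: int = 1_000_000,
                     structure: AgeStructure = AgeStructure(),
                     schedule: MortalitySchedule = MortalitySchedule(),
                     defects: DefectConfig = DefectConfig(),
                     mode: str = "deterministic", year: int = 2015):
    """One-call fixture: population, degraded deaths, comparators, truth."""
    population = generate_population(size, structure, seed=seed, year=year)
    true_deaths, truth = generate_true_deaths(population, schedule,
                                              seed=seed, mode=mode)
    truth.structure = dataclasses.asdict(structure)
    degraded, truth = degrade(true_deaths, defects, seed=seed, mode=mode,
                              truth=truth)
    comparators = make_comparators(truth)
    return degraded, population, comparators, truth
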