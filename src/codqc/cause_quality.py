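"""Cause-of-death quality: usability, garbage typologies, redistribution.

A recorded underlying cause is *usable* when it maps to one of the three
broad cause groups (group1 communicable/maternal/neonatal/nutritional,
group2 non-communicable, group3 injuries); it is *garbage* when it is
unusable as an underlying cause or insufficiently specified. Garbage is
classified along two axes:

* the ICD-error typology (five categories: 1 symptoms/ill-defined,
  2 impossible as underlying cause, 3 intermediate, 4 immediate,
  5 insufficiently specified), which says *why* the code is wrong;
* the severity-of-impact typology (four levels, 1 worst: the true cause
  could sit in more than one broad group, down to 4: confined to a single
  disease category), which says *how much* the error can distort the
  cause-of-death picture.

Similar garbage codes are grouped into named packages (e.g. ``sepsis``)
so certification-improvement work can target the codes physicians
actually misuse. A configurable proportional scheme redistributes garbage
deaths onto the broad groups to show the plausible corrected picture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CodeMetadataTable, ComparatorSet, DeathTable, InputError

__all__ = [
    "BROAD_GROUPS",
    "BINS",
    "CodeClassification",
    "classify_code",
    "CauseDistribution",
    "usability_distribution",
    "broad_group_distribution",
    "epi_transition_measure",
    "typology_distributions",
    "PackageReport",
    "extract_packages",
    "redistribute_garbage",
    "leading_causes",
]

BROAD_GROUPS = ("group1", "group2", "group3")
#: Every death lands in exactly one of these five bins.
BINS = BROAD_GROUPS + ("unusable", "insufficiently_specified")


@dataclass(frozen=True)
class CodeClassification:
    code: str
    usability: str
    broad_group: str            # 'none' for garbage
    icd_error_category: "int | None"
    severity_level: "int | None"
    package: "str | None"
    redistribution_targets: frozenset

    @property
    def is_garbage(self) -> bool:
        return self.usability != "usable"


def classify_code(code: str, metadata: CodeMetadataTable) -> CodeClassification:
    """Full classification of a normalized ICD-10 code (total function).

    Codes absent from the metadata, and the ``missing`` pseudo-code, get
    the documented default (insufficiently specified, category 5,
    severity 3) with a warning.
    """
    if code == "missing":
        from .data_io import UNMAPPED_DEFAULT
        return CodeClassification(code=code, **UNMAPPED_DEFAULT)
    row = metadata.lookup(code)
    return CodeClassification(
        code=code, usability=row.usability, broad_group=row.broad_group,
        icd_error_category=row.icd_error_category,
        severity_level=row.severity_level, package=row.package,
        redistribution_targets=row.redistribution_targets,
    )


def _classified_frame(deaths: DeathTable, metadata: CodeMetadataTable) -> pd.DataFrame:
    """Death rows annotated with their classification columns (cached)."""
    df = deaths.data.copy()
    cache: dict[str, CodeClassification] = {}
    cols = {"usability": [], "broad_group": [], "category": [], "severity": [],
            "package": [], "bin": []}
    for code in df["icd_code"]:
        cls = cache.get(code)
        if cls is None:
            cls = cache[code] = classify_code(code, metadata)
        cols["usability"].append(cls.usability)
        cols["broad_group"].append(cls.broad_group)
        cols["category"].append(cls.icd_error_category)
        cols["severity"].append(cls.severity_level)
        cols["package"].append(cls.package)
        cols["bin"].append(cls.broad_group if cls.usability == "usable"
                           else cls.usability)
    for k, v in cols.items():
        df[k] = v
    df["targets"] = [cache[c].redistribution_targets for c in df["icd_code"]]
    return df


@dataclass(frozen=True)
class CauseDistribution:
    """Counts and fractions of deaths over the five classification bins."""

    counts: dict[str, float]
    fractions: dict[str, float]
    total: float
    by_age: pd.DataFrame | None = field(default=None, compare=False)

    @classmethod
    def from_counts(cls, counts: dict[str, float],
                    by_age: pd.DataFrame | None = None) -> "CauseDistribution":
        total = float(sum(counts.values()))
        if total <= 0:
            raise InputError("empty death table: no distribution")
        fractions = {k: v / total for k, v in counts.items()}
        return cls(counts=dict(counts), fractions=fractions, total=total,
                   by_age=by_age)


def usability_distribution(deaths: DeathTable,
                           metadata: CodeMetadataTable) -> CauseDistribution:
    """Three-way split: usable / unusable / insufficiently specified."""
    df = _classified_frame(deaths, metadata)
    counts = {k: 0.0 for k in ("usable", "unusable", "insufficiently_specified")}
    for k, v in df.groupby("usability")["count"].sum().items():
        counts[k] = float(v)
    return CauseDistribution.from_counts(counts)


def broad_group_distribution(deaths: DeathTable, metadata: CodeMetadataTable,
                             by_age: bool = False) -> CauseDistribution:
    """Five-way split over broad groups and the two garbage classes.

    With ``by_age`` the same split is also returned per age band; the
    age-band counts sum to the overall counts (unknown age is a band of
    its own, so nothing is lost).
    """
    df = _classified_frame(deaths, metadata)
    counts = {k: 0.0 for k in BINS}
    for k, v in df.groupby("bin")["count"].sum().items():
        counts[k] = float(v)
    age_table = None
    if by_age:
        age_table = (df.pivot_table(index="age_group", columns="bin",
                                    values="count", aggfunc="sum", fill_value=0.0)
                     .reindex(columns=BINS, fill_value=0.0)
                     .reindex(deaths.ladder).dropna(how="all"))
        age_table = age_table.fillna(0.0)
    return CauseDistribution.from_counts(counts, by_age=age_table)


def epi_transition_measure(dist: CauseDistribution,
                           comparator: ComparatorSet) -> dict:
    """Share of group1 among group1+group2 deaths, against the envelope.

    The ratio G1/(G1+G2) over usable deaths tracks progress through the
    epidemiological transition (communicable-dominated mortality shifting
    to non-communicable). The same functional of the comparator envelope
    gives the expected value; the delta is observed minus expected.
    """
    g1 = dist.counts.get("group1", 0.0)
    g2 = dist.counts.get("group2", 0.0)
    env = comparator.broad_group_envelope
    expected = env["group1"] / (env["group1"] + env["group2"])
    if g1 + g2 <= 0:
        return {"measure": None, "expected": expected, "delta": None,
                "note": "undefined: no usable group1/group2 deaths"}
    measure = g1 / (g1 + g2)
    return {"measure": measure, "expected": expected,
            "delta": measure - expected, "note": ""}


def typology_distributions(deaths: DeathTable,
                           metadata: CodeMetadataTable) -> dict[str, pd.DataFrame]:
    """Garbage histograms over the two typologies.

    Returns ``{"by_category": ..., "by_severity": ...}``; each frame has
    the garbage death count per class and its fraction of *all* deaths
    (so the fractions of a garbage-free table are all zero).
    """
    df = _classified_frame(deaths, metadata)
    total = deaths.total
    garbage = df[df["usability"] != "usable"]
    by_cat = pd.DataFrame({
        "icd_error_category": range(1, 6),
        "deaths": [float(garbage.loc[garbage["category"] == c, "count"].sum())
                   for c in range(1, 6)],
    })
    by_sev = pd.DataFrame({
        "severity_level": range(1, 5),
        "deaths": [float(garbage.loc[garbage["severity"] == s, "count"].sum())
                   for s in range(1, 5)],
    })
    for frame in (by_cat, by_sev):
        frame["fraction_of_all_deaths"] = (
            frame["deaths"] / total if total > 0 else 0.0)
    return {"by_category": by_cat, "by_severity": by_sev}


@dataclass(frozen=True)
class PackageReport:
    package: str
    severity_level: "int | None"
    total: float
    rank: int                      # rank among packages, 1 = largest
    members: pd.DataFrame = field(compare=False, default=None)  # ranked codes


def extract_packages(deaths: DeathTable,
                     metadata: CodeMetadataTable) -> list[PackageReport]:
    """Garbage packages ranked by death count, with ranked member codes.

    Within a package the member ICD categories are ordered by descending
    count, ties broken by lexicographic code order; package importance is
    its total death count (same tie-break on the package name).
    """
    df = _classified_frame(deaths, metadata)
    garbage = df[(df["usability"] != "usable") & (df["count"] > 0)]
    if garbage.empty:
        return []
    member = (garbage.groupby(["package", "icd_code"], dropna=False)
              .agg(deaths=("count", "sum"), severity=("severity", "first"))
              .reset_index())
    reports = []
    pkg_totals = (member.groupby("package")["deaths"].sum()
                  .sort_values(ascending=False))
    order = sorted(pkg_totals.index, key=lambda p: (-pkg_totals[p], str(p)))
    for rank, pkg in enumerate(order, start=1):
        rows = member[member["package"] == pkg].copy()
        rows = rows.sort_values(["deaths", "icd_code"],
                                ascending=[False, True]).reset_index(drop=True)
        rows["rank"] = rows.index + 1
        reports.append(PackageReport(
            package=str(pkg), severity_level=int(rows["severity"].iloc[0])
            if pd.notna(rows["severity"].iloc[0]) else None,
            total=float(rows["deaths"].sum()), rank=rank,
            members=rows[["rank", "icd_code", "deaths"]],
        ))
    return reports


def redistribute_garbage(deaths: DeathTable, metadata: CodeMetadataTable
                         ) -> tuple[CauseDistribution, pd.DataFrame]:
    """Proportionally reallocate garbage deaths onto the broad groups.

    Each garbage death mass moves onto that code's redistribution-target
    groups, split in proportion to the observed usable deaths over those
    groups *within the same age-sex stratum*. When the stratum has no
    usable deaths on the targets the whole-dataset target distribution is
    used; when that is empty too, the mass is split equally (over the
    targets, or over all three groups if the target set is empty). Total
    deaths are conserved exactly; the audit trail records every move.
    """
    df = _classified_frame(deaths, metadata)
    usable = df[df["usability"] == "usable"]
    strat = usable.groupby(["age_group", "sex", "broad_group"])["count"].sum()
    overall = usable.groupby("broad_group")["count"].sum()

    counts = {g: float(usable.loc[usable["broad_group"] == g, "count"].sum())
              for g in BROAD_GROUPS}
    counts.update({"unusable": 0.0, "insufficiently_specified": 0.0})

    audit_rows = []
    garbage = df[(df["usability"] != "usable") & (df["count"] > 0)]
    for rec in garbage.itertuples(index=False):
        targets = sorted(rec.targets or BROAD_GROUPS)
        weights = np.array([float(strat.get((rec.age_group, rec.sex, g), 0.0))
                            for g in targets])
        basis = "stratum"
        if weights.sum() <= 0:
            weights = np.array([float(overall.get(g, 0.0)) for g in targets])
            basis = "overall"
        if weights.sum() <= 0:
            weights = np.ones(len(targets))
            basis = "equal_split"
        shares = weights / weights.sum()
        for g, s in zip(targets, shares):
            if s <= 0:
                continue
            counts[g] += rec.count * s
            audit_rows.append({
                "icd_code": rec.icd_code, "age_group": rec.age_group,
                "sex": rec.sex, "mass": rec.count * s, "target": g,
                "basis": basis,
            })
    audit = pd.DataFrame(audit_rows, columns=["icd_code", "age_group", "sex",
                                              "mass", "target", "basis"])
    return CauseDistribution.from_counts(counts), audit


def leading_causes(deaths: DeathTable, metadata: CodeMetadataTable,
                   n: int = 20) -> pd.DataFrame:
    """Top-n cause categories with garbage flags.

    Usable deaths aggregate to the 3-character ICD category; garbage
    deaths aggregate to their package. Garbage entries are flagged
    ``red`` at severity 1-2 (most policy impact) and ``orange`` at 3-4;
    a garbage category anywhere in the leading list signals that the
    dataset is partially unreliable.
    """
    df = _classified_frame(deaths, metadata)
    df = df[df["count"] > 0].copy()
    df["category_label"] = np.where(
        df["usability"] == "usable", df["icd_code"].str[:3],
        "[garbage] " + df["package"].astype(str))
    agg = (df.groupby("category_label")
           .agg(count=("count", "sum"),
                garbage=("usability", lambda u: (u != "usable").all()),
                severity=("severity", "first"))
           .reset_index())
    total = float(agg["count"].sum())
    agg["fraction"] = agg["count"] / total
    agg["flag"] = "none"
    is_g = agg["garbage"]
    agg.loc[is_g & (agg["severity"] <= 2), "flag"] = "red"
    agg.loc[is_g & (agg["severity"] >= 3), "flag"] = "orange"
    agg = agg.sort_values(["count", "category_label"],
                          ascending=[False, True]).reset_index(drop=True)
    agg["rank"] = agg.index + 1
    out = agg.head(n)[["rank", "category_label", "count", "fraction", "flag"]]
    return out.reset_index(drop=True)
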