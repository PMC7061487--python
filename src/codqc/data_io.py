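"""Reading, validation and normalization of mortality input tables.

Handles the four input surfaces of the assessment pipeline:

* death tabulations — counts by year, sex, age group and ICD-10 code,
  with an optional neonatal split on the under-1 rows;
* population counts by year, sex and age group;
* the code-metadata table mapping ICD-10 codes and ranges to usability
  class, broad cause group, ICD-error category, severity level, garbage
  package and redistribution targets (a packaged default is bundled);
* the comparator set — external reference series (crude-death-rate trend,
  estimated under-five mortality, broad-cause-group envelope, reference
  cause list) supplied as a local YAML/JSON file.

Age groups follow the standard tabulation ladder: ``<1``, ``1-4``, then
5-year bands up to a configurable open interval (default ``85+``), plus
an explicit ``unknown`` category. Sexes are normalized to
``male``/``female``/``unknown``.
"""

from __future__ import annotations

import hashlib
import io
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MALE",
    "FEMALE",
    "UNKNOWN",
    "NEONATAL_COLUMNS",
    "CodeValidationError",
    "InputError",
    "age_ladder",
    "age_midpoint",
    "age_lower_bound",
    "validate_icd10_code",
    "DeathTable",
    "PopulationTable",
    "IngestReport",
    "read_death_table",
    "write_death_table",
    "read_population_table",
    "CodeMetadataRow",
    "CodeMetadataTable",
    "load_code_metadata",
    "ComparatorSet",
    "load_comparators",
    "write_comparators",
]

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

#: Optional neonatal-detail columns on "<1" death rows: early (0-6 days),
#: late (7-27 days) and post-neonatal (28-364 days) deaths.
NEONATAL_COLUMNS = ("early_neonatal", "late_neonatal", "post_neonatal")

_SEX_ALIASES = {
    "1": MALE, "2": FEMALE, "9": UNKNOWN,
    "m": MALE, "f": FEMALE,
    "male": MALE, "female": FEMALE, "unknown": UNKNOWN,
}

#: Default raw-label aliases applied when reading age columns.
_AGE_ALIASES = {
    "0": "<1", "00": "<1", "<1": "<1", "0-0": "<1", "under 1": "<1",
    "1-4": "1-4", "01-04": "1-4",
    "unknown": UNKNOWN, "unk": UNKNOWN, "99": UNKNOWN, "999": UNKNOWN,
}

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")


class InputError(ValueError):
    """Hard error raised for invalid input files or tables."""


class CodeValidationError(InputError):
    """Rejection of an ICD-10 code, with a machine-readable reason."""

    def __init__(self, raw: str, reason: str):
        self.raw = raw
        self.reason = reason
        super().__init__(f"{reason}: {raw!r}")


def age_ladder(open_age: int = 85, include_unknown: bool = True) -> list[str]:
    """Standard tabulation age ladder.

    ``<1``, ``1-4``, then 5-year bands, closing with the open interval
    ``{open_age}+``. ``open_age`` must be a multiple of 5 and at least 5.
    """
    if open_age < 5 or open_age % 5:
        raise ValueError(f"open_age must be a positive multiple of 5, got {open_age}")
    bands = ["<1", "1-4"]
    bands += [f"{lo}-{lo + 4}" for lo in range(5, open_age, 5)]
    bands.append(f"{open_age}+")
    if include_unknown:
        bands.append(UNKNOWN)
    return bands


def age_lower_bound(label: str) -> float:
    """Lower bound in years of an age-group label ('unknown' -> nan)."""
    if label == UNKNOWN:
        return float("nan")
    if label == "<1":
        return 0.0
    if label.endswith("+"):
        return float(label[:-1])
    return float(label.split("-")[0])


def age_midpoint(label: str, open_interval_offset: float = 2.5) -> float:
    """Midpoint in years of an age-group label.

    ``<1`` -> 0.5, ``1-4`` -> 3.0, five-year bands -> lower + 2.5; the
    open interval uses ``lower + open_interval_offset`` (default 2.5).
    """
    if label == UNKNOWN:
        return float("nan")
    if label == "<1":
        return 0.5
    if label.endswith("+"):
        return float(label[:-1]) + open_interval_offset
    lo, hi = label.split("-")
    return (float(lo) + float(hi) + 1.0) / 2.0


def validate_icd10_code(raw: str, known_codes: "Iterable[str] | None" = None) -> str:
    """Normalize an ICD-10 code: uppercase, strip the dot, check the shape.

    Accepts 3- or 4-character codes (letter + 2 digits + optional digit).
    U-chapter and other local-use codes are accepted only when listed in
    ``known_codes`` (typically the expanded metadata table).

    Raises :class:`CodeValidationError` with reason ``invalid_code`` for a
    malformed pattern and ``unknown_code`` for an unrecognized local code.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise CodeValidationError(str(raw), "invalid_code")
    code = raw.strip().upper().replace(".", "")
    if not _ICD_RE.match(code):
        raise CodeValidationError(raw, "invalid_code")
    if code[0] == "U":
        known = set(known_codes or ())
        if code not in known and code[:3] not in known:
            raise CodeValidationError(raw, "unknown_code")
    return code


def _key_columns(with_icd: bool) -> list[str]:
    cols = ["year", "sex", "age_group"]
    if with_icd:
        cols.append("icd_code")
    return cols


@dataclass(frozen=True)
class IngestReport:
    """What normalization did to an input file: repairs, drops, warnings."""

    rows_read: int = 0
    rows_kept: int = 0
    duplicates_merged: int = 0
    dropped_count_total: int = 0
    warnings: tuple[str, ...] = ()


class _BaseTable:
    """Thin validated wrapper around a tidy pandas DataFrame."""

    _with_icd = False

    def __init__(self, data: pd.DataFrame, ladder: "Sequence[str] | None" = None):
        self.ladder = list(ladder) if ladder is not None else age_ladder()
        self.data = self._normalize(data)
        self._check()

    def _normalize(self, data: pd.DataFrame) -> pd.DataFrame:
        keys = _key_columns(self._with_icd)
        missing = [c for c in keys + ["count"] if c not in data.columns]
        if missing:
            raise InputError(f"missing mandatory column(s): {missing}")
        extra = [c for c in NEONATAL_COLUMNS if c in data.columns]
        df = data[keys + ["count"] + extra].copy()
        df["year"] = df["year"].astype(int)
        df["count"] = df["count"].astype(float)
        agg = {"count": "sum", **{c: "sum" for c in extra}}
        df = df.groupby(keys, as_index=False, sort=False).agg(agg)
        order = {lab: i for i, lab in enumerate(self.ladder)}
        df = df.sort_values(
            keys, key=lambda s: s.map(order) if s.name == "age_group" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        return df

    def _check(self) -> None:
        df = self.data
        if (df["count"] < 0).any():
            bad = df.index[df["count"] < 0][0]
            raise InputError(f"negative count at normalized row {bad}")
        bad_age = set(df["age_group"]) - set(self.ladder)
        if bad_age:
            raise InputError(f"age_group labels outside the ladder: {sorted(bad_age)}")
        bad_sex = set(df["sex"]) - {MALE, FEMALE, UNKNOWN}
        if bad_sex:
            raise InputError(f"unrecognized sex labels: {sorted(bad_sex)}")
        neo = [c for c in NEONATAL_COLUMNS if c in df.columns]
        if neo:
            sub = df[df["age_group"] == "<1"]
            tot = sub[list(neo)].sum(axis=1)
            if len(neo) == 3 and not np.allclose(tot, sub["count"], atol=1e-9):
                raise InputError("neonatal detail does not sum to the <1 count")

    @property
    def total(self) -> float:
        return float(self.data["count"].sum())

    def filter(self, **kw) -> pd.DataFrame:
        """Rows matching equality constraints, e.g. ``filter(sex='male')``."""
        df = self.data
        for col, val in kw.items():
            df = df[df[col] == val]
        return df

    def checksum(self) -> str:
        buf = io.StringIO()
        self.data.to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()

    def __len__(self) -> int:
        return len(self.data)


class DeathTable(_BaseTable):
    """Death counts keyed by (year, sex, age_group, icd_code).

    Unknown age and unknown sex are retained as explicit categories —
    they feed the age/sex VSPI(Q) component and are never imputed. The
    ICD code ``missing`` marks deaths without a recorded cause.
    """

    _with_icd = True

    def known_age_sex(self) -> pd.DataFrame:
        df = self.data
        return df[(df["age_group"] != UNKNOWN) & (df["sex"] != UNKNOWN)]


class PopulationTable(_BaseTable):
    """Person counts keyed by (year, sex, age_group)."""

    def _check(self) -> None:
        super()._check()
        if (self.data["sex"] == UNKNOWN).any():
            raise InputError("population rows cannot have unknown sex")
        present = set(self.data["age_group"])
        required = [a for a in self.ladder if a != UNKNOWN]
        gaps = [a for a in required if a not in present]
        if gaps:
            raise InputError(f"incomplete age ladder: missing {gaps}")


def _normalize_sex(value, extra: "Mapping[str, str] | None" = None) -> str:
    aliases = dict(_SEX_ALIASES)
    if extra:
        aliases.update({str(k).lower(): v for k, v in extra.items()})
    key = str(value).strip().lower()
    if key in aliases:
        return aliases[key]
    raise InputError(f"unrecognized sex value {value!r}")


def _normalize_age(value, ladder: Sequence[str],
                   extra: "Mapping[str, str] | None" = None) -> str:
    aliases = dict(_AGE_ALIASES)
    if extra:
        aliases.update({str(k).lower(): v for k, v in extra.items()})
    key = str(value).strip().lower()
    if key in aliases:
        return aliases[key]
    label = str(value).strip()
    if label in ladder:
        return label
    raise InputError(f"unrecognized age_group value {value!r}")


def _read_table(path, format_config, with_icd, table_cls, known_codes=None):
    cfg = dict(format_config or {})
    columns = cfg.get("columns", {})
    ladder = age_ladder(cfg.get("open_age", 85))
    df = pd.read_csv(path, dtype=str).rename(columns={v: k for k, v in columns.items()})
    keys = _key_columns(with_icd)
    missing = [c for c in keys + ["count"] if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing mandatory column(s): {missing}")

    warns: list[str] = []
    rows_read = len(df)
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        raise InputError(f"{path}: non-numeric count at file row "
                         f"{int(counts.index[counts.isna()][0]) + 2}")
    if (counts < 0).any():
        raise InputError(f"{path}: negative count at file row "
                         f"{int(counts.index[counts < 0][0]) + 2}")
    df["count"] = counts
    df["sex"] = df["sex"].map(lambda v: _normalize_sex(v, cfg.get("sex_aliases")))
    df["age_group"] = df["age_group"].map(
        lambda v: _normalize_age(v, ladder, cfg.get("age_aliases")))

    dropped = 0.0
    if with_icd:
        def _code(v):
            v = "" if v is None else str(v).strip()
            if not v or v.lower() in ("missing", "nan", "none"):
                return "missing"
            return validate_icd10_code(v, known_codes)
        codes, keep = [], np.ones(len(df), dtype=bool)
        for i, v in enumerate(df["icd_code"]):
            try:
                codes.append(_code(v))
            except CodeValidationError as exc:
                codes.append("missing")
                keep[i] = False
                warns.append(f"row {i + 2}: dropped ({exc.reason}: {v!r})")
        df["icd_code"] = codes
        dropped = float(df.loc[~keep, "count"].sum())
        df = df[keep]
    for col in NEONATAL_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0.0)

    before = len(df)
    table = table_cls(df, ladder=ladder)
    merged = before - len(table)
    if merged > 0:
        warns.append(f"{merged} duplicate key(s) merged by summation")
    report = IngestReport(
        rows_read=rows_read, rows_kept=len(table), duplicates_merged=merged,
        dropped_count_total=dropped, warnings=tuple(warns),
    )
    return table, report


def read_death_table(path, format_config=None, known_codes=None):
    """Read a deaths CSV into a normalized :class:`DeathTable`.

    Returns ``(table, report)``; the :class:`IngestReport` accounts for
    merged duplicates and dropped rows so that input counts are conserved:
    ``sum(input) == table.total + report.dropped_count_total``.
    """
    return _read_table(path, format_config, True, DeathTable, known_codes)


def read_population_table(path, format_config=None):
    """Read a population CSV into a normalized :class:`PopulationTable`."""
    return _read_table(path, format_config, False, PopulationTable)


def write_death_table(table: DeathTable, path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Code metadata
# ---------------------------------------------------------------------------

_USABILITIES = ("usable", "unusable", "insufficiently_specified")
_GROUPS = ("group1", "group2", "group3")

#: Classification applied to codes absent from the metadata table and to
#: the "missing" pseudo-code. A deliberate, documented guess: treat them
#: as insufficiently specified, ICD-error category 5, severity 3.
UNMAPPED_DEFAULT = dict(
    usability="insufficiently_specified", broad_group="none",
    icd_error_category=5, severity_level=3, package="unmapped",
    redistribution_targets=frozenset(_GROUPS),
)


def _code3_index(code3: str) -> int:
    return (ord(code3[0]) - ord("A")) * 100 + int(code3[1:3])


def _index_code3(idx: int) -> str:
    return f"{chr(ord('A') + idx // 100)}{idx % 100:02d}"


def expand_code_range(pattern: str) -> list[str]:
    """Expand an exact 3-character code or inclusive range ('A40-A41')."""
    parts = pattern.strip().upper().split("-")
    if len(parts) == 1:
        return [parts[0]]
    lo, hi = _code3_index(parts[0]), _code3_index(parts[1])
    if hi < lo:
        raise InputError(f"descending code range {pattern!r}")
    return [_index_code3(i) for i in range(lo, hi + 1)]


@dataclass(frozen=True)
class CodeMetadataRow:
    code_pattern: str
    usability: str
    broad_group: str
    icd_error_category: "int | None"
    severity_level: "int | None"
    package: "str | None"
    redistribution_targets: frozenset


class CodeMetadataTable:
    """Expanded, overlap-checked ICD-10 code metadata.

    Lookup resolves a 4-character code first against exact 4-character
    patterns, then against its 3-character parent; codes covered by no
    pattern resolve to :data:`UNMAPPED_DEFAULT` (a total function, with a
    warning emitted once per unmapped code family).
    """

    def __init__(self, rows: Sequence[CodeMetadataRow]):
        self.rows = list(rows)
        self._by3: dict[str, CodeMetadataRow] = {}
        self._by4: dict[str, CodeMetadataRow] = {}
        for row in self.rows:
            pat = row.code_pattern.strip().upper()
            if len(pat) == 4 and "-" not in pat:
                if pat in self._by4:
                    raise InputError(f"overlapping patterns: {pat!r} listed twice")
                self._by4[pat] = row
                continue
            for code in expand_code_range(pat):
                if code in self._by3:
                    other = self._by3[code].code_pattern
                    raise InputError(
                        f"overlapping patterns: {row.code_pattern!r} and "
                        f"{other!r} both cover {code}")
                self._by3[code] = row
        self._warned: set[str] = set()

    def lookup(self, code: str) -> CodeMetadataRow:
        code = code.strip().upper()
        if code in self._by4:
            return self._by4[code]
        c3 = code[:3]
        if c3 in self._by3:
            return self._by3[c3]
        if c3 not in self._warned:
            self._warned.add(c3)
            warnings.warn(f"ICD code {code} not in metadata; treated as "
                          f"insufficiently specified (severity 3)")
        return CodeMetadataRow(code_pattern=code, **UNMAPPED_DEFAULT)

    @property
    def known_codes(self) -> set[str]:
        return set(self._by3) | set(self._by4)


def load_code_metadata(path=None) -> CodeMetadataTable:
    """Load a code-metadata CSV; the packaged default when path is None.

    In the default table the four sepsis-package members A40, A41, D65 and
    R02 carry severity level 1, essential hypertension (I10) level 2,
    unspecified cancer (C76/C80) level 3 and unspecified stroke (I64)
    level 4.
    """
    if path is None:
        src = resources.files("codqc").joinpath("data/code_metadata.csv")
        df = pd.read_csv(io.StringIO(src.read_text()), dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    required = {"code_pattern", "usability", "broad_group", "icd_error_category",
                "severity_level", "package", "redistribution_targets"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"metadata file missing column(s): {sorted(missing)}")

    rows = []
    for i, rec in df.iterrows():
        usability = str(rec["usability"]).strip()
        if usability not in _USABILITIES:
            raise InputError(f"metadata row {i}: bad usability {usability!r}")
        group = str(rec["broad_group"]).strip() if pd.notna(rec["broad_group"]) else ""
        cat = rec["icd_error_category"]
        sev = rec["severity_level"]
        cat = int(cat) if pd.notna(cat) and str(cat).strip() else None
        sev = int(sev) if pd.notna(sev) and str(sev).strip() else None
        pkg = str(rec["package"]).strip() if pd.notna(rec["package"]) else None
        pkg = pkg or None
        tgt = rec["redistribution_targets"]
        targets = frozenset(
            t.strip() for t in str(tgt).split(";") if t.strip()
        ) if pd.notna(tgt) else frozenset()
        if usability == "usable":
            if group not in _GROUPS:
                raise InputError(f"metadata row {i}: usable code needs a broad "
                                 f"group, got {group!r}")
        else:
            if cat is None or sev is None:
                raise InputError(f"metadata row {i}: garbage code needs "
                                 "icd_error_category and severity_level")
            if not 1 <= cat <= 5 or not 1 <= sev <= 4:
                raise InputError(f"metadata row {i}: category/severity out of range")
            group = "none"
        rows.append(CodeMetadataRow(
            code_pattern=str(rec["code_pattern"]).strip(),
            usability=usability, broad_group=group or "none",
            icd_error_category=cat, severity_level=sev, package=pkg,
            redistribution_targets=targets))
    return CodeMetadataTable(rows)


# ---------------------------------------------------------------------------
# Comparators
# ---------------------------------------------------------------------------

@dataclass
class ComparatorSet:
    """External reference series used for plausibility comparison.

    cdr_trend maps year -> estimated crude death rate per 1000;
    u5mr_estimate is the estimated 5q0 (probability) at a reference year;
    broad_group_envelope gives the expected fractions of broad cause
    groups 1/2/3 (summing to one); reference_cause_list is the
    cause-granularity reference (192 entries in the bundled fixtures).
    """

    cdr_trend: pd.Series
    u5mr_estimate: float
    u5mr_year: int
    broad_group_envelope: dict[str, float]
    reference_cause_list: tuple[str, ...]

    def __post_init__(self):
        trend = self.cdr_trend
        years = np.asarray(trend.index, dtype=float)
        if len(years) and not np.all(np.diff(years) > 0):
            raise InputError("cdr_trend years must be strictly increasing")
        env = self.broad_group_envelope
        if set(env) != set(_GROUPS):
            raise InputError(f"envelope must have keys {_GROUPS}")
        if abs(sum(env.values()) - 1.0) > 1e-9:
            raise InputError("broad_group_envelope fractions must sum to 1")
        if len(set(self.reference_cause_list)) != len(self.reference_cause_list):
            raise InputError("reference_cause_list entries must be unique")

    def to_dict(self) -> dict:
        return {
            "cdr_trend": [{"year": int(y), "cdr": float(v)}
                          for y, v in self.cdr_trend.items()],
            "u5mr_estimate": {"year": int(self.u5mr_year),
                              "value": float(self.u5mr_estimate)},
            "broad_group_envelope": {k: float(v)
                                     for k, v in self.broad_group_envelope.items()},
            "reference_cause_list": list(self.reference_cause_list),
        }


def load_comparators(path) -> ComparatorSet:
    """Load the comparator set from a YAML or JSON file."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    return comparators_from_dict(payload)


def comparators_from_dict(payload: Mapping) -> ComparatorSet:
    for block in ("cdr_trend", "u5mr_estimate", "broad_group_envelope",
                  "reference_cause_list"):
        if block not in payload:
            raise InputError(f"comparator file missing block {block!r}")
    years = [int(r["year"]) for r in payload["cdr_trend"]]
    if any(b <= a for a, b in zip(years, years[1:])):
        raise InputError("cdr_trend years must be strictly increasing")
    trend = pd.Series([float(r["cdr"]) for r in payload["cdr_trend"]],
                      index=years)
    u5 = payload["u5mr_estimate"]
    return ComparatorSet(
        cdr_trend=trend,
        u5mr_estimate=float(u5["value"]),
        u5mr_year=int(u5["year"]),
        broad_group_envelope={k: float(v)
                              for k, v in payload["broad_group_envelope"].items()},
        reference_cause_list=tuple(payload["reference_cause_list"]),
    )


def write_comparators(comp: ComparatorSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(comp.to_dict(), sort_keys=False))
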