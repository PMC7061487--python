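"""The Vital Statistics Performance Index for Quality — VSPI(Q).

Five component scores, each in [0, 1], summarize the quality dimensions
of a cause-of-death dataset:

* completeness of death registration;
* garbage — the severity-weighted fraction of garbage-coded deaths,
  where severity levels 1-3 are penalised exactly twice as much per
  death as level 4;
* cause detail — the share of a 192-entry standard reference cause list
  represented in the data;
* age/sex recording — the share of deaths with both age and sex known;
* biological plausibility — the share of deaths whose cause is possible
  for the recorded age and sex.

Each raw score passes through a monotone transform (identity by default,
piecewise-linear configurable with endpoints pinned at f(0)=0, f(1)=1)
and the transformed scores multiply into the composite on a 0-100 scale.
The gap to 100 is attributed across components in proportion to their
transformed shortfalls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import UNKNOWN, DeathTable, InputError

__all__ = [
    "COMPONENTS",
    "EditRule",
    "DEFAULT_EDIT_RULES",
    "garbage_component",
    "detail_component",
    "agesex_component",
    "plausibility_component",
    "PiecewiseTransform",
    "identity_transforms",
    "validate_transforms",
    "VSPIQResult",
    "vspiq_score",
]

COMPONENTS = ("completeness", "garbage", "detail", "agesex", "plausibility")


def garbage_component(f1: float, f2: float, f3: float, f4: float) -> float:
    """Garbage score from per-severity fractions of *all* deaths.

    ``f_l`` is the fraction of all deaths coded to severity-level-l
    garbage. Levels 1-3 carry twice the per-death penalty of level 4::

        S = clamp(1 - (2 (f1+f2+f3) + f4) / 2, 0, 1)

    so a dataset that is all level-1 garbage scores 0 and one that is all
    level-4 garbage scores 0.5.
    """
    fracs = np.array([f1, f2, f3, f4], dtype=float)
    if (fracs < 0).any():
        raise InputError("severity fractions must be non-negative")
    if fracs.sum() > 1 + 1e-9:
        raise InputError("severity fractions sum to more than 1")
    penalty = (2.0 * (f1 + f2 + f3) + f4) / 2.0
    return float(min(1.0, max(0.0, 1.0 - penalty)))


def detail_component(deaths: DeathTable, reference_cause_list) -> float:
    """Cause granularity: share of reference causes present in the data.

    A reference cause counts as present when at least one death carries
    its 3-character ICD category; codes off the list (garbage included)
    never contribute.
    """
    ref = list(reference_cause_list)
    if not ref:
        raise InputError("empty reference cause list")
    present = {str(c)[:3] for c, k in
               zip(deaths.data["icd_code"], deaths.data["count"]) if k > 0}
    hits = sum(1 for cause in ref if str(cause)[:3] in present)
    return hits / len(ref)


def agesex_component(deaths: DeathTable) -> float:
    """Share of deaths with both age and sex recorded.

    A death missing both age and sex is penalised once, not twice.
    """
    df = deaths.data
    total = deaths.total
    if total <= 0:
        return 1.0
    missing = df[(df["age_group"] == UNKNOWN) | (df["sex"] == UNKNOWN)]
    return 1.0 - float(missing["count"].sum()) / total


@dataclass(frozen=True)
class EditRule:
    """Age/sex restriction on an ICD code block (a violation is implausible)."""

    name: str
    code_lo: str               # inclusive 3-character bounds
    code_hi: str
    sex: str | None = None     # required sex, if any
    age_min: float | None = None   # allowed age range (band lower bounds)
    age_max: float | None = None

    def violated(self, code3: str, sex: str, age_lower: float) -> bool:
        if not (self.code_lo <= code3 <= self.code_hi):
            return False
        if self.sex is not None and sex not in (self.sex, UNKNOWN):
            return True
        if not np.isnan(age_lower):
            if self.age_min is not None and age_lower < self.age_min:
                return True
            if self.age_max is not None and age_lower > self.age_max:
                return True
        return False


#: Bundled plausibility edit rules: maternal causes require a female of
#: reproductive age, prostate cancer a male, cervical/ovarian cancer a
#: female, perinatal-period causes an infant.
DEFAULT_EDIT_RULES = (
    EditRule("maternal", "O00", "O99", sex="female", age_min=10, age_max=50),
    EditRule("prostate_cancer", "C61", "C61", sex="male"),
    EditRule("cervical_cancer", "C53", "C53", sex="female"),
    EditRule("ovarian_cancer", "C56", "C56", sex="female"),
    EditRule("perinatal", "P00", "P96", age_max=0),
)


def plausibility_component(deaths: DeathTable, edit_rules=DEFAULT_EDIT_RULES
                           ) -> tuple[float, pd.DataFrame]:
    """Share of deaths passing every age/sex edit rule, plus an audit list."""
    from .data_io import age_lower_bound

    df = deaths.data
    total = deaths.total
    violations = []
    bad = 0.0
    for rec in df.itertuples(index=False):
        if rec.count <= 0 or rec.icd_code == "missing":
            continue
        lower = age_lower_bound(rec.age_group)
        for rule in edit_rules:
            if rule.violated(rec.icd_code[:3], rec.sex, lower):
                bad += rec.count
                violations.append({
                    "icd_code": rec.icd_code, "sex": rec.sex,
                    "age_group": rec.age_group, "count": rec.count,
                    "rule": rule.name,
                })
                break
    audit = pd.DataFrame(violations,
                         columns=["icd_code", "sex", "age_group", "count", "rule"])
    score = 1.0 if total <= 0 else 1.0 - bad / total
    return score, audit


@dataclass(frozen=True)
class PiecewiseTransform:
    """Monotone piecewise-linear score transform with pinned endpoints."""

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self):
        pts = sorted(self.knots)
        object.__setattr__(self, "knots", tuple(pts))
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        if not pts or xs[0] != 0.0 or xs[-1] != 1.0:
            raise InputError("transform knots must span x = 0 .. 1")
        if ys[0] != 0.0 or ys[-1] != 1.0:
            raise InputError("transform must satisfy f(0)=0 and f(1)=1")
        if any(b < a for a, b in zip(ys, ys[1:])):
            raise InputError("transform must be monotone non-decreasing")
        if any(not (0 <= v <= 1) for v in xs + ys):
            raise InputError("transform knots must lie in the unit square")

    def __call__(self, x: float) -> float:
        xs = [p[0] for p in self.knots]
        ys = [p[1] for p in self.knots]
        return float(np.interp(x, xs, ys))


IDENTITY = PiecewiseTransform(((0.0, 0.0), (1.0, 1.0)))


def identity_transforms() -> dict[str, PiecewiseTransform]:
    return {c: IDENTITY for c in COMPONENTS}


def validate_transforms(config: dict | None) -> dict[str, PiecewiseTransform]:
    """Build per-component transforms from a config block of knot lists."""
    transforms = identity_transforms()
    for name, knots in (config or {}).items():
        if name not in COMPONENTS:
            raise InputError(f"unknown VSPI(Q) component {name!r}")
        transforms[name] = PiecewiseTransform(tuple((float(x), float(y))
                                                    for x, y in knots))
    return transforms


@dataclass(frozen=True)
class VSPIQResult:
    raw: dict[str, float]           # S_i
    transformed: dict[str, float]   # f_i(S_i)
    composite: float                # 100 * prod f_i(S_i)
    gap_shares: dict[str, float]    # shares of (100 - composite); {} at 100


def vspiq_score(components: dict[str, float],
                transforms: dict[str, PiecewiseTransform] | None = None
                ) -> VSPIQResult:
    """Combine the five component scores into the 0-100 composite.

    ``components`` maps each of :data:`COMPONENTS` to a raw score in
    [0, 1]. The composite is 100 times the product of the transformed
    scores; the gap decomposition attributes (100 - composite) across
    components in proportion to 1 - f_i(S_i).
    """
    missing = [c for c in COMPONENTS if c not in components]
    if missing:
        raise InputError(f"missing component score(s): {missing}")
    transforms = transforms or identity_transforms()
    raw = {}
    transformed = {}
    for name in COMPONENTS:
        s = float(components[name])
        if not 0.0 <= s <= 1.0:
            raise InputError(f"component {name} score {s} outside [0, 1]")
        raw[name] = s
        transformed[name] = transforms[name](s)
    composite = 100.0 * float(np.prod(list(transformed.values())))
    shortfalls = {c: 1.0 - transformed[c] for c in COMPONENTS}
    denom = sum(shortfalls.values())
    gap = ({c: shortfalls[c] / denom for c in COMPONENTS} if denom > 0 else {})
    return VSPIQResult(raw=raw, transformed=transformed,
                       composite=composite, gap_shares=gap)
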