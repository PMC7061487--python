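"""Orchestration of the ten assessment steps and the machine-readable report.

``run_assessment`` takes a death tabulation, optionally a population
table and a comparator set, and produces a :class:`QualityReport` with
one section per step:

1.  age/sex structure of deaths and population;
2.  completeness of death registration (comparator, empirical, weighted);
3.  log-linearity of adult death rates;
4.  sex pattern of mortality;
5.  child mortality (5q0) and child-registration completeness;
6.  usability of causes, the two garbage typologies, garbage packages;
7.  broad cause groups, epidemiological-transition measure,
    redistribution of garbage;
8.  age pattern of broad groups and garbage;
9.  leading causes with garbage flags;
10. the VSPI(Q) components, composite and gap decomposition.

Rate-dependent steps (2-5) are skipped with explicit notes when no
population table is supplied; a small-numbers warning is emitted when
the dataset holds fewer than 4000 deaths. The report serializes to JSON
and round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (
    DeathTable, InputError, load_code_metadata, load_comparators,
    read_death_table, read_population_table,
)
from . import demography, completeness as completeness_mod, cause_quality, vspiq

__all__ = ["ConfigError", "QualityReport", "run_assessment", "export_report",
           "SMALL_DATASET_THRESHOLD"]

#: Below this many deaths, age-specific figures become unstable.
SMALL_DATASET_THRESHOLD = 4000


class ConfigError(InputError):
    """Invalid assessment configuration (exit code 2 at the CLI)."""


def _records(df: pd.DataFrame) -> list[dict]:
    out = []
    for rec in df.to_dict("records"):
        clean = {}
        for k, v in rec.items():
            if isinstance(v, np.generic):
                v = v.item()
            if isinstance(v, float) and not np.isfinite(v):
                v = None
            clean[str(k)] = v
        out.append(clean)
    return out


@dataclass
class QualityReport:
    """Per-step results, warnings and provenance stamps; JSON round-trippable."""

    meta: dict
    warnings: list
    steps: dict
    cleaned_deaths: DeathTable | None = field(default=None, compare=False,
                                              repr=False)

    def to_dict(self) -> dict:
        return {"meta": self.meta, "warnings": list(self.warnings),
                "steps": self.steps}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "QualityReport":
        return cls(meta=payload["meta"], warnings=list(payload["warnings"]),
                   steps=payload["steps"])

    @classmethod
    def from_json(cls, text: str) -> "QualityReport":
        return cls.from_dict(json.loads(text))

    def recompute_vspiq(self) -> float | None:
        """Composite recomputed from the stored raw components + transforms."""
        step10 = self.steps.get("step10", {})
        raw = step10.get("components")
        if not raw or any(raw.get(c) is None for c in vspiq.COMPONENTS):
            return None
        transforms = vspiq.validate_transforms(step10.get("transform_config"))
        return vspiq.vspiq_score(raw, transforms).composite


def _load_if_path(obj, loader):
    if obj is None or isinstance(obj, (str, Path)):
        return obj
    return obj


def run_assessment(deaths, population=None, comparators=None,
                   config: dict | None = None) -> QualityReport:
    """Run all ten steps; inputs may be paths or already-loaded objects."""
    cfg = dict(config or {})
    try:
        transforms = vspiq.validate_transforms(cfg.get("transforms"))
    except InputError as exc:
        raise ConfigError(str(exc)) from exc

    metadata = cfg.get("metadata")
    if metadata is None or isinstance(metadata, (str, Path)):
        metadata = load_code_metadata(metadata)
    if isinstance(comparators, (str, Path)):
        comparators = load_comparators(comparators)
    if isinstance(deaths, (str, Path)):
        deaths, ingest = read_death_table(deaths, cfg.get("deaths_format"),
                                          known_codes=metadata.known_codes)
    else:
        ingest = None
    if isinstance(population, (str, Path)):
        population, _ = read_population_table(population,
                                              cfg.get("population_format"))

    warnings_list: list[str] = []
    if ingest is not None:
        warnings_list.extend(ingest.warnings)
    total = deaths.total
    if total < SMALL_DATASET_THRESHOLD:
        warnings_list.append(
            f"small dataset: {int(total)} deaths (< {SMALL_DATASET_THRESHOLD}); "
            "age-specific figures may be unstable")
    if population is None:
        warnings_list.append("no population table: rate-dependent steps "
                             "(2-5) skipped")

    steps: dict[str, dict] = {}

    # -- Part I: all-cause mortality -------------------------------------
    step1 = {"deaths_pyramid": _records(demography.tabulate_age_sex(deaths))}
    if population is not None:
        step1["population_pyramid"] = _records(
            demography.tabulate_age_sex(population))
    steps["step1"] = step1

    child = None
    rates = None
    if population is not None:
        year = int(deaths.data["year"].iloc[0])
        cdr = demography.crude_death_rate(deaths, population)
        rates = demography.age_specific_rates(
            deaths, population, cfg.get("open_interval_offset", 2.5))

        step2: dict = {"cdr_observed": cdr}
        if comparators is not None:
            comp = completeness_mod.completeness_from_comparator(
                cdr, comparators, year)
            step2["comparator"] = {
                "completeness": comp.completeness, "raw_ratio": comp.raw_ratio,
                "cdr_expected": comp.cdr_expected, "notes": list(comp.notes)}
            try:
                child = demography.child_mortality(
                    deaths, population, comparators,
                    a0=cfg.get("a0", 0.3), a1=cfg.get("a1", 1.4))
            except InputError as exc:
                steps["step5"] = {"skipped": str(exc)}
        if child is not None:
            try:
                emp = completeness_mod.completeness_empirical(
                    deaths, population, child.child_completeness,
                    cfg.get("empirical_coefficients"))
                step2["empirical"] = {
                    "completeness": emp.completeness, "raw_ratio": emp.raw_ratio,
                    "cdr_predicted": emp.cdr_expected, "notes": list(emp.notes)}
            except InputError as exc:
                step2["empirical"] = {"skipped": str(exc)}
            if comparators is not None and "comparator" in step2:
                d = deaths.data
                obs_u5 = float(d.loc[d["age_group"].isin(["<1", "1-4"]),
                                     "count"].sum())
                exp_total = (step2["comparator"]["cdr_expected"] / 1000.0
                             * population.total)
                c_child = child.child_completeness
                est_u5 = obs_u5 / c_child if c_child > 0 else obs_u5
                est_adult = max(exp_total - est_u5, 0.0)
                obs_adult = total - obs_u5
                c_adult = min(1.0, obs_adult / est_adult) if est_adult > 0 else 1.0
                step2["weighted"] = {
                    "completeness": completeness_mod.weighted_completeness(
                        c_child, c_adult, est_u5, est_adult),
                    "deaths_under5_hat": est_u5, "deaths_5plus_hat": est_adult}
        steps["step2"] = step2

        step3 = {}
        for sex in ("male", "female"):
            try:
                fit = demography.log_linearity_check(
                    rates, sex=sex, min_age=cfg.get("min_age", 30.0))
                step3[sex] = {"slope": fit.slope, "intercept": fit.intercept,
                              "r_squared": fit.r_squared, "n_bands": fit.n_bands,
                              "non_monotone": list(fit.non_monotone)}
            except InputError as exc:
                step3[sex] = {"skipped": str(exc)}
        step3["rates"] = _records(rates)
        steps["step3"] = step3

        pattern = demography.sex_pattern_check(rates,
                                               cfg.get("sex_tolerance", 0.0))
        steps["step4"] = {
            "female_excess_flags": list(pattern.flagged),
            "under5_female_excess": list(pattern.under5_female_excess)}

        if child is not None:
            steps["step5"] = {
                "q1_0": child.q1_0, "q4_1": child.q4_1, "q5_0": child.q5_0,
                "comparator_q5_0": child.comparator_q5_0,
                "child_completeness": child.child_completeness,
                "raw_ratio": child.raw_ratio,
                "neonatal_split": child.neonatal_split}
        elif "step5" not in steps:
            steps["step5"] = {"skipped": "no comparator 5q0 available"}
    else:
        for s in ("step2", "step3", "step4", "step5"):
            steps[s] = {"skipped": "no population table"}

    # -- Part II: causes of death ----------------------------------------
    usability = cause_quality.usability_distribution(deaths, metadata)
    typology = cause_quality.typology_distributions(deaths, metadata)
    packages = cause_quality.extract_packages(deaths, metadata)
    steps["step6"] = {
        "usability": {"counts": usability.counts,
                      "fractions": usability.fractions},
        "by_icd_error_category": _records(typology["by_category"]),
        "by_severity_level": _records(typology["by_severity"]),
        "packages": [{"package": p.package, "rank": p.rank, "total": p.total,
                      "severity_level": p.severity_level,
                      "members": _records(p.members)} for p in packages],
    }

    broad = cause_quality.broad_group_distribution(deaths, metadata, by_age=True)
    redistributed, audit = cause_quality.redistribute_garbage(deaths, metadata)
    step7 = {
        "broad_groups": {"counts": broad.counts, "fractions": broad.fractions},
        "redistributed": {"counts": redistributed.counts,
                          "fractions": redistributed.fractions},
        "redistribution_audit_rows": len(audit),
    }
    if comparators is not None:
        step7["epi_transition"] = cause_quality.epi_transition_measure(
            broad, comparators)
    steps["step7"] = step7

    by_age = broad.by_age.reset_index(names="age_group")
    steps["step8"] = {"broad_groups_by_age": _records(by_age)}

    leading = cause_quality.leading_causes(deaths, metadata,
                                           n=cfg.get("leading_n", 20))
    steps["step9"] = {"leading_causes": _records(leading),
                      "garbage_in_leading": bool((leading["flag"] != "none").any())}

    # -- Part III: the VSPI(Q) -------------------------------------------
    sev = typology["by_severity"]
    fracs = dict(zip(sev["severity_level"], sev["fraction_of_all_deaths"]))
    components: dict[str, float | None] = {
        "garbage": vspiq.garbage_component(*(float(fracs.get(l, 0.0))
                                             for l in (1, 2, 3, 4))),
        "agesex": vspiq.agesex_component(deaths),
    }
    plaus, plaus_audit = vspiq.plausibility_component(
        deaths, cfg.get("edit_rules", vspiq.DEFAULT_EDIT_RULES))
    components["plausibility"] = plaus
    components["detail"] = (vspiq.detail_component(
        deaths, comparators.reference_cause_list)
        if comparators is not None else None)

    method = cfg.get("completeness_method", "comparator")
    if method not in ("comparator", "empirical", "weighted"):
        raise ConfigError(f"unknown completeness_method {method!r}")
    comp_score = None
    step2 = steps.get("step2", {})
    if isinstance(step2.get(method), dict):
        comp_score = step2[method].get("completeness")
    components["completeness"] = comp_score

    step10: dict = {
        "components": components,
        "completeness_method": method,
        "transform_config": cfg.get("transforms"),
        "plausibility_violations": _records(plaus_audit),
    }
    available = {k: v for k, v in components.items() if v is not None}
    if len(available) == len(vspiq.COMPONENTS):
        result = vspiq.vspiq_score(components, transforms)
        step10["transformed"] = result.transformed
        step10["composite"] = result.composite
        step10["gap_shares"] = result.gap_shares
    else:
        missing = sorted(set(vspiq.COMPONENTS) - set(available))
        partial = 100.0 * float(np.prod([transforms[k](v)
                                         for k, v in available.items()]))
        step10["composite"] = partial
        step10["note"] = (f"component(s) {missing} unavailable; composite "
                          "taken over the remaining components")
    steps["step10"] = step10

    meta = {
        "tool": "codqc", "version": __version__,
        "total_deaths": float(total),
        "config": {k: v for k, v in cfg.items()
                   if isinstance(v, (str, int, float, bool, list, dict,
                                     type(None)))},
        "checksums": {"deaths": deaths.checksum(),
                      **({"population": population.checksum()}
                         if population is not None else {})},
    }
    return QualityReport(meta=meta, warnings=warnings_list, steps=steps,
                         cleaned_deaths=deaths)


def export_report(report: QualityReport, out_dir, formats=("json", "csv")):
    """Write the master JSON report plus one CSV per step table.

    File naming is deterministic (``report.json``, ``step7_broad_groups_
    by_age.csv``, ...); re-exporting an identical report reproduces the
    files byte for byte. The cleaned (normalized) death table is written
    alongside when the report still carries it.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise InputError(f"cannot write to {out}: {exc}") from exc

    written = []
    if "json" in formats:
        path = out / "report.json"
        path.write_text(report.to_json())
        written.append(path)
    if "csv" in formats:
        for step, section in sorted(report.steps.items()):
            for key, value in sorted(section.items()):
                if (isinstance(value, list) and value
                        and all(isinstance(r, dict) for r in value)):
                    path = out / f"{step}_{key}.csv"
                    pd.DataFrame(value).to_csv(path, index=False)
                    written.append(path)
        if report.cleaned_deaths is not None:
            path = out / "cleaned_deaths.csv"
            report.cleaned_deaths.data.to_csv(path, index=False)
            written.append(path)
    return written
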