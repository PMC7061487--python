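# Methods

This note documents the models, defaults and design choices behind
`codqc`: what each diagnostic computes, what the synthetic-data
generator emulates, and where the design was genuinely open.

## Input model

Deaths are tabulated by calendar year, sex (male/female/unknown), age
group and ICD-10 code (3 or 4 characters, dot-stripped, e.g. `A41`,
`I219`). The age ladder is `<1`, `1-4`, then 5-year bands to a
configurable open interval (default `85+`), plus an explicit `unknown`
band. Unknown age and sex are first-class categories: they feed the
age/sex score and are never imputed. `<1` rows may carry a neonatal
split (early 0–6 days, late 7–27, post-neonatal 28–364) that must sum
to the row count. Population tables cover the full ladder for both
sexes; a missing band is a hard error, because every rate-based
diagnostic needs the complete denominator.

Codes with no chapter letter or the wrong shape are rejected as
`invalid_code`; U-chapter (local-use) codes are accepted only when the
metadata table declares them, otherwise `unknown_code`. Deaths with no
recorded cause become the `missing` pseudo-code. Normalization sums
duplicate keys and reports drops, so input counts are conserved:
input = kept + dropped.

## Code metadata

Classification is data-driven: a CSV maps code patterns (exact codes or
inclusive ranges like `A40-A41`) to usability
(usable / unusable / insufficiently specified), broad cause group for
usable codes (group1 communicable–maternal–neonatal–nutritional,
group2 non-communicable, group3 injuries), and for garbage codes an
ICD-error category (1 symptoms/ill-defined, 2 impossible as underlying
cause, 3 intermediate, 4 immediate, 5 insufficiently specified), a
severity-of-impact level 1–4, a package label, and redistribution
targets. Patterns must be non-overlapping after expansion over the
3-character code space; overlap is a hard error rather than a
first-match rule, so a metadata bug cannot silently reclassify codes.
Exact 4-character rows form a separate keyspace that refines their
3-character parent.

The packaged default seeds the canonical garbage families (R-chapter,
I10, I46, I50, I64, C76/C80, A40–A41, D65, R02, J96, E86, X59,
Y10–Y34) with severities anchored at the documented examples:
septicaemia level 1, essential hypertension level 2, unspecified cancer
level 3, unspecified stroke level 4. Severities and categories for the
remaining families follow the typology definitions (e.g. undetermined
intent Y10–Y34 stays within the injury chapter, hence level 3); the
table is deliberately user-replaceable data, not code. Codes absent
from the table default to insufficiently specified, category 5,
severity 3, with a warning — a documented guess, chosen to be
conservative rather than to ignore unmapped deaths.

## Demographic diagnostics

* Pyramids: counts and within-sex percentages by age band, for deaths
  and population.
* Crude death rate: 1000·ΣD/ΣP; unknown-age/sex deaths stay in the
  numerator because the CDR measures registration volume.
* Age-specific rates m_x exclude unknown-age/sex deaths from
  numerators — the rates describe the reported data; nothing is
  redistributed before a diagnostic look.
* Log-linearity: least-squares fit of ln m_x on band midpoints
  (open interval midpoint = lower bound + 2.5) for bands at or above
  age 30, per sex; requires ≥4 positive-rate bands; also flags any band
  whose rate drops below its younger neighbour. The age floor reflects
  where the exponential (Gompertz–Makeham) regularity of adult
  mortality sets in; both floor and midpoint offset are configurable.
* Sex pattern: any band (age ≥ 5) with female rate strictly above the
  male rate is flagged (excess female mortality is rare at every age);
  under-five bands are reported separately, not flagged, because small
  counts blur the signal there. The comparison tolerance defaults to
  zero and is configurable.
* Child mortality: m0 and m1 convert to probabilities with separation
  factors a0 = 0.3, a1 = 1.4 (standard demographic defaults,
  configurable), 5q0 combines them multiplicatively, and child
  registration completeness is observed 5q0 over the external estimate,
  capped at one (the raw ratio is retained).

## Completeness

The comparator method interpolates the reference CDR trend linearly in
the assessment year (terminal value with a warning outside the trend)
and takes observed/expected, capped at one with the raw ratio kept —
over-completeness is itself diagnostic. The empirical method predicts
ln(expected CDR) = c0 + c1·ln(5q0_obs) + c2·(% aged 65+) +
c3·(child completeness); the functional form is log-linear in the three
covariates the approach is defined by, and the packaged coefficients
are explicitly illustrative placeholders — real-world use requires a
fitted set, supplied through the config. The weighted summary combines
under-five and five-plus completeness weighted by estimated deaths in
each block; the under-five death envelope is operationalized as
observed under-five deaths divided by child completeness, and the
five-plus envelope as the comparator-expected total minus that.

## Cause quality

Every death lands in exactly one of five bins (three broad groups plus
unusable and insufficiently specified), so all distributions conserve
totals by construction. The epidemiological-transition measure is
G1/(G1+G2) over usable deaths, compared against the same functional of
the comparator envelope; this operationalization is documented as this
package's choice, not asserted as canonical. Garbage histograms are
reported over both typologies, with fractions relative to all deaths.

Packages rank by total death count (descending, name as tie-break);
within a package, member ICD categories rank by count with
lexicographic code order breaking ties. Leading causes aggregate usable
deaths to the 3-character category and garbage deaths to their package;
garbage entries are flagged red at severity 1–2 and orange at 3–4 (the
split at 2/3 is a design choice between "most impact" and "lesser
consequence").

Redistribution is proportional-within-stratum: each garbage mass moves
onto its code's target groups in proportion to usable deaths over those
groups in the same age×sex stratum, falling back to the whole-dataset
target distribution, then to an equal split. Country-specific
redistribution algorithms are out of scope by design; the target sets
live in the metadata table so users can refine them. Totals are
conserved exactly and an audit trail records every move.

## The VSPI(Q)

The garbage score operationalizes the stated 2:1 penalty as a clamped
linear form, S = 1 − (2(f₁+f₂+f₃)+f₄)/2, normalized so that all-level-1
garbage scores 0 and all-level-4 garbage 0.5. The detail denominator is
the 192-entry reference cause list; presence is matched on the
3-character category. A death missing both age and sex is penalised
once. Plausibility rules are bundled data-like defaults (maternal codes
require a female aged 10–54, prostate cancer a male, cervical/ovarian
cancer a female, perinatal codes an infant); deaths with unknown age or
sex are not counted as violations, since the rule cannot be evaluated.

Transforms default to the identity; any replacement must be monotone
piecewise-linear with f(0)=0 and f(1)=1, validated at config time.
Transformed scores multiply directly (no extra caps or floors) into the
0–100 composite, and the gap decomposition shares (100 − composite)
proportionally to the transformed shortfalls 1 − f_i(S_i). The
completeness score uses the comparator method by default; config can
switch to the empirical or weighted figure. When no population table is
available the completeness score cannot be computed; steps 2–5 are
skipped with notes and the composite is taken over the four remaining
components, recorded as such in the report — a partial figure was
judged more useful than no figure, and the report says exactly which
components entered it.

## Synthetic data generator

The generator emulates the statistical shape of a national dataset with
known truth, not any real country:

* population: band weights ∝ e^(−ρ·midpoint) with ρ = 0.02 by default
  (≈10% aged 65+, a mid-transition structure), apportioned exactly by
  largest remainder;
* mortality: Gompertz–Makeham hazard λ + αe^(βx) above age five with
  λ = 2·10⁻⁴, α = 2·10⁻⁵, β = 0.095 (adult rates rising from ≈10⁻³ at
  30 to ≈8·10⁻² at the open interval, a plausible middle-income
  schedule), child rates m0 = 0.025, m1 = 0.0015; male rates are the
  base ×1.15 and female ÷1.15, so male excess holds at every age;
* causes: a 192-cause reference list (60 group1, 100 group2, 32 group3
  three-character codes), drawn from age-profiled group mixtures
  (children group1-heavy, 15–30 injury-heavy, old ages
  non-communicable-heavy) with uniform weights within a group, so that
  at the default size every reference cause is realized; none of the
  generator's causes is age/sex-restricted, so undegraded data passes
  every plausibility rule;
* defects, applied in a fixed order — (1) thinning to the configured
  completeness (optionally child-differential), (2) garbage recoding by
  severity level, (3) age/sex blanking, (4) implausible injection
  (adult male deaths recoded to a maternal cause) — each step recoding
  or removing existing deaths so totals stay interpretable. Garbage is
  recoded *from* deaths whose true broad group is a plausible origin of
  the injected code (the code's redistribution targets), which is both
  the realistic error mechanism and what makes redistribution with true
  targets recover the pre-injection cause mix.

Deterministic (expected-value) mode rounds band expectations and hits
every defect target exactly via largest-remainder apportionment;
Poisson mode draws counts, multinomial causes and Bernoulli defects.
Identical seeds and configs reproduce outputs byte-for-byte.
Comparators are computed from the realized undegraded deaths (CDR trend
through the true CDR with a mild decline, realized 5q0, realized
broad-group envelope, the generator's reference list), so a perfect
dataset scores exactly 100 against its own comparators and recovery
tests have an exact reference.

What passing tests on this generator do **not** show: robustness to
real-world coding idiosyncrasies (country-specific garbage profiles,
correlated age misstatement such as heaping, multi-year trends,
migration-distorted denominators), comparator error (the generator's
comparators are exact, real ones are estimates), or verbal-autopsy
style cause lists. The defect model is independent across dimensions;
real defects correlate.

## Numerical choices

* Integer apportionment everywhere uses largest remainder with ties to
  the lower index — deterministic and conserving by construction.
* The log-linearity fit uses ordinary least squares
  (`scipy.stats.linregress`) on band midpoints; bands with zero rates
  are excluded from the fit but reported.
* Completeness and child-completeness ratios are capped at 1 with raw
  ratios retained; expected CDR ≤ 0 is an error rather than a cap.
* Transform validation pins endpoints exactly (no tolerance): a config
  that scores perfect data below 100 is rejected rather than warned.
* Degenerate inputs: empty tables error in tabulations; zero usable
  deaths make the transition measure undefined (reported as such);
  zero-garbage input makes redistribution the identity.

## Test and acceptance problem sizes

Simulation-based tests run at populations of 150k–8M with deterministic
mode wherever exactness is asserted; Poisson-mode recovery uses 100
seeds at 150k population for completeness and 20 seeds for garbage
mixes, sizes at which the sampling standard errors are far below the
asserted tolerances. The acceptance script scores one deterministic
dataset at 1M population (~7,900 deaths).

## Known limitations

* Single underlying cause per death; no multiple-cause analysis, no
  ICD-11, no verbal-autopsy cause lists.
* One year per assessment; trend monitoring is done by running the tool
  per year and comparing composites.
* The empirical completeness coefficients are placeholders; the
  comparator method is the default for that reason.
* The bundled metadata covers the major garbage families, not the full
  published garbage-code inventories; it is replaceable data.
* Redistribution is proportional within stratum — adequate as a
  plausibility view, not a substitute for cause-specific redistribution
  algorithms.
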