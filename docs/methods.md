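# Methods

## Screening model

The package implements the first tier of a cumulative risk assessment for
non-carcinogenic effects of chemical mixtures in drinking water. Exposure
to each chemical in a sample is normalized by its permitted dose (PD) to a
hazard quotient, quotients are summed under dose additivity to the hazard
index, and the maximum cumulative ratio MCR = HI / max HQ measures how much
of the predicted toxicity a single-chemical assessment would capture.
Dose additivity is a screening assumption; interaction and relative-potency
refinements belong to later assessment tiers and are out of scope.

The dose model is deliberately minimal: chronic intake of 2 L/day of
untreated water by a 60 kg person with 100% oral absorption, i.e.
`dose = C × 2/60` for a concentration C in mg/L. All concentrations are
mg/L and all doses mg/kg/day throughout the core; unit conversion is an I/O
concern.

## Permitted doses

The packaged table carries 115 chemicals with provenance (source code and
regulatory basis). Three conventions matter:

* **Verbatim values.** PDs are stored exactly as published, including two
  entries (fluoride 60, natural uranium 30 mg/kg/day) that are orders of
  magnitude above the corresponding authoritative reference values. The
  registry flags any PD above a configurable plausibility ceiling
  (default 10 mg/kg/day) through a warning channel but never alters it:
  reproducing a source table faithfully and auditing it are separate
  operations.
* **Metabolites.** A chemical without its own record resolves to its parent
  compound's PD via a packaged metabolite → parent map (aldicarb
  sulfone/sulfoxide → aldicarb, atrazine degradates → atrazine). A direct
  record always takes precedence over the parent rule, so a degradate with
  its own published PD keeps it.
* **No PD is an outcome, not an error.** Major ions and other chemicals with
  no PD and no parent contribute nothing to HI; lookups return a
  distinguishable null.

Chloromethane has no oral reference dose; its PD is derived from the
inhalation reference concentration as
`RfC × breathing rate × lung clearance / body weight`
(0.09 mg/m³ × 20 m³/day × 0.4 / 60 kg = 0.012, entered in the table rounded
to one significant figure, 0.01). The conversion function returns the
unrounded value; rounding is the caller's presentation choice.

Name matching casefolds and strips whitespace and hyphens, because published
tables spell the same compound several ways; registry construction verifies
the normalized names are still unique.

## Non-detects

Two bracketing conventions are computed side by side: case 1 sets ND
concentrations to 0; case 2 to DL/√2, the preferred substitution for
lognormally distributed data. Under case 1 the component count n of a
mixture is its number of detects; under case 2 it is the number of measured
analytes, since imputed NDs then contribute. A measured non-detect with no
recorded DL cannot be imputed and is dropped with a warning. Mixtures with
HI = 0 (possible under case 1) have undefined MCR; they are excluded from
MCR summaries and their count is reported.

## Data reduction

Before cohort statistics, two survey-style rules are applied, in order:

1. **Panel completeness.** Chemicals are ranked by their mean HQ across the
   cohort (computed under case-2 imputation, so potent-but-censored
   chemicals register); samples whose panel did not measure every one of the
   top-k chemicals (default k = 3) are excluded. The effect of k = 3 versus
   k = 6 is tabulated side by side; requiring six is strictly more
   restrictive, so its retained set is a subset.
2. **Minimum detects.** Samples with fewer than 5 detected components are
   excluded, to avoid MCR estimates from near-empty mixtures.

An exclusion log records which rule removed each sample. The ranking used
for exclusion is computed on the full input cohort; the reported
top-contributor table is recomputed on the final retained set. Two
denominator conventions exist for a chemical's mean HQ: averaging over the
samples in which it was measured (default for ranking — it does not dilute
sparsely assayed chemicals) or over all samples (used for the cumulative
contribution table, so that shares of the cohort mean HI are exact
percentages and cannot exceed 100%).

## Statistics and conventions

* **Centile subgroups.** Mixtures are ranked by HI (ties broken by sample
  id for determinism); the r-th of N has centile 100·r/N, and a band
  (low, high] is half-open. With N = 618 the 49–51st band holds 13 members;
  published analyses using an unstated centile convention report 11, so
  band-size assertions allow 11–13. Bands default to 49–51, 94–96 and
  98–100 (typical, high-end, upper-bound toxicity).
* **HI split.** A mixture with HI exactly at the threshold (default 1.0)
  counts as "above"; the choice is arbitrary but fixed.
* **Kendall trends** use tau-b (tie-corrected), as HI, MCR and component
  counts all contain ties. When every value of one variable is identical
  tau is undefined and reported as NaN. Grouped-median trends compute
  medians only for component-count groups with at least 5 members and need
  at least two surviving groups.
* **Wilcoxon comparisons** default to the unpaired two-sample rank-sum
  test: exact, by exhaustive enumeration of group assignments over midranks,
  whenever C(m+n, m) ≤ 200,000, otherwise the tie-corrected normal
  approximation. The exact path handles ties correctly. A paired signed-rank
  option exists for per-sample case-1 vs case-2 comparisons but the default
  is unpaired, matching the subgroup comparisons the report is built
  around. No multiple-testing correction is applied; p-values are raw.

## Synthetic cohort generator

The generator emulates the structure of multi-analyte ground-water surveys,
not any particular aquifer: per-sample analytical panels (independent
Bernoulli per analyte), lognormal concentrations when a chemical is
present, and detection as a hard threshold at the analyte's detection limit
on the latent concentration — the simplest mechanism that produces
realistic censoring. Panel membership, occurrence and concentrations are
independent across analytes and samples.

The default panel has 103 analytes in three tiers:

* **6 dominant contributors** (arsenic, fluoride, natural uranium, lead,
  lithium, strontium — the inorganic-dominance pattern of productive
  aquifers), nearly always measured (panel 0.97), present with probability
  0.95, log-GSD 1.2, detection limits 2.33 log-GSDs below the log-mean
  (≈1% censored when present). Each log-mean is chosen in closed form so
  the chemical's expected HQ over measured samples hits its target
  (0.362, 0.217, 0.098, 0.059, 0.040, 0.040).
* **8 major ions** (calcium, magnesium, …): always measured, almost always
  detected, no PD — they contribute panel and detect counts but no hazard,
  as in real surveys.
* **89 background chemicals** drawn from the packaged PD table: measured
  with probability 0.95, present with probability 0.12, detected ~27% of
  the time when present. Their potency levels (the HQ at the geometric-mean
  concentration) are spread lognormally around 2×10⁻³ and were drawn once
  with a fixed internal seed; they are frozen constants of the package, not
  functions of the user's cohort seed.

These constants were calibrated once by coarse search and then frozen. A
618-sample cohort yields on the order of 16 detects and 98 measured
analytes per sample, the six dominants carrying roughly three quarters of
the cohort mean HI, and an HI > 1 fraction in the mid-20s percent (case 1)
to mid-30s (case 2). Concentration scales and detection limits are
plausible stand-ins chosen to produce this hazard structure; they are not
survey measurements, and passing structural tests shows the pipeline
handles survey-shaped data, not that it reproduces any real cohort's
numbers. Features of real data the generator deliberately omits:
correlation between co-occurring chemicals, method-block panel structure
(an optional extension point), spatial structure between wells, and
measurement error around the detection limit.

## Numerical choices

* HI and MHQ are plain float sums/maxima; MCR ties in the maximum do not
  affect HI or MCR, and the reported top chemical is the lexicographically
  first among tied names.
* `missed_fraction(mcr) = 1 − 1/mcr`, domain mcr ≥ 1.
* Cumulative contributions validate that the partial sum does not exceed
  the claimed total (within 1e-12 relative).
* Degenerate inputs are modelled outcomes where the domain warrants (no-PD
  chemical, HI = 0 mixture, insufficient trend groups) and errors where it
  does not (empty HQ vector, non-positive PD, negative DL).

## Problem sizes

The test suite and the acceptance script run the full pipeline on seeded
618-sample cohorts (the size at which the subgroup conventions were
designed) and verify the statistical routines against brute-force oracles
on inputs small enough to enumerate exhaustively (length ≤ 8 for rank
statistics, 10⁴ random mixtures for the MCR bound). These sizes were chosen
as the smallest at which every claimed property is actually exercised.

## Known limitations

* Dose additivity across all chemicals regardless of mechanism is a
  deliberate screening overstatement.
* Pre-treatment concentrations overstate consumed doses.
* The two published PD anomalies (fluoride, uranium) are reproduced, so
  absolute HI levels involving those chemicals understate hazard relative
  to authoritative reference values; the registry's warning channel makes
  the anomaly visible.
* The generator's independence assumptions understate the variance of HI
  relative to correlated real-world mixtures.
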