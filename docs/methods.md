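# Methods

This note documents the modelling choices behind `cadphen`: what the
classification hierarchy assumes, how the two fidelity evaluations are
specified, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout.

## Classification hierarchy

The algorithm is a fixed-order sieve over code-list matches. Qualifying
events are extracted from four sources — hospital diagnoses (primary and
secondary positions by default; a flag restricts to primary), hospital
procedures, death-registry causes (underlying and contributing), and
self-reported revascularisation procedures — and filtered to the censor
date (default 2016-11-01, the last date of complete linkage follow-up)
*before* classification, so a participant whose only qualifying event is
post-censor is a control. Matching is longest-prefix-wins within a coding
system: nested prefixes with different disease tags are legal and express
carve-outs (I25.2 "old MI" inside the I25 chronic-IHD block); only equal
prefixes with conflicting tags are rejected as ambiguous.

Conventions the data force us to fix:

- **Enrolment-day events** count as prevalent by default ("prior to
  enrolment" leaves the boundary open); configurable.
- **Both-sides conflicts** (events before and after enrolment within one
  disease tag) resolve globally to incident by default, the more recent
  event having better-documented date and diagnosis; configurable to
  prevalent. The qualifying date is the earliest event on the chosen side.
- **Self-reported revascularisations carry no usable date** and therefore
  always count as prevalent CAD-without-MI evidence. When they are the
  only evidence, the assignment's qualifying date is anchored at the
  enrolment date — the survival analysis starts prevalent follow-up there
  anyway, so no information is invented.
- **A self-reported angina plus a self-reported revascularisation** is
  classified by the stronger (procedure) rule, i.e. prevalent CAD without
  MI rather than self-report-only CAD.
- **Death-registry MI causes after enrolment** yield incident MI with the
  death date as qualifying date.
- Events with missing dates are rejected at load time and reported, never
  silently dropped; the prevalent/incident split is date-driven and cannot
  use them.

The run log reports counts at each hierarchy step in execution order, so a
module-wise run of one step reproduces the corresponding slice of a full
run.

## Mortality evaluation

One Cox proportional-hazards model per phenotype versus the *same* pooled
CAD-free control group (never + no CAD), with covariates: case indicator,
age at enrolment (linear, years) and sex. Follow-up starts at enrolment
for prevalent, self-report and control groups and at the qualifying
admission for incident groups; it ends at death or the administrative
censor date. Records with a death before follow-up start (dirty linkage)
are excluded and counted. We use age at enrolment for incident cases too
(age at event is not generally available at classification time). Ties are
handled by Efron's approximation (lifelines' default). The
proportional-hazards assumption is checked by correlating the case
indicator's scaled Schoenfeld residuals with rank event time; the check is
*reported*, never used to reject a fit — the aggregated all-CAD group is a
mixture of hazards and fails it by construction. Sparse groups that break
Newton convergence are refitted with a light ridge penalty (0.1) and
flagged unreliable rather than silently reported.

## Polygenic-score evaluation

Weights come from an external GWAS summary file (vid, chrom, pos,
effect allele, beta, p). Harmonization is exact-match on (vid,
effect_allele); mismatches are dropped with a count. Variants with
p < 5×10⁻⁶ are greedily clumped: repeatedly keep the smallest-p remaining
variant (ties broken by chrom, pos, vid) and remove same-chromosome
variants within 250 kb whose in-sample dosage r² exceeds 0.2. Using the
scored sample itself as the LD reference avoids an external panel; a
zero-variance dosage column has undefined correlation, which we define as
0 (it can never be clumped away). The raw score is Σβ·dosage with missing
dosages imputed at the column mean (= 2 × effect-allele frequency);
standardization to mean 0 / SD 1 (population SD) is exact to 10⁻⁸ by
construction. Odds ratios per SD come from maximum-likelihood logistic
regression (case indicator ~ score + age + sex) with Wald 95% intervals;
fewer than two cases or unstable standard errors flag the estimate.

## Synthetic biobank generator

The generator's defaults are the study conditions the package is tested
under:

- **Label mix**: the published cohort counts over n = 502,631 (prevalent
  MI 4,900; incident MI 4,621; prevalent CAD-without-MI 10,910; incident
  8,668; self-report MI 2,754; self-report CAD 5,623; 10,649 died
  controls). Enrolment uniform over 2006-01-01–2010-12-31, ages uniform
  40–69, censoring 2016-11-01.
- **Record patterns**: one minimal, uniquely-classifiable pattern per label
  (e.g. prevalent MI → one MI-coded admission before enrolment; ~10% of
  prevalent MI uses ICD-9; prevalent CAD splits between diagnosis,
  procedure and self-reported-revascularisation-only patterns). An
  *adversarial* mode adds distractor records — a CAD code before enrolment
  for an incident-MI case, self-reported illnesses on EHR-verified cases,
  unrelated hospital contacts — whose correct resolution is still uniquely
  determined by the hierarchy; it exists to test precedence, and label
  recovery is asserted at 100%, not approximately.
- **Survival**: time-to-death is exponential with hazard
  λ = λ₀ · HR(label) · exp(β_age (age − 54.5)), with λ₀ = 0.002/year and
  β_age = 0.09/year chosen to give ~2.3% control mortality over the
  enrolment-to-censor window (the published control death fraction), and
  label hazard ratios defaulting to the published gradient (6.66, 5.65,
  2.52, 1.77, 1.75, 1.31). Incident follow-up starts at the qualifying
  event, so the Cox models see exactly the follow-up conventions they
  assume. Controls are split into never/no CAD by realized survival, which
  keeps labels and tables consistent by construction. Death causes are
  non-cardiac codes so that a death record never changes a classification
  (except the deliberate cardiovascular-cause pattern in adversarial
  incident-MI cases, whose resolution is unchanged).
- **Genotypes**: m = 60 variants in 3-variant LD blocks (blocks far apart
  or on different chromosomes). Within a block, haplotypes share an allele
  frequency (uniform 0.1–0.9) and tags copy the first variant's haplotype
  with probability √r², giving dosage r² equal to the configured 0.5 in
  expectation. The first variant per block is causal and carries the
  smallest p-value; one tag per block is significant-but-correlated (what
  clumping must remove) and the rest sit above the p threshold (what the
  filter must remove), so the correct clumped set is exactly the 20 causal
  variants.
- **Score effects**: labels are drawn from an exponentially tilted
  multinomial given the standardized causal score z:
  P(label g | z) ∝ f_g exp(β_g z) / mean(exp(β_g z)), with β = 0 for
  controls. The log-odds of each case label versus controls is therefore
  *exactly* linear in z with slope β_g, making the logistic evaluation
  correctly specified and its recovery unbiased; marginal label fractions
  stay at their configured values to first order. Per-SD odds ratios
  default to the published values where printed (prevalent MI 1.50,
  prevalent CAD 1.44, self-report CAD 1.08); the unprinted groups (1.35,
  1.30, 1.20) interpolate the reported prevalent > incident > self-report
  gradient. Survival and score effects are planted independently — no
  confounding — because clean parameter recovery is the point of the
  generator.

What the generator does **not** emulate: hospital episode/spell structure,
realistic code frequency distributions, real LD maps, missing-not-at-random
linkage gaps, or correlation between genetic risk and mortality. Passing
recovery tests therefore demonstrates that the *algorithms* are correct
under their stated models, not that real EHR data are this clean.

## Test and evaluation sizes

Recovery suites run at n = 100,000 participants per cohort. Hazard-ratio
coverage uses 10 replicate cohorts (each group's planted HR must fall in
the 95% CI in at least 8), odds-ratio coverage 3 replicates (at least 2) —
a single 95% interval misses its target in 5% of draws by design, so
single-replicate assertions would be noise. Gradient *ordering* is
asserted on replicate-mean log hazard ratios for all pairs whose planted
values are separable at this design's resolution; the 1.77 vs 1.75 pair
differs by 0.011 on the log scale, an order of magnitude below the
per-replicate standard error that the published group sizes admit, and is
treated as tied. The acceptance script reports gradient estimates as
geometric means over 20 replicate cohorts (~2 minutes on one CPU).

## Known limitations

- Primary-care records are out of scope; the hierarchy covers hospital,
  death-registry and baseline-interview sources only.
- No SNOMED/Read-code or ICD-10-CM dialect support; code lists are UK
  ICD-10/ICD-9/OPCS-4 prefixes.
- The PRS module reads dosage matrices as delimited text; VCF/BGEN input
  is a documented extension point, not implemented.
- Duplicate episodes across linked hospital systems are treated as
  independent events; classification only uses the earliest per side, so
  duplicates are harmless but are not deduplicated.
- The shipped code lists are sensible defaults, clearly labelled as such;
  study-specific lists should be supplied as CSV.
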