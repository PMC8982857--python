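# cadphen

Rules-based electronic-health-record (EHR) phenotyping of coronary artery
disease (CAD), with built-in fidelity evaluation and a fully synthetic
linked-biobank generator.

## The problem

Large population biobanks link baseline questionnaires to hospital
admission records (ICD-10/ICD-9 diagnoses, OPCS-4 procedures) and national
death registries. Deciding who "has CAD" from these sources is surprisingly
inconsistent in practice: self-reported disease is unreliable, different
sources have different misclassification rates, and pooling everything into
one case definition can dilute association estimates. `cadphen` implements
a transparent, code-list-driven hierarchy that partitions every participant
into exactly one of six CAD sub-phenotypes or one of two CAD-free control
labels:

1. **EHR-coded MI** (hospital diagnosis or death-registry cause matching
   the MI code list) → `prevalent_MI` or `incident_MI` depending on whether
   the earliest qualifying event falls on/before or after the enrolment
   date;
2. **EHR-coded CAD without MI** (diagnosis, revascularisation procedure,
   death cause, or self-reported revascularisation) → `prevalent_CAD_noMI`
   or `incident_CAD_noMI`;
3. **self-reported heart attack** at the baseline interview → `sr_MI`;
4. **self-reported angina** → `sr_CAD_noMI`;
5. otherwise a CAD-free control: `never_CAD` if the participant has died by
   the censor date (2016-11-01 by default), `no_CAD` if alive.

A participant matched at a step is censored from all later steps, so the
eight labels partition the cohort. When one disease tag has events both
before and after enrolment, a global switch resolves the conflict
(incident by default). Code lists are plain CSV prefix sets
(longest-prefix-wins, so "I25 is chronic IHD except I25.2 which is old MI"
is two rows) and every source x tag combination is configurable.

Because the phenotype labels cannot be validated by chart review at
biobank scale, the package ships the two standard indirect fidelity checks:

- **mortality gradient** — one Cox proportional-hazards model per phenotype
  versus the pooled controls, adjusted for age at enrolment and sex (Efron
  ties, Schoenfeld-residual check), with follow-up from enrolment for
  prevalent/self-report groups and from the qualifying admission for
  incident groups, plus Kaplan–Meier curves;
- **polygenic-score gradient** — a CAD polygenic risk score built from GWAS
  summary weights (p < 5×10⁻⁶, greedy LD clumping at r² = 0.2 within
  250 kb, missing dosages imputed at twice the effect-allele frequency,
  scores standardized to mean 0 / SD 1), with per-SD odds ratios from
  age/sex-adjusted logistic regression per phenotype versus controls.

The `synthetic` module generates a complete linked biobank — baseline,
hospital, death-registry and self-report tables plus a genotype dosage
matrix and weights file — with planted labels, hazard ratios and per-SD
score effects, so every stage of the pipeline has a ground truth to
recover without access to restricted data.

## Worked example

```python
from cadphen import (SimulationConfig, aggregate_all_cad, default_codelist,
                     run_algorithm, simulate_cohort)

cohort, truth = simulate_cohort(SimulationConfig(n=50_000, seed=42, adversarial=True))
assignments, log = run_algorithm(cohort, default_codelist())
counts = aggregate_all_cad(assignments)
merged = assignments.merge(truth, on="pid")
print(counts["all_CAD"], counts["controls"],
      100.0 * (merged["label"] == merged["true_label"]).mean())
```

prints

```
3699 46301 100.0
```

i.e. 3,699 participants fall into one of the six CAD sub-phenotypes,
46,301 are CAD-free controls, and — although the adversarial generator
planted distractor records such as a CAD diagnosis before enrolment for an
incident-MI case — the hierarchy recovered 100% of the planted labels.
Running `python examples/mortality_gradient.py` then fits the Cox models
(e.g. incident MI HR 6.40 [4.97, 8.25] against a planted 6.66) and
`python examples/prs_gradient.py` the score associations (e.g. prevalent
MI OR per SD 1.49 [1.39, 1.58] against a planted 1.50); each example
prints the planted value next to every estimate.

The same pipeline is scriptable from a shell:

```bash
cadphen simulate --seed 5 --n 50000 --out-dir simdata
cadphen phenotype --cohort-dir simdata --out assignments.csv
cadphen eval-survival --assignments assignments.csv --cohort-dir simdata --out hr.csv
cadphen eval-prs --dosages simdata/dosages.csv --weights simdata/weights.csv \
    --assignments assignments.csv --cohort-dir simdata --out or.csv
```

Real cohorts are read from the same five delimited tables (participants,
diagnoses, procedures, deaths, self_reports); a YAML schema config maps
your column names onto the expected fields, and `--codelists` swaps the
shipped default code lists for study-specific ones.

## Layout

- `src/cadphen/model.py` — cohort container, delimited-table I/O, validation
- `src/cadphen/codelists.py` — code normalization, prefix matching, event extraction
- `src/cadphen/phenotyper.py` — the classification hierarchy
- `src/cadphen/survival.py` — Kaplan–Meier and Cox evaluation
- `src/cadphen/prs.py` — LD clumping, scoring, logistic association
- `src/cadphen/synthetic.py` — ground-truth biobank generator
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
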