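"""Recover a planted mortality gradient with age/sex-adjusted Cox models.

Each phenotype is compared with the pooled CAD-free controls; follow-up
starts at enrolment for prevalent/self-report groups and at the qualifying
hospital admission for incident groups.  The planted hazard ratios follow
the published gradient (incident MI 6.66 down to self-reported CAD 1.31).
"""

from cadphen import (
    SimulationConfig,
    build_survival_records,
    default_codelist,
    hazard_table,
    km_curve,
    run_algorithm,
    simulate_cohort,
)
from cadphen.synthetic import DEFAULT_HAZARD_RATIOS

cohort, _ = simulate_cohort(SimulationConfig(n=100_000, seed=7))
assignments, _ = run_algorithm(cohort, default_codelist())
records, log = build_survival_records(assignments, cohort)
print(f"{len(records)} survival records "
      f"({log['n_excluded_death_before_t0']} excluded for death before follow-up start)")

table = hazard_table(records)
print("\nage/sex-adjusted hazard ratio vs CAD-free controls (planted in brackets):")
for row in table.itertuples():
    planted = DEFAULT_HAZARD_RATIOS.get(row.group, float("nan"))
    print(f"  {row.group:20s} HR {row.hr:5.2f} [{row.ci_low:.2f}, {row.ci_high:.2f}]"
          f"  planted {planted:.2f}  PH-check p={row.ph_p:.2f}")
print("(a covered planted value and a non-small PH p-value indicate a faithful fit)")

km = km_curve(records, "incident_MI")
print(f"\nKaplan-Meier for incident MI: survival at last step "
      f"{km['survival'].iloc[-1]:.3f} after {km['time'].iloc[-1]:.0f} days")
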