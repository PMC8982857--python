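"""Build a clumped polygenic risk score and recover a planted odds-ratio
gradient.

Variants below p = 5e-6 are greedily LD-clumped (r² 0.2, 250 kb window);
the remaining weights score every participant, scores are standardized,
and each phenotype's odds ratio per SD versus CAD-free controls is
estimated by age/sex-adjusted logistic regression.
"""

import numpy as np

from cadphen import (
    SimulationConfig,
    association_table,
    compute_prs,
    default_codelist,
    ld_clump,
    run_algorithm,
    simulate_all,
)
from cadphen.synthetic import DEFAULT_PRS_LOG_ODDS

sim = simulate_all(SimulationConfig(n=100_000, seed=19))
assignments, _ = run_algorithm(sim.cohort, default_codelist())

selected = ld_clump(sim.variants, sim.dosages)
print(f"{len(sim.variants)} variants in weights file; "
      f"{(sim.variants['pvalue'] < 5e-6).sum()} below p=5e-6; "
      f"{len(selected)} retained after clumping")

scores = compute_prs(sim.dosages, selected)
print(f"standardized score: mean {scores['z'].mean():+.2e}, SD {scores['z'].std(ddof=0):.6f}")

table = association_table(scores, assignments, sim.cohort)
print("\nodds ratio per 1 SD of the score vs controls (planted in brackets):")
for row in table.itertuples():
    planted = float(np.exp(DEFAULT_PRS_LOG_ODDS.get(row.group, 0.0)))
    note = f"planted {planted:.2f}" if row.group in DEFAULT_PRS_LOG_ODDS else "pooled"
    print(f"  {row.group:20s} OR {row.or_per_sd:5.2f} "
          f"[{row.ci_low:.2f}, {row.ci_high:.2f}]  {note}")
print("(the gradient mirrors the published pattern: strongest for EHR-verified "
      "prevalent disease, weakest for uncorroborated self-report)")
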