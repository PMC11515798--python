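"""DAG-informed Bayesian mediation of the antibiotic effect.

Encodes the study DAG, derives the backdoor adjustment sets, fits the
total- and direct-effect Bayesian negative-binomial models, and reports
the indirect effect as the posterior of the coefficient difference c - c'.
"""

import periomed as pm
from periomed.experiments import final_visit_records
from periomed.mediation import (
    MEDIATOR,
    OUTCOME,
    TREATMENT,
    SamplerConfig,
    backdoor_adjustment_sets,
)

dag = pm.build_study_dag()
print("total-effect adjustment sets:",
      [sorted(s) for s in backdoor_adjustment_sets(dag, TREATMENT, OUTCOME,
                                                   forbidden=(MEDIATOR,))])
print("mediator-outcome adjustment sets:",
      [sorted(s) for s in backdoor_adjustment_sets(dag, MEDIATOR, OUTCOME)])

cohort = pm.generate_cohort(pm.CohortConfig(seed=4))
final = final_visit_records(cohort)

result, report = pm.run_mediation_analysis(final,
                                           sampler=SamplerConfig(seed=0))
print(f"\ntotal effect (c):    RR {result.total_rr:.2f} "
      f"[{result.total_ci[0]:.2f}, {result.total_ci[1]:.2f}]")
print(f"direct effect (c'):  RR {result.direct_rr:.2f} "
      f"[{result.direct_ci[0]:.2f}, {result.direct_ci[1]:.2f}]")
print(f"indirect (c - c'):   RR {result.indirect_rr:.2f} "
      f"[{result.indirect_ci[0]:.2f}, {result.indirect_ci[1]:.2f}]")
print("-> an indirect RR below 1 with the direct interval crossing 1 "
      "indicates the microbial response pattern mediates the antibiotic "
      "benefit; a wide indirect interval supports presence, not magnitude, "
      "of mediation.")
max_rhat = max(max(result.diagnostics["total_rhat"].values()),
               max(result.diagnostics["direct_rhat"].values()))
print(f"sampler diagnostics: max R-hat {max_rhat:.3f}")
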