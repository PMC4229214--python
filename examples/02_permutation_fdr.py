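"""Estimate the false discovery rate of the strict selection rule.

Clinical records (survival, event, age) are re-assigned to samples at
random while the mutation profiles stay fixed; the full screen is
re-run on each shuffled dataset.  The FDR estimate is the fraction of
null results passing the joint rule (p_rank < 0.05, p_cox < 0.05,
CP < 0.025, beta < 0) divided by the observed fraction.
"""

from mmsurv import (
    FdrThresholds,
    SimConfig,
    build_mms_matrix,
    build_null,
    estimate_fdr,
    filter_terms,
    screen_mms,
    simulate_cohort,
    tp53_status,
)
from mmsurv.mms import TermFilter

cohort = simulate_cohort(
    SimConfig(n_samples=160, n_terms=40, n_genes=8000, planted_effects={"GO:9900003": -0.9}, seed=2)
)
terms = filter_terms(cohort.annotation, TermFilter(1, 10**6))
matrix = build_mms_matrix(cohort.mutations, cohort.annotation, terms, sample_ids=cohort.sample_ids)
tp53 = tp53_status(cohort.mutations, cohort.sample_ids)

associations = screen_mms(matrix, cohort.clinical, tp53)
null = build_null(matrix, cohort.clinical, tp53, n_permutations=50, seed=2)
est = estimate_fdr(associations, null, FdrThresholds(), sign="negative_beta")

print(f"null discovery fraction     : {est.null_fraction:.4f}")
print(f"observed discovery fraction : {est.observed_fraction:.4f}")
print(f"estimated FDR               : {est.fdr:.3f}" if est.defined else "no discoveries")
print()
print(
    "With one strongly planted protective term among 40, the observed\n"
    "fraction is dominated by a real effect, so the estimated FDR is\n"
    "well below 1; on a cohort with no planted effects it approaches 1."
)
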