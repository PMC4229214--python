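"""Screen GO-term mutation-burden signatures on a synthetic cohort.

Simulates 320 tumors (~50 somatic mutations each, TP53 in ~70%) with
one planted protective term whose capped burden lowers the hazard by
exp(-0.7) per dose, builds the capped burden matrix, and screens every
term with the log-rank test and the age/TP53-adjusted Cox model.
"""

from mmsurv import SimConfig, build_mms_matrix, filter_terms, screen_mms, simulate_cohort, tp53_status
from mmsurv.mms import TermFilter

cohort = simulate_cohort(SimConfig(planted_effects={"GO:9900003": -0.7}, seed=1))
terms = filter_terms(cohort.annotation, TermFilter(1, 10**6))
matrix = build_mms_matrix(cohort.mutations, cohort.annotation, terms, sample_ids=cohort.sample_ids)
tp53 = tp53_status(cohort.mutations, cohort.sample_ids)

associations = screen_mms(matrix, cohort.clinical, tp53)
top = sorted(associations, key=lambda a: a.cp)[:5]

print(f"{'term':<12}{'beta':>7}{'p_cox':>10}{'p_rank':>10}{'CP':>10}")
for a in top:
    print(f"{a.term_id:<12}{a.beta:>7.2f}{a.p_cox:>10.1e}{a.p_rank:>10.1e}{a.cp:>10.1e}")
print()
print(
    "The planted term should top the list with a negative coefficient\n"
    "(protective: more burden, lower hazard); unplanted terms hover at\n"
    "unremarkable p-values."
)
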