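"""Stratify patients with the two-node feature-set prognosis tree.

Hazard-increasing (negative) predictor burdens are summed first: a
total of 2 or more marks poor prognosis.  Among the rest, the top-k
protective (positive) predictor burdens are summed with the same
threshold to split a good-prognosis group; everyone else is
intermediate.  Groups are then compared with the k-group log-rank.
"""

import numpy as np

from mmsurv import (
    SelectionRule,
    SimConfig,
    TreeConfig,
    build_mms_matrix,
    evaluate_groups,
    filter_terms,
    km_estimate,
    screen_mms,
    select_predictors,
    simulate_cohort,
    tp53_status,
    tree_classify,
)
from mmsurv.mms import TermFilter

planted = {"GO:9900003": -0.7, "GO:9900017": -0.7, "GO:9900042": -0.7}
cohort = simulate_cohort(SimConfig(planted_effects=planted, seed=3))
terms = filter_terms(cohort.annotation, TermFilter(1, 10**6))
matrix = build_mms_matrix(cohort.mutations, cohort.annotation, terms, sample_ids=cohort.sample_ids)
tp53 = tp53_status(cohort.mutations, cohort.sample_ids)

associations = screen_mms(matrix, cohort.clinical, tp53)
predictors = select_predictors(associations, SelectionRule())
k = min(5, len(predictors.positive))
labels = tree_classify(matrix, predictors, TreeConfig(k=k, burden_threshold=2))

print(f"selected predictors : {len(predictors.positive)} positive, {len(predictors.negative)} negative")
print(f"group sizes (k={k})  : {labels.counts()}")

time, event, _ = cohort.clinical.endpoint("OS")
for grp in ("good", "intermediate", "poor"):
    mask = labels.labels == grp
    if mask.sum():
        med = km_estimate(time[mask], event[mask]).median()
        med_txt = f"{med:6.1f}" if np.isfinite(med) else "  not reached"
        print(f"median OS, {grp:<12}: {med_txt} months")

result = evaluate_groups(labels, cohort.clinical, endpoint="OS")
print(f"log-rank across groups: chi2 = {result.statistic:.1f}, df = {result.df}, p = {result.p_value:.2e}")
print()
print(
    "A small log-rank p confirms the tree separates survival profiles;\n"
    "the good group's median OS should exceed the intermediate group's."
)
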