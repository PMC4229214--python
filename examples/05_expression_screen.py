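"""Per-gene expression screening against survival.

Generates an expression matrix tied to a synthetic cohort, with ten
genes whose expression tracks the (log) true survival time, then fits
a Cox model per gene with age as the covariate and keeps genes with
Wald p < 0.01.
"""

from mmsurv import SimConfig, screen_expression, simulate_cohort
from mmsurv.synthetic_data import simulate_expression

cohort = simulate_cohort(SimConfig(n_samples=160, n_terms=10, n_genes=2000, seed=4))
expression = simulate_expression(cohort, n_predictive_genes=10, effect_size=1.5)

hits = screen_expression(expression, cohort.clinical, p_threshold=0.01)
planted = {f"G{i:05d}" for i in range(10)}
recovered = [h.gene for h in hits if h.gene in planted]

print(f"genes passing p < 0.01 : {len(hits)} of {expression.shape[0]}")
print(f"planted genes recovered: {len(recovered)} of 10 -> {recovered}")
print("top five hits:")
for h in hits[:5]:
    flag = "planted" if h.gene in planted else "chance"
    print(f"  {h.gene}  beta = {h.beta:+.3f}  p = {h.p:.2e}  ({flag})")
print()
print(
    "Higher expression of the planted genes accompanies longer survival,\n"
    "so their coefficients are negative; the remaining hits are the\n"
    "~1% false positives expected at this threshold."
)
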