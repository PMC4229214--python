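"""Small packaged reference tables.

``OVARIAN_OS_SCREENING`` is the published screening summary for the
22 signature predictors of overall survival in the TCGA high-grade
serous ovarian carcinoma training cohort (320 samples): per GO term,
the Cox coefficient, the two test p-values as printed (two significant
digits), the printed composite p-value, the member-gene counts N1/N2
and the term name.  It is shipped so worked examples and consistency
checks can recompute the composite statistic from the printed
p-value pairs without any external download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["OVARIAN_OS_SCREENING", "ovarian_os_screening"]

# columns: term id, direction, beta, cox p, log-rank p, printed CP, N1, N2, name
_ROWS = [
    ("GO:0000786", "positive", -0.67, 4.4e-2, 4.3e-5, 1.4e-3, 65, 25, "nucleosome"),
    ("GO:0005765", "positive", -0.28, 1.1e-2, 3.7e-4, 2.0e-3, 232, 135, "lysosomal membrane"),
    ("GO:0050900", "positive", -0.42, 1.9e-3, 3.8e-3, 2.7e-3, 110, 92, "leukocyte migration"),
    ("GO:0007229", "positive", -0.44, 3.0e-3, 8.0e-3, 4.9e-3, 77, 80, "integrin-mediated signaling pathway"),
    ("GO:0010923", "positive", -0.54, 1.1e-2, 3.1e-3, 5.7e-3, 51, 49, "negative regulation of phosphatase activity"),
    ("GO:0007584", "positive", -0.63, 3.4e-3, 1.1e-2, 6.1e-3, 67, 54, "response to nutrient"),
    ("GO:0007067", "positive", -0.36, 4.5e-3, 8.5e-3, 6.2e-3, 245, 126, "mitosis"),
    ("GO:0007160", "positive", -0.41, 8.2e-3, 7.0e-3, 7.6e-3, 79, 75, "cell-matrix adhesion"),
    ("GO:0000910", "positive", -0.58, 2.0e-3, 3.0e-2, 7.8e-3, 64, 54, "cytokinesis"),
    ("GO:0006928", "positive", -0.49, 1.0e-2, 5.9e-3, 7.8e-3, 97, 60, "cellular component movement"),
    ("GO:0001666", "positive", -0.31, 1.4e-2, 7.4e-3, 1.0e-2, 153, 115, "response to hypoxia"),
    ("GO:0000922", "positive", -0.39, 7.0e-3, 1.6e-2, 1.1e-2, 86, 77, "spindle pole"),
    ("GO:0031965", "positive", -0.33, 1.7e-2, 8.6e-3, 1.2e-2, 162, 108, "nuclear membrane"),
    ("GO:0005813", "positive", -0.21, 2.6e-2, 7.4e-3, 1.4e-2, 353, 165, "centrosome"),
    ("GO:0004674", "positive", -0.23, 1.7e-2, 1.3e-2, 1.5e-2, 374, 217, "protein serine/threonine kinase activity"),
    ("GO:0070374", "positive", -0.36, 3.1e-2, 9.1e-3, 1.7e-2, 97, 57, "positive regulation of ERK1 and ERK2 cascade"),
    ("GO:0044325", "positive", -0.37, 9.1e-3, 3.5e-2, 1.8e-2, 71, 87, "ion channel binding"),
    ("GO:0055037", "positive", -0.63, 1.5e-2, 2.7e-2, 2.0e-2, 60, 37, "recycling endosome"),
    ("GO:0004843", "positive", -0.46, 1.8e-2, 2.9e-2, 2.3e-2, 55, 39, "ubiquitin-specific protease activity"),
    ("GO:0051436", "negative", 0.55, 2.5e-2, 1.0e-3, 5.1e-3, 65, 27,
     "negative regulation of ubiquitin-protein ligase activity involved in mitotic cell cycle"),
    ("GO:0045666", "negative", 0.15, 4.0e-1, 3.6e-3, 3.8e-2, 68, 50, "positive regulation of neuron differentiation"),
    ("GO:0042393", "negative", 0.17, 3.6e-1, 7.1e-3, 5.0e-2, 62, 47, "histone binding"),
]

OVARIAN_OS_SCREENING = pd.DataFrame(
    _ROWS,
    columns=["term_id", "direction", "beta", "p_cox", "p_rank", "cp_printed", "n1", "n2", "name"],
)


def ovarian_os_screening() -> pd.DataFrame:
    """A fresh copy of the published screening summary table."""
    return OVARIAN_OS_SCREENING.copy()
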