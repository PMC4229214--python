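"""Expression-based survival screening and Wang GO semantic similarity.

Two pieces used to compare mutation-derived signatures with
expression-derived ones: a per-gene Cox screen of an expression matrix
against survival (age-adjusted, following the expression analysis
convention of using age as the only covariate), and the Wang (2007)
graph-based semantic similarity between GO terms, in which each
ancestor of a term contributes a relation-weighted S-value and two
terms are similar in proportion to the S-value mass of their shared
ancestors.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mmsurv.io_formats import ClinicalTable, GODag
from mmsurv.survival_stats import coxph_fit

logger = logging.getLogger(__name__)

__all__ = [
    "SemanticWeights",
    "ExpressionHit",
    "screen_expression",
    "wang_similarity",
    "similarity_matrix",
]


@dataclass(frozen=True)
class SemanticWeights:
    """Semantic contribution per relation; strictly inside (0, 1).

    The published defaults of the Wang measure: 0.8 for is_a, 0.6 for
    part_of.  Weights below one guarantee S-values decay with distance,
    which makes the similarity 1 only for identical terms.
    """

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self):
        for w in (self.w_is_a, self.w_part_of):
            if not 0 < w < 1:
                raise ValueError("semantic weights must lie strictly in (0, 1)")

    def of(self, relation: str) -> float:
        return self.w_is_a if relation == "is_a" else self.w_part_of


@dataclass(frozen=True)
class ExpressionHit:
    """One gene passing the expression survival screen."""

    gene: str
    beta: float
    p: float


def screen_expression(
    expression: pd.DataFrame,
    clinical: ClinicalTable,
    p_threshold: float = 0.01,
    endpoint: str = "OS",
    standardize: bool = False,
) -> list[ExpressionHit]:
    """Per-gene Cox screen of a genes x samples expression matrix.

    Each gene is fitted with covariates [expression, age]; genes whose
    expression-coefficient Wald p falls below ``p_threshold`` are
    returned, ordered by p ascending.  Constant rows are skipped with
    a logged count.  ``standardize`` z-scores each gene first, which
    rescales beta but not its p-value.
    """
    common = [s for s in expression.columns if s in set(clinical.sample_ids)]
    if len(common) < 10:
        raise ValueError("fewer than 10 samples shared between expression and clinical data")
    clin = clinical.subset(common)
    time, event, keep = clin.endpoint(endpoint)
    age = clin.rows["age"].to_numpy(float)[keep]
    X = expression[common].to_numpy(float)[:, keep]

    hits = []
    n_skipped = 0
    for gene, row in zip(expression.index, X):
        if np.ptp(row) == 0:
            n_skipped += 1
            continue
        x = (row - row.mean()) / row.std() if standardize else row
        fit = coxph_fit(time, event, np.column_stack([x, age]))
        if fit.p_values[0] < p_threshold:
            hits.append(ExpressionHit(gene=str(gene), beta=float(fit.beta[0]), p=float(fit.p_values[0])))
    if n_skipped:
        logger.info("screen_expression: skipped %d constant genes", n_skipped)
    return sorted(hits, key=lambda h: h.p)


def _svalues(term: str, dag: GODag, weights: SemanticWeights) -> dict[str, float]:
    """Wang S-values of every ancestor of ``term`` (term itself = 1).

    S(t) is the largest product of relation weights along a path from
    the term up to t; with weights < 1 this is a max-product shortest
    path, solved Dijkstra-style.
    """
    S = {term: 1.0}
    heap = [(-1.0, term)]
    while heap:
        negs, t = heapq.heappop(heap)
        s = -negs
        if s < S.get(t, 0.0):
            continue
        for parent, rel in dag.parents(t):
            cand = s * weights.of(rel)
            if cand > S.get(parent, 0.0):
                S[parent] = cand
                heapq.heappush(heap, (-cand, parent))
    return S


def wang_similarity(
    term_a: str, term_b: str, dag: GODag, weights: SemanticWeights = SemanticWeights()
) -> float:
    """Wang semantic similarity between two GO terms of one namespace.

    sim(A, B) = sum over shared ancestors t of S_A(t) + S_B(t),
    divided by SV(A) + SV(B) where SV is each term's total S-value
    mass.  Lies in (0, 1] and equals 1 only for identical terms.
    """
    for t in (term_a, term_b):
        if t not in dag:
            raise KeyError(f"term {t!r} not present in the ontology")
    ns_a, ns_b = dag.namespace(term_a), dag.namespace(term_b)
    if ns_a != ns_b:
        raise ValueError(f"terms belong to different namespaces: {ns_a!r} vs {ns_b!r}")
    sa = _svalues(term_a, dag, weights)
    sb = _svalues(term_b, dag, weights)
    shared = set(sa) & set(sb)
    return float(sum(sa[t] + sb[t] for t in shared) / (sum(sa.values()) + sum(sb.values())))


def similarity_matrix(
    row_terms: list[str],
    col_terms: list[str],
    dag: GODag,
    weights: SemanticWeights = SemanticWeights(),
) -> pd.DataFrame:
    """Pairwise Wang similarities, rows x columns.

    Cross-namespace pairs get NaN rather than raising, so mixed term
    lists (e.g. expression signatures spanning all three GO branches)
    can be compared in one call.
    """
    all_terms = set(row_terms) | set(col_terms)
    missing = sorted(t for t in all_terms if t not in dag)
    if missing:
        raise KeyError(f"terms not present in the ontology: {missing}")
    svals = {t: _svalues(t, dag, weights) for t in all_terms}
    out = np.full((len(row_terms), len(col_terms)), np.nan)
    for i, a in enumerate(row_terms):
        for j, b in enumerate(col_terms):
            if dag.namespace(a) != dag.namespace(b):
                continue
            sa, sb = svals[a], svals[b]
            shared = set(sa) & set(sb)
            out[i, j] = sum(sa[t] + sb[t] for t in shared) / (
                sum(sa.values()) + sum(sb.values())
            )
    return pd.DataFrame(out, index=row_terms, columns=col_terms)
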