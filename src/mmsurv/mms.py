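"""Macro mutation signatures: capped GO-term-level mutation burdens.

A macro mutation signature (MMS) for one GO term counts, per tumor
sample, the somatic mutations on the term's member genes — excluding
TP53, whose near-universal mutation would otherwise dominate every
term it belongs to — and caps the count at a ceiling (default 2).
The cap encodes the dose-dependent reading of the survival curves:
one mutation on a gene set rarely shifts prognosis, two or more do,
and capping blunts leverage points from hyper-mutated samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mmsurv.io_formats import GOAnnotation, MutationTable

logger = logging.getLogger(__name__)

__all__ = ["TermFilter", "MMSMatrix", "filter_terms", "build_mms_matrix", "tp53_status"]

DEFAULT_EXCLUDED_GENES = frozenset({"TP53"})


@dataclass(frozen=True)
class TermFilter:
    """Inclusive bounds on GO-term gene-set size (default 50..500).

    Small terms give burdens too sparse to test; huge terms are too
    broad to interpret.
    """

    min_genes: int = 50
    max_genes: int = 500

    def __post_init__(self):
        if not (0 < self.min_genes <= self.max_genes):
            raise ValueError("require 0 < min_genes <= max_genes")


@dataclass
class MMSMatrix:
    """Samples x terms matrix of capped mutation burdens.

    ``values[i, j]`` is min(raw burden of sample i on term j, cap), so
    every entry lies in {0, 1, ..., cap}.  ``n1``/``n2`` carry, per
    term, the member-gene count and the number of member genes mutated
    in at least one sample (the N1/N2 columns of the screening table);
    they are filled by :func:`build_mms_matrix`.
    """

    values: np.ndarray
    sample_ids: list[str]
    term_ids: list[str]
    cap: int = 2
    n1: np.ndarray | None = None
    n2: np.ndarray | None = None
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sample_ids), len(self.term_ids)):
            raise ValueError("values shape must be (n_samples, n_terms)")

    def column(self, term_id: str) -> np.ndarray:
        return self.values[:, self.term_ids.index(term_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.term_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def filter_terms(annotation: GOAnnotation, term_filter: TermFilter = TermFilter()) -> list[str]:
    """Terms whose gene-set size falls within the filter bounds, sorted."""
    return sorted(
        term
        for term, genes in annotation.term_to_genes.items()
        if term_filter.min_genes <= len(genes) <= term_filter.max_genes
    )


def build_mms_matrix(
    mutations: MutationTable,
    annotation: GOAnnotation,
    terms: list[str],
    sample_ids: list[str] | None = None,
    excluded_genes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_GENES,
    cap: int | None = 2,
) -> MMSMatrix:
    """Aggregate mutation records into the capped burden matrix.

    Each mutation record of sample i on a gene in term j's set (minus
    ``excluded_genes``) increments the raw entry; multiple records on
    one gene all count, and a gene in several terms contributes to
    each.  The stored entry is ``min(raw, cap)``; ``cap=None`` keeps
    raw counts.  Mutated genes absent from every term are only
    reported as an aggregate count.
    """
    for term in terms:
        if term not in annotation.term_to_genes:
            raise KeyError(f"term {term!r} not present in the annotation")
    if sample_ids is None:
        sample_ids = mutations.sample_ids
    excluded = {g.upper() for g in excluded_genes}

    rec = mutations.records
    rec = rec[rec["sample_id"].isin(set(sample_ids))]
    all_mutated = set(rec["gene_symbol"])
    rec = rec[~rec["gene_symbol"].isin(excluded)]

    # dense (samples x mutated genes) record-count matrix, then one
    # matrix product against term membership
    genes = sorted(set(rec["gene_symbol"]))
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    C = np.zeros((len(sample_ids), len(genes)), dtype=np.int64)
    if len(rec):
        si = rec["sample_id"].map(sample_index).to_numpy()
        gi = rec["gene_symbol"].map(gene_index).to_numpy()
        np.add.at(C, (si, gi), 1)
    M = np.zeros((len(genes), len(terms)), dtype=np.int64)
    n1 = np.zeros(len(terms), dtype=np.int64)
    n2 = np.zeros(len(terms), dtype=np.int64)
    for j, term in enumerate(terms):
        members = annotation.term_to_genes[term]
        n1[j] = len(members)
        n2[j] = len(members & all_mutated)
        for g in (members - excluded) & set(genes):
            M[gene_index[g], j] = 1
    raw = C @ M

    annotated = set().union(*(annotation.term_to_genes[t] for t in terms)) if terms else set()
    n_unannotated = len(set(genes) - annotated)
    if n_unannotated:
        logger.info("%d mutated genes fall in no selected term", n_unannotated)

    values = raw if cap is None else np.minimum(raw, cap)
    return MMSMatrix(
        values=values,
        sample_ids=list(sample_ids),
        term_ids=list(terms),
        cap=int(cap) if cap is not None else np.iinfo(np.int64).max,
        n1=n1,
        n2=n2,
        term_names={t: annotation.name(t) for t in terms},
    )


def tp53_status(mutations: MutationTable, sample_ids: list[str]) -> np.ndarray:
    """Binary indicator (not count) of any TP53 mutation per sample."""
    rec = mutations.records
    carriers = set(rec.loc[rec["gene_symbol"] == "TP53", "sample_id"])
    return np.array([1 if s in carriers else 0 for s in sample_ids], dtype=np.int64)
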