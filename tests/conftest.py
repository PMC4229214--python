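import networkx as nx
import numpy as np
import pytest

from mmsurv import SimConfig, simulate_cohort
from mmsurv.io_formats import GODag
from mmsurv.mms import build_mms_matrix, filter_terms, tp53_status
from mmsurv.mms import TermFilter


# scaled-down cohort for unit tests: same per-term burden regime as the
# full defaults (coverage ~1%, so capped burdens are mostly 0/1)
SMALL = dict(
    n_samples=120,
    n_genes=10000,
    n_terms=20,
    term_size_range=(50, 200),
    seed=7,
)


@pytest.fixture(scope="session")
def null_cohort():
    """A small cohort with no planted term effects."""
    return simulate_cohort(SimConfig(**SMALL))


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with one strongly protective planted term."""
    cfg = SimConfig(**{**SMALL, "planted_effects": {"GO:9900003": -0.9}})
    return simulate_cohort(cfg)


def cohort_inputs(cohort, term_filter=None):
    """(burden matrix, clinical, tp53) for a synthetic cohort."""
    terms = filter_terms(cohort.annotation, term_filter or TermFilter(1, 10**6))
    matrix = build_mms_matrix(
        cohort.mutations, cohort.annotation, terms, sample_ids=cohort.sample_ids
    )
    tp53 = tp53_status(cohort.mutations, cohort.sample_ids)
    return matrix, cohort.clinical, tp53


@pytest.fixture(scope="session")
def planted_inputs(planted_cohort):
    return cohort_inputs(planted_cohort)


def toy_dag(edges, namespaces=None):
    """Build a GODag from (child, parent, relation) triples."""
    g = nx.MultiDiGraph()
    nodes = {n for e in edges for n in e[:2]}
    for n in nodes:
        g.add_node(n, namespace=(namespaces or {}).get(n, "biological_process"))
    for child, parent, rel in edges:
        g.add_edge(child, parent, key=rel)
    return GODag(graph=g)
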