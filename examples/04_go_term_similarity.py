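"""Wang semantic similarity between GO terms on a toy ontology.

Each ancestor of a term contributes an S-value: 1 for the term itself,
decaying by 0.8 per is_a edge (0.6 per part_of) along the best path.
Two terms are similar in proportion to the S-value mass of their
shared ancestors.
"""

import networkx as nx

from mmsurv import similarity_matrix, wang_similarity
from mmsurv.io_formats import GODag
from mmsurv.similarity import SemanticWeights

g = nx.MultiDiGraph()
edges = [
    ("GO:0000011", "GO:0000001", "is_a"),
    ("GO:0000012", "GO:0000001", "is_a"),
    ("GO:0000111", "GO:0000011", "is_a"),
    ("GO:0000112", "GO:0000011", "part_of"),
]
for n in {x for e in edges for x in e[:2]}:
    g.add_node(n, namespace="biological_process")
for c, p, rel in edges:
    g.add_edge(c, p, key=rel)
dag = GODag(graph=g)

siblings = wang_similarity("GO:0000011", "GO:0000012", dag)
print(f"siblings sharing only the root : {siblings:.4f}")
print(f"self-similarity                : {wang_similarity('GO:0000011', 'GO:0000011', dag):.4f}")

mat = similarity_matrix(
    ["GO:0000111", "GO:0000112"], ["GO:0000011", "GO:0000012"], dag, SemanticWeights()
)
print()
print("similarity matrix (children x upper terms):")
print(mat.round(3))
print()
print(
    "Values lie in (0, 1]; 1 only for identical terms.  The part_of\n"
    "child (GO:0000112) is less similar to its ancestors than the is_a\n"
    "child because part_of carries the smaller semantic weight."
)
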