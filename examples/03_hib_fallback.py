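"""Rescue a query with no essential GO terms via hierarchical (HIB) mapping.

A query annotated only with non-essential terms projects to a null feature
vector.  Because GO terms live in a per-taxonomy DAG, a non-essential term
G still contributes f_G * w(d) to the effective count of an essential term
E at hierarchy distance d (default decay w(d) = 2^-d, cutoff D = 5).
"""

from collections import Counter

import numpy as np

import sparseloc as sl
from sparseloc.go_features import GoTerm
from sparseloc.hib import HibParams, dag_distance, map_to_essential
from sparseloc.multilabel import EssentialTermSet

dag, _db = sl.make_toy_dag(depth=3, branching=2, extra_edge_frac=0.1, seed=1)
cc_nodes = sorted(n for n, c in dag.categories.items() if c == "CC")
root = next(iter(dag.roots("CC")))
essential = EssentialTermSet(np.array([0]), (GoTerm(root, "CC"),))

leaf = cc_nodes[-1]
d = dag_distance(dag, leaf, root)
print(f"essential term: {root}; query annotated with {leaf} (count 3), "
      f"hierarchy distance {d:.0f}")

query = Counter({GoTerm(leaf, "CC"): 3})
effective = map_to_essential(query, essential, dag, HibParams(max_distance=5))
print(f"effective count of {root}: {effective[0]:.4f}  (= 3 * 2^-{d:.0f})")

plain = map_to_essential(query, essential, dag, HibParams(max_distance=0))
print(f"with D = 0 the mapping reduces to plain projection: {plain[0]:.1f} "
      "(null here, since the query lacks the essential term itself)")
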