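import sys
from collections import Counter
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sparseloc.go_features import GoTerm, GoVocabulary


@pytest.fixture
def rng():
    return np.random.default_rng(20160224)


@pytest.fixture
def small_vocab():
    terms = tuple(
        GoTerm(f"GO:{1000 + j:07d}", ("CC", "MF", "BP")[j % 3]) for j in range(6)
    )
    return GoVocabulary(terms, {t.id: j for j, t in enumerate(terms)})


@pytest.fixture
def annotation_tsv():
    """3-accession fixture whose per-term tallies are hand-countable."""
    return [
        "P1\tGO:0005634\tCC\n",
        "P1\tGO:0005634\tCC\n",
        "P1\tGO:0003677\tMF\n",
        "P2\tGO:0006355\tBP\t3\n",
        "P3\tGO:0005737\tCC\n",
        "P3\tGO:0005634\tCC\n",
    ]


@pytest.fixture
def tiny_obo():
    """Five-term single-taxonomy ontology: chain C -> B -> A plus D part_of B."""
    return """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: cellular_component

[Term]
id: GO:0000002
name: b
namespace: cellular_component
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: c
namespace: cellular_component
is_a: GO:0000002 ! b

[Term]
id: GO:0000004
name: d
namespace: cellular_component
relationship: part_of GO:0000002 ! b

[Term]
id: GO:0000005
name: gone
namespace: cellular_component
is_obsolete: true
"""


def multiset(*items):
    """Helper: build a GO multiset from (id, category, count) tuples."""
    ms = Counter()
    for go_id, category, count in items:
        ms[GoTerm(go_id, category)] += count
    return ms
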