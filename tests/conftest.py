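import numpy as np
import pytest

from gofuse.ontology import parse_obo
from gofuse.synthetic import SyntheticConfig, generate_world, split_zero_shot

TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: mid process
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: leaf process
namespace: biological_process
is_a: GO:0000002 ! mid process

[Term]
id: GO:0000009
name: molecular thing
namespace: molecular_function
"""


@pytest.fixture
def chain_graph():
    """root ← mid ← leaf, namespace BP."""
    return parse_obo(TOY_OBO, "BP")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture(scope="session")
def small_world():
    """A tiny but complete synthetic world for fast pipeline tests."""
    cfg = SyntheticConfig(
        n_proteins=60, n_terms=12, latent_dim=6, d_seq=10, d_text=14,
        mean_annotations=2.0, zero_shot_fraction=0.25, seed=42,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_split(small_world):
    return split_zero_shot(small_world)


def random_toy_dag(rng, n_terms: int):
    """Random-tree OntologyGraph over n_terms BP terms (test helper)."""
    from gofuse.ontology import OntologyGraph, Term

    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    g = OntologyGraph(namespace="BP", version_tag="toy")
    for tid in ids:
        g.terms[tid] = Term(id=tid)
        g.dag.add_node(tid)
    for i in range(1, n_terms):
        parent = int(rng.integers(0, i))
        g.dag.add_edge(ids[i], ids[parent])
    return g, ids
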