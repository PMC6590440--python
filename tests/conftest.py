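import numpy as np
import pytest

from plastevol.content import ContentMatrix, load_catalog
from plastevol.simulate import (
    FIXTURE_TREE_14,
    MINI_CLADE_TREE,
    SimulationConfig,
    _published_orders,
    content_matrix_states,
    simulate_history,
)
from plastevol.trees import parse_newick

RATE_TREE = "(A:0.12,B:0.18,(C:0.10,(D:0.15,E:0.25)DE:0.08)CDE:0.08);"


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from plastevol.simulate import make_fixture_set

    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_set(7, out)


@pytest.fixture(scope="session")
def mini_clade():
    """Scripted 7-taxon history: a static lineage, one DR tip, and
    IR->DR->IR trajectories via overlapping repeat-spanning inversions."""
    config = SimulationConfig(
        seed=7,
        tree=MINI_CLADE_TREE,
        n_inversions=0,
        loss_rate=0.0,
        branch_events={
            "Dynamic": [("invert", 26, 31)],
            "T5": [("invert", 26, 30)],
            "T67": [("invert", 25, 31)],
            "T7": [("invert", 2, 5)],
            "Static": [("lose", "trnT-GGU")],
        },
    )
    return simulate_history(config)


@pytest.fixture(scope="session")
def published_orders():
    return _published_orders()


@pytest.fixture(scope="session")
def content_matrix():
    df = content_matrix_states()
    cat = load_catalog()
    categories = {e: cat.loc[e, "category"] for e in df.columns if e in cat.index}
    return ContentMatrix(states=df, categories=categories)


@pytest.fixture(scope="session")
def lycophyte_tree():
    return parse_newick(FIXTURE_TREE_14)


@pytest.fixture(scope="session")
def random_genomes():
    """A small bank of simulated quadripartite genomes across seeds."""
    out = []
    for seed in (3, 11, 42):
        cfg = SimulationConfig(seed=seed, n_inversions=1, p_span_repeat=0.5, loss_rate=0.02)
        records, truth = simulate_history(cfg)
        out.append((records, truth))
    return out
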