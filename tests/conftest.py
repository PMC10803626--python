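import numpy as np
import pytest

from lncdap.pipeline import PipelineConfig, run_pipeline_core
from lncdap.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study conditions: 80 diseases x 120 lncRNAs,
    rank 4, density 0.1, 10% hidden positives, master seed 42."""
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced conditions for fast I/O, CLI and ablation tests."""
    return generate_fixture(FixtureSpec(n_diseases=15, n_lncrnas=20, rank=3,
                                        seq_len_range=(60, 90), seed=7))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    """One full pipeline run on the default conditions, shared across tests."""
    cfg = PipelineConfig(seed=1)
    return run_pipeline_core(bundle.A_observed, bundle.dag, bundle.sequences, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dag_edges(rng, n=10):
    """Random acyclic child->parent edges over n nodes (node i's parents
    are drawn among nodes with smaller index)."""
    names = [f"d{i}" for i in range(n)]
    edges = []
    for i in range(1, n):
        k = int(rng.integers(0, min(i, 3) + 1))
        for p in rng.choice(i, size=k, replace=False):
            edges.append((names[i], names[int(p)]))
    if not edges:
        edges.append((names[1], names[0]))
    return names, edges
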