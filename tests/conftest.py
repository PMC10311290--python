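import numpy as np
import pytest

import crosstype as ct


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic species pair with full ground truth."""
    return ct.simulate_pair(ct.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def quick_sim():
    """A small, fast pair for functional tests that need a trained model."""
    return ct.simulate_pair(ct.SimulationConfig(
        seed=0, n_types=3, cells_per_type_a=40, cells_per_type_b=30,
        n_genes_shared=80, n_genes_specific_a=15, n_genes_specific_b=15))


def quick_pipeline_config(seed: int = 0) -> ct.PipelineConfig:
    cfg = ct.PipelineConfig(seed=seed)
    cfg.model.epochs = 40
    cfg.model.batch_per_species = 192
    return cfg


@pytest.fixture(scope="session")
def quick_run(quick_sim):
    """Full pipeline run on the quick fixture; shared by downstream tests."""
    cfg = quick_pipeline_config()
    result, model, graph = ct.run_pipeline(
        quick_sim.expr_a, quick_sim.expr_b, quick_sim.correspondence, cfg,
        emb_a=quick_sim.emb_a, emb_b=quick_sim.emb_b)
    return {"result": result, "model": model, "graph": graph, "cfg": cfg}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_embedding_sets(rng, n_a=10, n_b=10, dim=6):
    A = ct.ProteinEmbeddingSet("A", {f"a{i}": rng.normal(size=dim) for i in range(n_a)})
    B = ct.ProteinEmbeddingSet("B", {f"b{j}": rng.normal(size=dim) for j in range(n_b)})
    return A, B
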