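import numpy as np
import pytest

import dartfish as df
from dartfish.decoder import DecoderConfig
from dartfish.simulate import truth_frame


@pytest.fixture(scope="session")
def brain_pool():
    """All multi-color barcodes of the 6-round, 3-on design (480 of them)."""
    return df.enumerate_barcodes(6, 3, multicolor_only=True)


@pytest.fixture(scope="session")
def brain_codebook(brain_pool):
    """121 genes + 10 empty barcodes drawn from an independent set."""
    seed = df.find_seed_set(brain_pool, n_restarts=50, rng_seed=0)
    graph = df.conflict_graph(brain_pool)
    mis = df.select_mis(graph, seed, n_runs=300, rng_seed=0)
    genes = [f"G{i:03d}" for i in range(121)]
    return df.assign_genes(mis, genes, 10, rng_seed=0)


@pytest.fixture(scope="session")
def tiny_codebook(brain_pool):
    """Small codebook (34 genes + 6 empties) for fast decoding tests."""
    seed = df.find_seed_set(brain_pool, n_restarts=20, rng_seed=1)
    mis = df.select_mis(df.conflict_graph(brain_pool), seed, n_runs=50,
                        rng_seed=1)
    genes = [f"g{i:02d}" for i in range(34)]
    return df.assign_genes(mis[:40], genes, 6, rng_seed=1)


@pytest.fixture(scope="session")
def tiny_sim(tiny_codebook):
    """A small simulated field of view with known truth and coefficients."""
    stack, truth, coeffs = df.simulate_fov(
        tiny_codebook, 800, shape=(256, 256), rng_seed=3)
    return {"stack": stack, "truth": truth_frame(truth), "coeffs": coeffs,
            "codebook": tiny_codebook}


@pytest.fixture(scope="session")
def tiny_decode(tiny_sim):
    """Full SpD fit + spot calls on the small simulation (shared, costly)."""
    model = df.SparseDeconvolution(tiny_sim["stack"], tiny_sim["codebook"],
                                   DecoderConfig(rng_seed=5))
    res = model.fit()
    spots = res.call_spots()
    return {"results": res, "spots": spots, **tiny_sim}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
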