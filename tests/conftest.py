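import numpy as np
import pytest

from lvlink.containers import LabelledMatrix, LatentModel
from lvlink.simulate import generate_models, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(n_individuals=800, n_snps=40, n_blocks=10,
                          within_block_r=0.8, maf_range=(0.1, 0.4), seed=11)


@pytest.fixture(scope="session")
def small_models(small_panel):
    return generate_models(small_panel, n_genes=8, tissues_per_gene=3,
                           snps_per_model=2, seed=12, genes_per_block=2)


@pytest.fixture()
def tiny_model():
    rng = np.random.default_rng(0)
    Z = rng.uniform(0.0, 0.05, size=(20, 4))
    for j in range(4):
        Z[5 * j:5 * (j + 1), j] += 1.0
    return LatentModel(Z, lambda2=0.4,
                       gene_ids=[f"g{i}" for i in range(20)],
                       lv_ids=[f"LV{j}" for j in range(4)])


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(1)
    return LabelledMatrix(rng.standard_normal((20, 3)),
                          [f"g{i}" for i in range(20)], ["t0", "t1", "t2"],
                          orientation="rows=genes")
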