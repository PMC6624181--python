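import numpy as np
import pytest

from pharaoh_gee import (
    ClusteredPhenotypes,
    GenotypeMatrix,
    PathwayAnnotation,
    build_design,
)
from pharaoh_gee.simulate import SimulationConfig, simulate_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_annotation():
    """Two pathways x two genes, five variants, one gene shared across pathways."""
    variant_to_gene = {
        "v1": "G1",
        "v2": "G1",
        "v3": "G2",
        "v4": "G3",
        "v5": "G3",
    }
    pathway_to_genes = {"pwA": ["G1", "G2"], "pwB": ["G2", "G3"]}
    return PathwayAnnotation.from_maps(variant_to_gene, pathway_to_genes)


@pytest.fixture
def tiny_genotypes(rng):
    n, v = 12, 5
    maf = np.array([0.01, 0.02, 0.03, 0.005, 0.04])
    dosages = rng.binomial(2, np.tile(np.minimum(maf * 8, 0.45), (n, 1))).astype(float)
    # guarantee every gene has at least one carrier so no column is dropped
    dosages[0, :] = 1.0
    dosages[1, 2] = 2.0
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=[f"s{i}" for i in range(n)],
        variant_ids=[f"v{j + 1}" for j in range(v)],
        maf=maf,
    )


@pytest.fixture
def tiny_design(tiny_genotypes, tiny_annotation):
    return build_design(tiny_genotypes, tiny_annotation)


@pytest.fixture
def gaussian_data(tiny_design, rng):
    beta_true = np.array([0.8, -0.5])
    eta = 0.3 + tiny_design.X[:, 1] * beta_true[0] + tiny_design.X[:, 3] * beta_true[1]
    Y = eta[:, None] + rng.normal(scale=0.5, size=(tiny_design.N, 2))
    return ClusteredPhenotypes(Y=Y, family="gaussian")


@pytest.fixture(scope="session")
def study_replicate():
    """One simulated replicate at reduced scale, shared across slower tests."""
    cfg = SimulationConfig(N=300, K=5, genes_per_pathway=5, H1=2, w=1.5, beta=0.4, seed=7)
    rep = simulate_replicate(cfg, np.random.default_rng(7))
    design = build_design(rep.genotypes, rep.annotation)
    Y = ClusteredPhenotypes(Y=rep.Y, family="binomial")
    return rep, design, Y
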