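import numpy as np
import pandas as pd
import pytest

from sigtarget.features import assemble_feature_table
from sigtarget.simulate import SimulationConfig, generate_benchmark
from sigtarget.types import Compendium, build_candidate_space


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted benchmark shared across tests."""
    config = SimulationConfig(
        n_genes=300,
        n_kd_genes=80,
        n_cells=3,
        n_drugs=16,
        n_controls_per_cell=4,
        noise_sd=0.5,
        seed=42,
    )
    return generate_benchmark(config)


@pytest.fixture(scope="session")
def small_compendium(small_bundle):
    return Compendium(small_bundle.signatures, small_bundle.meta)


@pytest.fixture(scope="session")
def small_features(small_bundle, small_compendium):
    tables = []
    for drug in sorted(small_bundle.truth):
        space = build_candidate_space(small_compendium, drug)
        tables.append(
            assemble_feature_table(
                space, small_compendium, small_bundle.network,
                small_bundle.locmap, x=20,
            )
        )
    return pd.concat(tables, ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def mini_compendium(columns):
    """Build a Compendium from rows of
    (sample_id, pert_type, perturbagen, cell, kd_gene, vector)."""
    from sigtarget.types import SampleMeta, SignatureMatrix

    ids = [c[0] for c in columns]
    z = np.column_stack([c[5] for c in columns])
    matrix = SignatureMatrix(
        gene_ids=[f"g{i}" for i in range(z.shape[0])], sample_ids=ids, z=z
    )
    meta = [
        SampleMeta(sample_id=c[0], perturbagen_id=c[2], pert_type=c[1],
                   cell_line=c[3], kd_gene=c[4])
        for c in columns
    ]
    return Compendium(matrix, meta)
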