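from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from effectoronset import SimulationConfig, simulate_dataset
from effectoronset.onset import TIME_GRID


@pytest.fixture(scope="session")
def small_bundle():
    """Default-noise synthetic bundle, 250 genes, fixed seed."""
    return simulate_dataset(SimulationConfig(n_genes=250, seed=7))


@pytest.fixture(scope="session")
def zero_noise_bundle():
    return simulate_dataset(SimulationConfig(n_genes=250, noise_sd=0.0, seed=11))


def random_hit_tables(rng: np.random.Generator, n_a: int = 6, n_b: int = 6, n_rows: int = 25):
    """Random directional hit tables with deliberate bitscore/evalue ties and
    duplicate (query, subject) rows, to exercise every tie-break path."""
    genes_a = [f"a{i}" for i in range(n_a)]
    genes_b = [f"b{i}" for i in range(n_b)]
    bit_choices = [50.0, 60.0, 60.0, 70.0]
    ev_choices = [1e-10, 1e-10, 1e-20]

    def table(queries, subjects):
        rows = []
        for _ in range(n_rows):
            rows.append(
                {
                    "query_id": str(rng.choice(queries)),
                    "subject_id": str(rng.choice(subjects)),
                    "bitscore": float(rng.choice(bit_choices)),
                    "evalue": float(rng.choice(ev_choices)),
                }
            )
        return pd.DataFrame(rows)

    return table(genes_a, genes_b), table(genes_b, genes_a)


def random_cluster_matrix(rng: np.random.Generator, n_genes: int = 40):
    """Random genes x 15-cluster averages spanning the 0.3 boundary."""
    clusters = [str(i) for i in range(15)]
    values = rng.choice(
        [0.0, 0.05, 0.25, 0.3, 0.31, 0.5, 1.5], size=(n_genes, len(clusters))
    )
    mat = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=clusters)
    mat.index.name = "gene_id"
    return mat


def random_temporal_matrix(rng: np.random.Generator, n_genes: int = 100):
    """Random temporal FPKM spanning the 1 / 3 thresholds, on the standard grid."""
    values = rng.choice(
        [0.0, 0.5, 0.9, 1.0, 2.0, 2.9, 3.0, 3.1, 4.0, 10.0], size=(n_genes, len(TIME_GRID))
    )
    mat = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=list(TIME_GRID))
    mat.index.name = "gene_id"
    return mat
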