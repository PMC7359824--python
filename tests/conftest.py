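import numpy as np
import pytest

from barcurate.distmat import DistMatrix
from barcurate.partition import Partition
from barcurate.seqio import BarcodeRecord, ReferenceLibrary


def make_matrix(ids, dist_fn):
    """Symmetric DistMatrix from a pairwise distance function on indices."""
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dist_fn(i, j)
    sites = np.full((n, n), 500, dtype=int)
    return DistMatrix(ids=list(ids), values=values, comparable_sites=sites)


def block_matrix(block_sizes, intra, inter, prefix="r"):
    """Matrix of well-separated blocks: distance `intra` within a block,
    `inter` between blocks."""
    ids, labels = [], []
    for b, size in enumerate(block_sizes):
        for k in range(size):
            ids.append(f"{prefix}{b}_{k}")
            labels.append(b)
    return (
        make_matrix(ids, lambda i, j: intra if labels[i] == labels[j] else inter),
        Partition({rid: f"B{lab}" for rid, lab in zip(ids, labels)}),
    )


@pytest.fixture
def three_record_library():
    return ReferenceLibrary(
        records=[
            BarcodeRecord("X1", "ACGTACGTAC", nominal_taxon="Alpha beta"),
            BarcodeRecord("X2", "ACGTACGTAG", nominal_taxon="Alpha beta"),
            BarcodeRecord("X3", "ACGAACGTAC", nominal_taxon="Gamma delta"),
        ]
    )


@pytest.fixture(scope="session")
def clean_simulation():
    """A 15x5 simulated library with a wide barcode gap (shared across
    tests; treated as read-only)."""
    from barcurate.simlib import SimConfig, simulate_library

    cfg = SimConfig(
        n_species=15,
        n_per_species=5,
        intra_depth=0.01,
        gap_factor=5.0,
        seed=7,
    )
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def workflow_simulation():
    """Simulation with sampled-OTU queries plus 3 unsampled query OTUs."""
    from barcurate.simlib import SimConfig, simulate_library

    cfg = SimConfig(
        n_species=15,
        n_per_species=5,
        n_unsampled_query_otus=3,
        n_queries_per_otu=2,
        seed=11,
    )
    return simulate_library(cfg)
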