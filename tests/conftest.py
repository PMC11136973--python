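"""Shared fixtures: small synthetic datasets with planted truth."""

import numpy as np
import pytest

from mcatlas import synth


@pytest.fixture(scope="session")
def small_truth():
    """4 planted cell types, 300 genes, 8 markers each at fold 8."""
    return synth.make_expression_truth(4, 300, 8, [8.0], seed=7)


@pytest.fixture(scope="session")
def small_matrix(small_truth):
    """40 cells per type at constant depth 1000."""
    matrix, labels = synth.sample_umi_matrix(small_truth, 40, 1000, seed=7)
    return matrix, labels


@pytest.fixture(scope="session")
def toy_genome():
    """Genes spaced far enough apart that a gene's own peaks stay closest."""
    return synth.make_genome(10, 400000, gc_target=0.4, min_spacing=30000, seed=5)


@pytest.fixture(scope="session")
def toy_regulome(toy_genome):
    return synth.make_peaks(toy_genome, peaks_per_gene=2, extra_orphans=4, seed=5)


def majority_labels(partition, true_labels):
    """Relabel each cell by the majority true type of its metacell."""
    out = np.array(["outlier"] * len(true_labels), dtype=object)
    for mc in partition.metacell_ids():
        members = partition.members(mc)
        vals, counts = np.unique(true_labels[members], return_counts=True)
        out[members] = vals[np.argmax(counts)]
    return out
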