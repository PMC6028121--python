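"""Shared fixtures: small synthetic datasets and tmp input files."""

import numpy as np
import pandas as pd
import pytest

from mmclassify import AbundanceTable, relative_abundance
from mmclassify.simulate import SyntheticConfig, generate_dataset, planted_indices_by_rank


@pytest.fixture(scope="session")
def null_dataset():
    """A null dataset (no planted effect), modest size for speed."""
    return generate_dataset(SyntheticConfig(seed=11, n_taxa=120))


@pytest.fixture(scope="session")
def planted_dataset():
    """Five taxa planted at 4-fold in moderately abundant tiers."""
    probe = SyntheticConfig(seed=7, n_taxa=150)
    idx = planted_indices_by_rank(probe, [10, 14, 18, 22, 26])
    cfg = SyntheticConfig(seed=7, n_taxa=150, planted=[(i, 4.0, +1) for i in idx])
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_rel(planted_dataset):
    return relative_abundance(planted_dataset.abundance)


@pytest.fixture(scope="session")
def planted_labels(planted_dataset):
    return planted_dataset.labels.data.iloc[0]


@pytest.fixture
def tiny_counts():
    """A hand-sized counts table with lineage taxon ids."""
    taxa = [
        "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Roseburia",
        "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia",
        "k__Bacteria;p__Fusobacteria;c__Fusobacteriia;o__Fusobacteriales;f__Fusobacteriaceae;g__Fusobacterium",
        "k__Bacteria;p__Bacteroidetes",
    ]
    data = pd.DataFrame(
        [[10, 0, 5, 1], [4, 6, 2, 8], [0, 14, 3, 1], [6, 0, 0, 10]],
        index=taxa,
        columns=["S1", "S2", "S3", "S4"],
        dtype=float,
    )
    return AbundanceTable(data)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
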