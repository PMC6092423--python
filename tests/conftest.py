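import numpy as np
import pandas as pd
import pytest

import sortscreen as ss


@pytest.fixture(scope="session")
def small_config():
    """A desk-sized screen: 60 genes, ~10% modifiers, light sequencing."""
    return ss.SimConfig(
        seed=11,
        n_genes=60,
        constructs_per_gene=(5, 7),
        abundance_sigma=0.5,
        fraction_modifiers=0.1,
        n_cells=300_000,
        n_reads=150_000,
        n_replicates=3,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    """(library, abundance, effects, count matrix) for the small screen."""
    library, abundance = ss.make_library(small_config)
    effects = ss.assign_effects(library, small_config)
    matrix = ss.simulate_screen(library, abundance, effects, small_config)
    return library, abundance, effects, matrix


@pytest.fixture()
def toy_matrix():
    """Hand-sized 4-construct, 2-replicate count matrix."""
    counts = pd.DataFrame(
        {
            "rep1_input": [10, 20, 30, 40],
            "rep1_high": [12, 18, 33, 37],
            "rep2_input": [11, 19, 29, 41],
            "rep2_high": [13, 21, 31, 35],
        },
        index=pd.Index([f"c{i}" for i in range(4)], name="construct_id"),
    )
    genes = pd.Series(["gA", "gA", "gB", "gB"], index=counts.index, name="gene")
    return ss.CountMatrix(counts=counts, genes=genes)
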