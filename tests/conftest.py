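import numpy as np
import pytest

import gmconn as gc


@pytest.fixture(scope="session")
def atlas():
    return gc.default_atlas()


@pytest.fixture(scope="session")
def labeling(atlas):
    return gc.label_edges(atlas)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort shared by tests that only need plausible structure."""
    cfg = gc.SyntheticConfig(n_subjects=12, ts_length=200, seed=1234)
    return cfg, gc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def block_masks(small_cohort):
    """Within/between-block edge masks for the shared cohort's MC partition."""
    _, ds = small_cohort
    blocks = ds.truth.mc_blocks
    pairs = gc.edge_index_pairs(len(blocks))
    within = blocks[pairs[:, 0]] == blocks[pairs[:, 1]]
    return within, ~within


def mc_from_table(table):
    return gc.build_mc(gc.minmax_scale(gc.residualize_metrics(table)))


def block_contrast(mc_matrix, blocks):
    """Mean within-block minus mean between-block edge strength."""
    pairs = gc.edge_index_pairs(len(blocks))
    within = blocks[pairs[:, 0]] == blocks[pairs[:, 1]]
    e = mc_matrix.upper()
    return e[within].mean() - e[~within].mean()
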