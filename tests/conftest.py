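import numpy as np
import pytest

import spotniche as sn

CANONICAL_SEED = 0


@pytest.fixture(scope="session")
def sim_config():
    """The default study conditions on the canonical fixture seed."""
    return sn.SimulationConfig(seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def tissue(sim_config):
    """(grid, layout, counts) for the canonical synthetic tissue."""
    cfg = sim_config
    grid = sn.make_hex_grid(cfg.n_rows, cfg.n_cols)
    layout = sn.paint_layout(
        grid, cfg.seed, cfg.tumor_fraction, cfg.necrotic_fraction, cfg.marker_fraction
    )
    counts = sn.simulate_counts(layout, cfg)
    return grid, layout, counts


@pytest.fixture(scope="session")
def annotated(sim_config, tissue):
    """Nearby-classified annotation for the canonical tissue."""
    grid, layout, counts = tissue
    ann = sn.call_marker_positivity(counts, layout.region_of, sim_config.marker_gene)
    graph = sn.build_adjacency(grid)
    return sn.classify_nearby(ann, graph), graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
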