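import warnings

import numpy as np
import pandas as pd
import pytest

from scretina import cluster as cl
from scretina import preprocess as pp
from scretina import simulate as sim


@pytest.fixture(scope="session")
def retina_sim():
    """A 6-class retina-like dataset with damaged cells and doublets."""
    cfg = sim.retina_like_config(
        cells_per_cluster=150, seed=42, doublet_rate=0.05, damaged_fraction=0.05)
    m, truth = sim.simulate_counts(cfg)
    return cfg, m, truth


@pytest.fixture(scope="session")
def small_clean_sim():
    """Three well-separated classes, no damage/doublets (fast fixture)."""
    cfg = sim.retina_like_config(
        cells_per_cluster=120, seed=7, classes=("rods", "cones", "glial cells"))
    m, truth = sim.simulate_counts(cfg)
    return cfg, m, truth


@pytest.fixture(scope="session")
def clean_normalized(small_clean_sim):
    _, m, truth = small_clean_sim
    nm_log = pp.library_normalize(m, log=True)
    nm = pp.library_normalize(m)
    labels = pd.Series(truth.cluster, index=truth.cell_ids, name="cluster")
    dense = {"rods": 1, "cones": 2, "glial cells": 3}
    clustering = cl.Clustering(labels.map(dense))
    return m, nm, nm_log, clustering


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
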