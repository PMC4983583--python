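import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import traitassembly as ta
from traitassembly import ingest
from traitassembly.config import ScenarioConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def traits_from_leaf(leaf: pd.DataFrame) -> pd.DataFrame:
    """Leaf table -> tree-level trait table (no corrections needed)."""
    leaf = leaf.assign(lma=ingest.compute_leaf_lma(leaf))
    return ingest.aggregate_to_trees(leaf)


def small_scenario(**kwargs) -> ScenarioConfig:
    """A four-plot gradient kept small for fast simulation."""
    defaults = dict(
        n_plots=4,
        env=(200.0, 1200.0, 2200.0, 3200.0),
        pool_size=60,
        trees_per_species=(3, 4),
        leaves_per_tree=(2, 2),
        include_shade=False,
        seed=0,
    )
    defaults.update(kwargs)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def default_sim():
    """One full default-scenario simulation shared across tests."""
    return ta.simulate_region(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def default_traits(default_sim):
    leaf, census, meta, truth = default_sim
    return traits_from_leaf(leaf)


def make_trait_table(plot_ids, species, values, layer="sun"):
    """Build a minimal trait table from parallel label/value lists.

    ``values`` are placed in both lma (exp) and log_lma (as given) so
    log-scale statistics can use hand-picked numbers directly.
    """
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "plot_id": plot_ids,
            "species": species,
            "tree_id": [f"t{i}" for i in range(len(values))],
            "layer": layer,
            "lma": np.exp(values),
            "log_lma": values,
        }
    )
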