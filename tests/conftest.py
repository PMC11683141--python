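import numpy as np
import pandas as pd
import pytest

import rhizoguild as rg


@pytest.fixture(scope="session")
def scenario():
    """One deterministic full synthetic study shared across tests."""
    return rg.full_scenario(rg.ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def assignment(scenario):
    ds = scenario.dataset
    return rg.assign_guilds(ds.bacterial_taxonomy, ds.fungal_taxonomy, ds.traits)


@pytest.fixture
def toy_table():
    return rg.FeatureTable(
        pd.DataFrame(
            {"s1": [6, 4, 0], "s2": [2, 4, 4], "s3": [0, 0, 10]},
            index=["t1", "t2", "t3"],
        )
    )


@pytest.fixture
def toy_metadata():
    return rg.SampleMetadata(
        pd.DataFrame(
            {"stage": ["BL", "BL", "2YV"], "site": "s", "plot": "p"},
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
    )


def make_metadata(sample_ids, stages, site="Site1", plot="1"):
    return rg.SampleMetadata(
        pd.DataFrame(
            {"stage": list(stages), "site": site, "plot": plot},
            index=pd.Index(list(sample_ids), name="sample_id"),
        )
    )


@pytest.fixture
def metadata_factory():
    return make_metadata


def neutral_table(seed, n_taxa=60, depth=2339, n_samples=30, nm=500.0, sigma=1.5):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0.0, sigma, n_taxa)
    return rg.sample_neutral(x / x.sum(), nm, depth, n_samples, rng)


@pytest.fixture
def neutral_table_factory():
    return neutral_table
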