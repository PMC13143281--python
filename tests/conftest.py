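import numpy as np
import pandas as pd
import pytest

import streamtx.simulate as sim


@pytest.fixture(scope="session")
def tiny_scenario() -> sim.ScenarioConfig:
    return sim.ScenarioConfig(
        n_genes=30,
        isoforms_per_gene=[0.6, 0.4],
        seed=11,
        fold_change_set={"G0003": 4.0, "G0004": 0.25},
        knockout_set={"G0005"},
        marker_map={"treated": {"KanR"}},
        abundance_boost={"G0005": 2.0},
        isoform_switch_set={"G0012"},
    )


@pytest.fixture(scope="session")
def tiny_reference(tiny_scenario) -> sim.Reference:
    return sim.build_reference(tiny_scenario)


@pytest.fixture(scope="session")
def tiny_profiles(tiny_reference, tiny_scenario):
    return sim.make_expression_profiles(tiny_reference, tiny_scenario)


@pytest.fixture(scope="session")
def tiny_manifest(tiny_scenario) -> pd.DataFrame:
    return sim.make_manifest(tiny_scenario)


@pytest.fixture(scope="session")
def tiny_groups(tiny_manifest) -> pd.Series:
    return pd.Series(dict(zip(tiny_manifest["sample_id"],
                              tiny_manifest["condition"])))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
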