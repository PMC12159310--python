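import numpy as np
import pandas as pd
import pytest

import twinspec as ts


@pytest.fixture(scope="session")
def scenario1_preset():
    return ts.scenario_preset("scenario1_environmental", 0.10, -1)


@pytest.fixture(scope="session")
def scenario1_dataset(scenario1_preset):
    """Study-scale observed dataset under the environmental scenario."""
    return ts.make_twin_dataset(scenario1_preset, n_mz=426, n_dz=604, seed=2026)


@pytest.fixture(scope="session")
def small_grid_config():
    """Multi-axis but compact grid: (2 + 1) x 2 x 2 = 12 phenotypic cells."""
    cfg = ts.default_config()
    cfg["asb_measures"] = {"cbcl_aggression": ["mother", "all"],
                           "interview": ["twin"]}
    cfg["nurturance_informants"] = ["mother", "all"]
    return cfg


@pytest.fixture(scope="session")
def small_curve(scenario1_dataset, small_grid_config):
    """A fitted curve over the compact grid, shared across tests."""
    return ts.SpecificationCurve(config=small_grid_config,
                                 seed=5).fit(scenario1_dataset)


@pytest.fixture()
def tiny_long():
    """Hand-built long table: 3 families, 2 measures, fully observed."""
    rows = []
    values = {
        ("cbcl_aggression", "mother"): [3.0, 1.0, 5.0, 2.0, 8.0, 4.0],
        ("peq_nurturance", "mother"): [10.0, 12.0, 9.0, 15.0, 11.0, 13.0],
    }
    zyg = ["MZ", "MZ", "DZ", "DZ", "DZ", "DZ"]
    for (measure, informant), vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"family_id": i // 2, "zygosity": zyg[i],
                         "twin_index": i % 2 + 1, "measure_id": measure,
                         "informant_id": informant, "value": v})
    return pd.DataFrame(rows)
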