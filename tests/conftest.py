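import dataclasses

import pandas as pd
import pytest

from igqtl.simulate import default_config, simulate_cohort


def small_config(seed: int = 0, **overrides):
    """Scaled-down study cohort for fast unit tests."""
    cfg = default_config(seed, n_individuals=50, repertoire_size=600)
    return dataclasses.replace(cfg, **overrides)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(11))


@pytest.fixture()
def toy_records():
    """Hand-built record table: two samples, three V genes."""
    rows = []
    for k in range(120):
        rows.append(dict(sample_id="A", v_call="V1*01", j_call="J1*01",
                         junction_aa="CQQYNSYPLTF", v_identity=100.0,
                         j_identity=100.0, duplicate_count=1 + k % 3))
    for k in range(60):
        rows.append(dict(sample_id="A", v_call="V2*01", j_call="J2*01",
                         junction_aa="CASSLGF", v_identity=100.0,
                         j_identity=100.0, duplicate_count=2))
    for k in range(9):
        rows.append(dict(sample_id="A", v_call="V3*01", j_call="J1*01",
                         junction_aa="CARF", v_identity=100.0,
                         j_identity=100.0, duplicate_count=1))
    for k in range(99):
        rows.append(dict(sample_id="B", v_call="V1*01", j_call="J1*01",
                         junction_aa="CQQYNSYPLTF", v_identity=100.0,
                         j_identity=100.0, duplicate_count=1))
    return pd.DataFrame(rows)
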