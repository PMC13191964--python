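import numpy as np
import pandas as pd
import pytest


def make_survey(cluster_outcomes, wave="W"):
    """Build a microdata frame from {(state, district, cluster): [0/1,...]}."""
    rows = []
    for (state, district, cluster), ys in cluster_outcomes.items():
        for i, y in enumerate(ys):
            rows.append((state, district, cluster, f"b{i + 1}", wave, y))
    df = pd.DataFrame(
        rows, columns=["state_id", "district_id", "cluster_id", "birth_id", "wave", "lbw"]
    )
    df["lbw"] = df["lbw"].astype("Int64")
    return df


@pytest.fixture
def two_cluster_data():
    """1 state / 1 district / 2 clusters of 5 births (asymmetric outcomes)."""
    return make_survey({("S1", "D1", "c1"): [1, 0, 0, 0, 0],
                        ("S1", "D1", "c2"): [1, 1, 1, 0, 1]})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
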