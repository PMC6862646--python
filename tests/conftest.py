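import numpy as np
import pandas as pd
import pytest

from geofgm.data_model import make_dataset
from geofgm.spatial import RegionGraph, kenya_province_graph
from geofgm.synthetic import GeneratorConfig, simulate_survey, single_year_config


@pytest.fixture(scope="session")
def kenya_graph():
    return kenya_province_graph()


@pytest.fixture(scope="session")
def path3_graph():
    return RegionGraph.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])


def _raw_frame(n=10, year=2014, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "girl_id": [f"g{i}" for i in range(n)],
        "mother_id": [f"m{i // 2}" for i in range(n)],
        "cluster_id": [f"c{(i // 2) // 3}" for i in range(n)],  # mothers nest in clusters
        "region_id": ["Nairobi"] * n,
        "survey_year": year,
        "y": rng.integers(0, 2, n),
        "age_girl": rng.integers(0, 15, n),
        "age_mother": rng.integers(15, 50, n),
        "mother_cut": rng.integers(0, 2, n),
        "mother_supports_continuation": rng.integers(0, 2, n).astype(float),
        "mother_believes_religious_obligation": rng.integers(0, 2, n).astype(float),
        "ethnicity": rng.choice(["a", "b"], n),
        "religion": "christian",
        "education": "primary",
        "wealth_quintile": "middle",
        "urban": 0,
        "weight": np.exp(rng.normal(0, 0.3, n)),
    })


@pytest.fixture
def raw_frame():
    return _raw_frame()


@pytest.fixture
def tiny_dataset():
    ds, diags = make_dataset(_raw_frame())
    assert not diags
    return ds


@pytest.fixture(scope="session")
def small_survey():
    """Pooled three-wave synthetic survey, small but structurally complete."""
    cfg = GeneratorConfig(n_clusters_per_region=3, n_mothers_per_cluster=10,
                          seed=11)
    ds, truth = simulate_survey(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def single_year_survey():
    """One-wave (all-daughters) synthetic survey at reduced size."""
    cfg = single_year_config(2014, seed=5, n_clusters_per_region=4,
                             n_mothers_per_cluster=12)
    ds, truth = simulate_survey(cfg)
    return ds, truth
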