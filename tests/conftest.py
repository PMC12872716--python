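import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from triadscan import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_triads=300, n_nontriad_genes=80, n_deg_genes=30,
                            seed=101)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def fixture_dir(small_dataset, tmp_path_factory):
    from triadscan import write_fixture
    path = tmp_path_factory.mktemp("fixture")
    write_fixture(small_dataset, path)
    return path


@pytest.fixture(scope="session")
def assignment(small_dataset):
    from triadscan import (aggregate_condition_tpm, categorize_all,
                           filter_expressed_triads)
    ds = small_dataset
    expr = aggregate_condition_tpm(ds.tpm, ds.sample_sheet, ds.triads)
    expressed = filter_expressed_triads(expr)
    return categorize_all(expr, expressed)


def random_assignment(seed, n_triads=60, genotypes=("G1", "G2"),
                      stages=("Day0", "Day7", "Day21"), p_undefined=0.1):
    """A random triad-category assignment table for oracle tests."""
    from triadscan.triads import CATEGORIES, UNDEFINED
    rng = np.random.default_rng(seed)
    labels = list(CATEGORIES) + [UNDEFINED]
    p = np.array([0.35, 0.05, 0.07, 0.05, 0.11, 0.14, 0.08, p_undefined])
    p[:-1] *= (1 - p_undefined) / p[:-1].sum()
    rows = []
    for g in genotypes:
        for s in stages:
            cats = rng.choice(labels, size=n_triads, p=p)
            for i, c in enumerate(cats):
                rows.append((f"T{i:03d}", g, s, c))
    df = pd.DataFrame(rows, columns=["triad_id", "genotype", "stage", "category"])
    df["stage"] = pd.Categorical(df["stage"], categories=list(stages), ordered=True)
    return df
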