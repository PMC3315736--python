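import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")

from pooldiver import calling, simulate  # noqa: E402


@pytest.fixture(scope="session")
def toy_genome():
    """Six-gene toy genome with planted variants of every class."""
    return simulate.simulate_toy_genome(6, seed=11)


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.SimConfig(seed=5, n_loci=300)


@pytest.fixture(scope="session")
def small_run(small_cfg):
    """Truth, counts and calls for a small simulated experiment."""
    truth = simulate.simulate_truth(small_cfg)
    counts = simulate.simulate_pool_counts(truth, small_cfg)
    calls = calling.call_variants(counts)
    return {"truth": truth, "counts": counts, "calls": calls}


@pytest.fixture()
def unrelated_pedigree():
    """Six founders, no parents, fixed EBVs."""
    return pd.DataFrame({
        "id": [f"F{i}" for i in range(6)],
        "sire": [None] * 6, "dam": [None] * 6,
        "ebv": [-5.0, -1.0, 1.0, 5.0, -2.0, 2.0],
    })
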