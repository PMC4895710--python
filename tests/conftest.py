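import pytest
from hypothesis import HealthCheck, settings

import psieve as ps

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated study (2,000 spectra) shared across tests."""
    config = ps.SimConfig(seed=11)
    entries, stats, truth = ps.simulate_search_space(config)
    tables, truth = ps.simulate_psm_tables(entries, truth, config)
    return config, entries, stats, tables, truth


@pytest.fixture(scope="session")
def small_sim_survivors(small_sim):
    _, entries, _, tables, truth = small_sim
    merged = ps.merge_engines(list(tables.values()))
    qvalued = ps.compute_qvalues(merged)
    kept = ps.filter_significant(qvalued)
    evidence = ps.aggregate_peptides(kept)
    return entries, truth, merged, qvalued, kept, evidence
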