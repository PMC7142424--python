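import pytest

from glycodyn.synthetic import GeneratorConfig, simulate_gi_experiment
from glycodyn.timeseries import deisotope


@pytest.fixture(scope="session")
def gi_sim():
    """One default gastrointestinal simulation shared across the suite."""
    table, truth = simulate_gi_experiment(seed=42)
    return table, truth


@pytest.fixture(scope="session")
def gi_mono(gi_sim):
    """The same simulation after deisotoping, isotopologues removed."""
    table, truth = gi_sim
    return deisotope(table).without_isotopes(), truth


@pytest.fixture(scope="session")
def small_sim():
    """A lighter simulation (fewer matrix features) for faster unit tests."""
    cfg = GeneratorConfig(n_matrix_features=28, matrix_intensity_range=(1e5, 5e6))
    table, truth = simulate_gi_experiment(cfg, seed=7)
    return table, truth
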