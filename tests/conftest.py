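import numpy as np
import pytest

from soilrisk.simulate import ScenarioConfig, generate_scenario
from soilrisk.tables import SoilSampleTable


@pytest.fixture(scope="session")
def reference_scenario():
    """The reference synthetic study: 20x20 town lattice, 600 soil samples,
    D=6 elements with 2 planted factors, beta=(0.2, 0)."""
    cfg = ScenarioConfig(seed=7)
    soil, towns, graph, truth = generate_scenario(cfg, seed=7)
    return cfg, soil, towns, graph, truth


def small_scenario_config(**overrides) -> ScenarioConfig:
    """A fast scenario: 8x8 towns, 100 samples on a 10 km square."""
    kwargs = dict(side=10.0, n_rows=8, n_cols=8, n_soil_samples=100,
                  mesh_max_edge=1.8, mean_expected=40.0)
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture()
def random_soil_table():
    rng = np.random.default_rng(42)
    n, elements = 40, ["Cu", "Pb", "Zn", "Ni"]
    conc = np.exp(rng.normal(3.0, 0.8, size=(n, len(elements))))
    return SoilSampleTable(
        sample_id=np.arange(n),
        coords=rng.uniform(0, 10, size=(n, 2)),
        concentrations=conc,
        elements=elements,
    )
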