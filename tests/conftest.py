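import pytest

from aromaquant import datasets
from aromaquant.synthetic import StudyScenario, generate_registry, generate_study


@pytest.fixture(scope="session")
def strawberry_registry():
    return datasets.load_strawberry_registry()


@pytest.fixture(scope="session")
def strawberry_conc():
    return datasets.load_strawberry_concentrations()


@pytest.fixture(scope="session")
def daily_totals():
    return datasets.load_strawberry_daily_totals()


@pytest.fixture(scope="session")
def printed_oav():
    return datasets.load_strawberry_oav_printed()


@pytest.fixture(scope="session")
def scenario():
    return StudyScenario(seed=42)


@pytest.fixture(scope="session")
def synthetic_registry(scenario):
    return generate_registry(scenario)


@pytest.fixture(scope="session")
def noiseless_study():
    sc = StudyScenario(seed=7, noise_sigma=0.0, threshold_sigma=0.0, dt_sigma=0.0)
    reg = generate_registry(sc)
    truth, areas, cal = generate_study(sc, reg)
    return sc, reg, truth, areas, cal
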