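from pathlib import Path

import numpy as np
import pytest

from cherenkov_xsec.physics import BeamSpec, get_material
from cherenkov_xsec.synthetic import CCDConfig, simulate_experiment

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def water():
    return get_material("water")


@pytest.fixture(scope="session")
def quartz():
    return get_material("quartz")


@pytest.fixture(scope="session")
def polyethylene():
    return get_material("polyethylene")


@pytest.fixture(scope="session")
def reference_beam():
    """72.0 MeV pencil beam, 30 nA for 30 min."""
    return BeamSpec(initial_energy=72.0, current_na=30.0, irradiation_duration=1800.0)


@pytest.fixture(scope="session")
def noiseless_sim():
    """One shared noiseless synthetic experiment at the default conditions."""
    return simulate_experiment(seed=123, noise=False)


@pytest.fixture(scope="session")
def noisy_sim():
    return simulate_experiment(seed=123, noise=True)


def load_pstar_water():
    import pandas as pd

    df = pd.read_csv(DATA_DIR / "pstar_water.tsv", sep="\t", comment="#")
    return df.to_records(index=False)
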