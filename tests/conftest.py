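import numpy as np
import pandas as pd
import pytest

from invafun.data_model import (
    AbundanceMatrix,
    EnvTable,
    SpeciesTable,
    TraitTable,
)
from invafun.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture
def tiny_species():
    return SpeciesTable(
        pd.DataFrame(
            {
                "species_id": ["barbel", "chub", "carp", "gobio"],
                "origin": ["native", "native", "exotic", "exotic"],
                "body_mass_class": [3, 2, 3, 1],
            }
        )
    )


@pytest.fixture
def tiny_traits():
    return TraitTable(
        pd.DataFrame(
            {
                "species_id": ["barbel", "chub", "carp", "gobio"],
                "feeding": ["invertivorous", "omnivorous", "omnivorous", "invertivorous"],
                "reproduction": ["lithophilic", "phytolithophilic", "phytophilic", "psammophilic"],
                "migration": ["potamodromous", "resident", "resident", "resident"],
                "tolerance": ["intermediate", "tolerant", "tolerant", "tolerant"],
                "habitat_use": ["rheophilic", "eurytopic", "limnophilic", "benthic"],
            }
        )
    )


@pytest.fixture
def tiny_abundance():
    return AbundanceMatrix(
        pd.DataFrame(
            {
                "site_id": ["up", "mid", "low"],
                "barbel": [4, 2, 0],
                "chub": [2, 3, 1],
                "carp": [0, 1, 5],
                "gobio": [0, 2, 3],
            }
        )
    )


@pytest.fixture
def tiny_env():
    n = 3
    return EnvTable(
        pd.DataFrame(
            {
                "site_id": ["up", "mid", "low"],
                "longitude": [10.5, 10.9, 11.4],
                "latitude": [44.3, 44.6, 44.9],
                "altitude": [650.0, 180.0, 12.0],
                "water_temperature": [12.0, 17.5, 22.0],
                "electrical_conductivity": [220.0, 450.0, 780.0],
                "cod": [4.0, 9.0, 16.0],
                "bod": [1.2, 2.5, 4.8],
                "tss": [6.0, 14.0, 28.0],
                "total_phosphorus": [0.04, 0.12, 0.22],
                "ammonia": [0.05, 0.18, 0.35],
                "nitrate": [0.9, 2.1, 3.4],
                "urban": [0.05, 0.12, 0.20],
                "agricultural": [0.10, 0.45, 0.60],
                "forest": [0.60, 0.25, 0.05],
                "other_natural": [0.20, 0.10, 0.05],
                "freshwater": [0.05, 0.07, 0.08],
                "brackish_water": [0.00, 0.01, 0.02],
                "stream_order": [1, 3, 5],
                "is_canal": [False, False, False],
            }
        )
    )


@pytest.fixture(scope="session")
def synth_dataset():
    """Default-size synthetic dataset (335 sites, 37 native + 22 exotic), seed 1."""
    return generate_dataset(SynthConfig(rng_seed=1))
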