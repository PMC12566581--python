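import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phasemet import FeatureTable, FragmentSpectrum, SimulationConfig, simulate_s9_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A 2-mixture synthetic S9 experiment used across pipeline tests."""
    config = SimulationConfig(
        n_mixtures=2, parents_per_mixture=4, decoy_feature_count=10, seed=7
    )
    return config, simulate_s9_dataset(config)


@pytest.fixture
def simple_table():
    """Three treatment replicates, three blanks, hand-checkable values."""
    features = pd.DataFrame(
        {"mz": [153.0546, 204.1053, 300.0], "rt": [5.75, 6.42, 3.0]},
        index=pd.Index(["f1", "f2", "f3"], name="id"),
    )
    intensities = pd.DataFrame(
        {
            "rep_1": [100.0, 1000.0, 5.0],
            "rep_2": [110.0, 0.0, 4.0],
            "rep_3": [90.0, 2000.0, 6.0],
            "blank_1": [1.0, 0.0, 5.0],
            "blank_2": [2.0, 0.0, 6.0],
            "blank_3": [1.0, 0.0, 4.0],
        },
        index=features.index,
    )
    return FeatureTable(features, intensities)


def make_spectrum(peaks, precursor=300.0, name="", rt=None):
    return FragmentSpectrum(precursor, tuple(peaks), name=name, rt=rt)
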