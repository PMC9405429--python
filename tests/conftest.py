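import numpy as np
import pytest

from isoniche import (
    CalibrationPair,
    GroupConfig,
    HabitatGroup,
    IsotopeSample,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_sample(**overrides) -> IsotopeSample:
    base = dict(
        sample_id="S-001",
        species="Common dolphin",
        year=2018,
        d13C_bulk=-17.5,
        d15N=14.1,
        cn_ratio=3.2,
    )
    base.update(overrides)
    return IsotopeSample(**base)


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def noiseless_pairs():
    """Calibration pairs lying exactly on Δ = −1.2 + 0.5·C:N."""
    cns = np.linspace(3.0, 8.6, 15)
    return [
        CalibrationPair(d13C_bulk=-18.0, d13C_lipid_extracted=-18.0 + (-1.2 + 0.5 * cn), cn_ratio=cn)
        for cn in cns
    ]


@pytest.fixture
def two_species_config():
    return GroupConfig(
        habitat_groups={
            "Common dolphin": HabitatGroup.MESOPELAGIC,
            "Killer whale": HabitatGroup.MESOPELAGIC,
        },
        length_thresholds={"Common dolphin": 150.0, "Killer whale": 300.0},
    )
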