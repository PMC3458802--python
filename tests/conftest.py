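import numpy as np
import pytest

from softagar import SimulationConfig, SirnaCondition


@pytest.fixture
def rng():
    return np.random.default_rng(20201)


@pytest.fixture
def tiny_config():
    """A fast, small chip: 3 conditions x 3 replicates, 40 cells/well."""
    return SimulationConfig(
        sirnas=[
            SirnaCondition("no_sirna", "negative_control", 0.4, 0.3),
            SirnaCondition("non_targeting", "non_targeting", 0.4, 0.3, labeled_fraction=0.0),
            SirnaCondition("strong_hit", "targeted", 0.4, 0.05),
        ],
        wells_per_chip=12,
        replicates_per_sirna=3,
        cells_per_well=(40, 50),
        imaging_days=(2.0, 5.0),
        frame_px=220,
        well_diameter_px=200,
        seed=99,
    )
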