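import numpy as np
import pytest

from lgibp.preprocessing import RawBattery, standardize_battery
from lgibp.schema import default_schema
from lgibp.synthetic import SyntheticConfig, OutcomeSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset with outcomes, reused across tests."""
    cfg = SyntheticConfig(
        n_participants=120, n_measures=12, planted_k=3, noise_sd=0.4,
        missing_rate=0.05, membership_probs=0.3, raw_scale=True,
        outcome_specs=(
            OutcomeSpec("impulsivity", "impulsive_behavior",
                        (0.3, 0.0, 0.0)),
            OutcomeSpec("substance", "substance_use", (0.0, 0.0, 0.0)),
        ),
        seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def standardized(small_dataset):
    return standardize_battery(small_dataset.battery)


@pytest.fixture()
def tiny_battery():
    """3 participants x 2 measures, one missing cell, custom 2-measure
    schema."""
    from lgibp.schema import MeasureDescriptor, MeasureSchema, Battery
    schema = MeasureSchema((
        MeasureDescriptor("m1", Battery.CNB, "synthetic", "m1"),
        MeasureDescriptor("m2", Battery.ANT, "synthetic", "m2",
                          higher_is_better_raw=False, reverse_score=True),
    ))
    values = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 0.0]])
    mask = np.array([[True, True], [True, True], [True, False]])
    return RawBattery(("a", "b", "c"), values, mask, schema)
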