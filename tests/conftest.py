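import numpy as np
import pandas as pd
import pytest

from lwl.data_model import Dataset, LEFT, RIGHT
from lwl.simulate import SimConfig, simulate_dataset, T_GRID_MS


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """Six infants (two per age group), default effect structure."""
    return simulate_dataset(SimConfig(n_per_group=2, seed=42))


@pytest.fixture(scope="session")
def medium_dataset() -> Dataset:
    """24 infants, mild positive bias; used by preprocessing/cluster tests."""
    return simulate_dataset(SimConfig(n_per_group=8, delta=0.1, seed=7))


def manual_trial_dataset(labels: list[str], target_side: str = LEFT,
                         target_onset_ms: float = 3000.0) -> Dataset:
    """One-participant, one-trial dataset with hand-placed sample labels
    (one label per 60 Hz grid point, padded with OFFSCREEN)."""
    n = len(T_GRID_MS)
    padded = list(labels) + ["OFFSCREEN_OR_INVALID"] * (n - len(labels))
    gaze = pd.DataFrame(
        {
            "participant_id": "p1",
            "trial_id": "p1_t00",
            "t_ms": T_GRID_MS,
            "label": pd.Categorical(padded),
        }
    )
    design = pd.DataFrame(
        [
            {
                "participant_id": "p1", "trial_id": "p1_t00", "pair_id": "pair01",
                "target_word": "ball", "target_side": target_side,
                "target_onset_ms": target_onset_ms, "half": 1,
            }
        ]
    )
    pairs = pd.DataFrame([{"pair_id": "pair01", "word_a": "ball", "word_b": "book"}])
    participants = pd.DataFrame([{"participant_id": "p1", "age_days": 300}])
    return Dataset(gaze=gaze, design=design, pairs=pairs, participants=participants)
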