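import numpy as np
import pytest

from nirsgraph import GroupDataset, SimulationConfig, simulate_group


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_group():
    """Factory for small random GroupDatasets."""

    def _make(n=5, t=40, c=6, seed=0, fs=7.81):
        data = np.random.default_rng(seed).standard_normal((n, t, c))
        return GroupDataset(
            participants=[f"P{i:02d}" for i in range(n)],
            data=data,
            fs=fs,
            channel_ids=[f"C{j:02d}" for j in range(c)],
        )

    return _make


@pytest.fixture(scope="session")
def effect_group():
    """Shared strong-effect simulation with known ground truth."""
    config = SimulationConfig(
        n_participants=8,
        n_long_channels=10,
        n_short_channels=2,
        n_frames=600,
        fs=7.81,
        event_onsets=(15.0, 45.0),
        event_duration=10.0,
        responsive_channels=(1, 4, 7),
        effect_size=3.0,
        seed=42,
    )
    group, truth = simulate_group(config)
    return config, group, truth
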