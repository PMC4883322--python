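import numpy as np
import pytest

from aggropig.pipeline import process_sequence
from aggropig.synthetic import SimConfig, simulate_episode


@pytest.fixture(scope="session")
def fast_sim() -> SimConfig:
    """Default world with short episodes, to keep rendering time down."""
    return SimConfig(duration_s_range=(1.1, 1.4))


@pytest.fixture(scope="session")
def processed_episodes(fast_sim):
    """A few rendered episodes of each two-pig class, already processed.

    Returns a list of (behavior, ground_truth, tracks, episodes) shared
    by pipeline-level tests to avoid re-rendering.
    """
    out = []
    meta = fast_sim.meta()
    for behavior in ("walk_together", "knocking", "chasing"):
        for seed in (3, 11):
            frames, gt = simulate_episode(behavior, fast_sim, seed)
            _, tracks, eps = process_sequence(frames, meta)
            out.append((behavior, gt, tracks, eps))
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160502)
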