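import numpy as np
import pytest

from ictolat import (
    GroundTruth,
    Leadfield,
    SourceSpaceSpec,
    generate_leadfield,
    generate_planted_network,
)


@pytest.fixture(scope="session")
def small_spec() -> SourceSpaceSpec:
    """Desk-scale source space: 60 sources over the 15 ROIs."""
    return SourceSpaceSpec(n_sources=60, seed=1)


@pytest.fixture(scope="session")
def small_leadfield(small_spec) -> Leadfield:
    return generate_leadfield(small_spec)


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return GroundTruth(focus_roi="Superior temporal right", coupling_gain=5.0)


@pytest.fixture(scope="session")
def planted_net():
    """15-node network with focus node 3 scaled x10."""
    return generate_planted_network(n_nodes=15, focus=3, strength=10.0, seed=1)


@pytest.fixture(scope="session")
def tiny_random_leadfield() -> Leadfield:
    """8 channels x 12 sources random gain, for exhaustive inverse sweeps."""
    rng = np.random.default_rng(0)
    return Leadfield(
        gain=rng.standard_normal((8, 12)),
        positions=np.zeros((12, 3)),
        roi_of_source=np.array(["roi"] * 12),
        channel_labels=tuple(f"ch{i}" for i in range(8)),
    )
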