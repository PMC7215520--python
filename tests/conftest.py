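import numpy as np
import pytest

from resdyn import GeneratorConfig, Trajectory, generate


@pytest.fixture
def tiny_trajectory() -> Trajectory:
    """3 residues (one glycine), 2 frames, hand-laid coordinates."""
    sites = [
        ("CA", "ALA", 23, "A"),
        ("CB", "ALA", 23, "A"),
        ("CA", "GLY", 24, "A"),
        ("CA", "TRP", 25, "A"),
        ("CB", "TRP", 25, "A"),
    ]
    coords = np.array(
        [
            [[0, 0, 0], [1.5, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [7.6, 1.5, 0]],
            [[0, 0, 1], [1.5, 0, 1], [3.8, 0, 1], [7.6, 0, 1], [7.6, 1.5, 1]],
        ],
        dtype=float,
    )
    return Trajectory(sites, coords, label="tiny", timestep_ps=100.0)


@pytest.fixture
def jitter_trajectory() -> Trajectory:
    """Small seeded compact-walk trajectory with pure isotropic jitter."""
    cfg = GeneratorConfig(
        n_residues=30, n_frames=120, seed=11, fluctuation_sigma=0.4,
        glycine_positions=frozenset({25, 40}),
    )
    return generate(cfg)
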