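import numpy as np
import pytest

import simplesig as ss


@pytest.fixture
def tiny_matrix() -> ss.MethylMatrix:
    """3 probes x 4 samples, hand-enterable beta values."""
    vals = np.array(
        [
            [0.8, 0.9, 0.1, 0.2],
            [0.1, 0.2, 0.8, 0.9],
            [0.5, 0.5, 0.5, 0.5],
        ]
    )
    return ss.MethylMatrix(
        vals, ["cg000001", "cg000002", "cg000003"], ["s1", "s2", "s3", "s4"]
    )


@pytest.fixture
def tiny_labels() -> ss.LabelVector:
    return ss.LabelVector(
        ["s1", "s2", "s3", "s4"],
        {"s1": "tcell", "s2": "tcell", "s3": "bcell", "s4": "bcell"},
    )


@pytest.fixture
def small_simulation():
    """Small planted-marker dataset: 3 types, 1 marker each, 200 background."""
    cfg = ss.SimulationConfig(
        n_cell_types=3,
        n_markers_per_type=1,
        n_background=200,
        samples_per_type=10,
        seed=7,
    )
    X, labels, marker_map = ss.simulate_purified(cfg)
    return cfg, X, labels, marker_map
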