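import numpy as np
import pytest

from memcontact.synthetic import (
    MembraneSystemSpec,
    make_membrane_system,
    make_toy_structure,
)
from memcontact.types import ContactConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def membrane_system():
    spec = MembraneSystemSpec(n_residues=30, n_lipid_tail_atoms=40,
                              n_frames=12, jitter_sigma=0.4, seed=7)
    return make_membrane_system(spec, ContactConfig())


@pytest.fixture
def toy_structure():
    return make_toy_structure(20, seed=3)


def brute_force_occupancy(frames, config):
    """Independent per-frame all-pairs distance loop (the test oracle)."""
    import math

    ca = np.flatnonzero(frames.roles == "protein_ca")
    tails = np.flatnonzero(frames.roles == "lipid_tail_carbon")
    sel = config.frame_indices(frames.n_frames)
    values = []
    for r in ca:
        count = 0
        for f in sel:
            hit = False
            for t in tails:
                if math.dist(frames.coords[f, r], frames.coords[f, t]) <= config.cutoff_A:
                    hit = True
                    break
            if hit:
                count += 1
        values.append(count / len(sel))
    return np.array(values)


def random_rotation(rng):
    """Uniform-ish proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
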