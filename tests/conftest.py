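"""Shared fixtures: small synthetic ensembles reused across test modules."""

import numpy as np
import pytest

from coedecomp import (Ensemble, GeneratorConfig, HISTATIN5, backbone_topology,
                       build_backbone, generate_ensemble)


@pytest.fixture(scope="session")
def hst5_topology():
    return backbone_topology(HISTATIN5)


@pytest.fixture(scope="session")
def helix_frame(hst5_topology):
    """Ideal 24-residue α-helix (φ, ψ) = (−57, −47)."""
    return build_backbone(HISTATIN5, (np.full(24, -57.0), np.full(24, -47.0)))


@pytest.fixture(scope="session")
def extended_frame(hst5_topology):
    """Near-fully-extended chain (φ, ψ) = (−179, 179)."""
    return build_backbone(HISTATIN5, (np.full(24, -179.0), np.full(24, 179.0)))


@pytest.fixture(scope="session")
def mixed_ensemble():
    """600 frames under the default mixed dihedral weights, seed 11."""
    return generate_ensemble(GeneratorConfig(n_frames=600, seed=11))


@pytest.fixture(scope="session")
def compact_ensemble():
    """Helix/turn-biased ensemble: small Rg, H-bond rich."""
    cfg = GeneratorConfig(
        n_frames=60, seed=5,
        region_weights={"beta": 0.0, "ppii": 0.0, "alpha": 0.55, "lh": 0.05, "coil": 0.40},
    )
    return generate_ensemble(cfg)


@pytest.fixture(scope="session")
def extended_ensemble():
    """PPII/β-biased ensemble: large Rg, extended."""
    cfg = GeneratorConfig(
        n_frames=60, seed=5,
        region_weights={"beta": 0.30, "ppii": 0.50, "alpha": 0.0, "lh": 0.0, "coil": 0.20},
    )
    return generate_ensemble(cfg)


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-50, 50, 3)
    return R, t
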