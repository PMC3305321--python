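import dataclasses

import numpy as np
import pytest

from ihcmap.geometry import DihedralOp
from ihcmap.slide_io import SlideImage
from ihcmap.synthetic import SyntheticSpec, default_spec, generate_case

SIGNS = {"ACPP": -1, "CD34": +1, "MKI67": +1}


def small_spec(seed: int = 0, size: int = 512, noise: float = 2.0) -> SyntheticSpec:
    """Default three-stain case shrunk for fast unit tests."""
    spec = default_spec(seed=seed)
    spec.image_size = (size, size)
    spec.noise_sigma = noise
    return spec


@pytest.fixture(scope="session")
def identity_case():
    """Small case with all stains left in reference orientation, noise-free."""
    spec = small_spec(seed=3, noise=0.0)
    return generate_case(spec)


@pytest.fixture(scope="session")
def moved_case():
    """Small case with a nontrivial dihedral + rigid move per stain."""
    spec = small_spec(seed=3)
    moves = [
        (DihedralOp.ROT90, 4.0, (12.0, -9.0)),
        (DihedralOp.FLIP_H, -6.0, (-15.0, 7.0)),
        (DihedralOp.IDENTITY, 2.5, (8.0, 11.0)),
    ]
    spec.stains = [
        dataclasses.replace(s, pre=op, theta=th, translation=t)
        for s, (op, th, t) in zip(spec.stains, moves)
    ]
    return generate_case(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_slide():
    """Uniform mid-gray slide (useful wherever content does not matter)."""
    px = np.full((64, 64, 3), 128, dtype=np.uint8)
    return SlideImage(px, microns_per_pixel=0.5, name="flat")
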