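from dataclasses import replace

import numpy as np
import pytest

from photoseed.phantom import (
    GLAND,
    Material,
    PhantomConfig,
    PhotoseedSpec,
    TissuePhantom,
    build_breast_phantom,
)


@pytest.fixture(scope="session")
def default_phantom():
    """The full default in-vivo phantom (60^3, 2x2 seed array)."""
    return build_breast_phantom(PhantomConfig())


@pytest.fixture()
def small_seed_phantom():
    """A 21^3 gland cube with one absorbing cylindrical seed.

    Odd voxel count keeps the seed axis on a voxel center so a 1 mm
    cylinder is resolved at 1 mm spacing.
    """
    cfg = PhantomConfig(
        block_size=(0.021, 0.021, 0.021),
        spacing=1.0e-3,
        fat_thickness=0.0,
        seed_rows=1,
        seed_cols=1,
        seed=PhotoseedSpec(length=0.01, mu_a_seed=1.0e5),
    )
    return build_breast_phantom(cfg)


def inert(material: Material) -> Material:
    """Strip perfusion and metabolic heat so conduction closed forms apply."""
    return replace(material, thermo=replace(material.thermo, q_met=0.0, omega_b0=0.0))


@pytest.fixture()
def inert_gland_cube():
    """Uniform 6^3 non-perfused gland block for conservation tests."""
    from photoseed.phantom import GLAND_MATERIAL

    labels = np.full((6, 6, 6), GLAND, dtype=np.uint8)
    return TissuePhantom(labels, (1e-3,) * 3, {GLAND: inert(GLAND_MATERIAL)})
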