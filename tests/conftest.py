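import numpy as np
import pytest

from mocha_asl import (
    AcquisitionModel,
    PSFModel,
    RigidTransform,
    make_synthetic_coil_maps,
    make_undersampling_mask,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_model(
    shape=(12, 12, 8),
    spacing=(2.0, 2.0, 2.0),
    fwhm=(0.0, 1.0, 1.5),
    truncation_radius=8,
    transforms=None,
    factors=(2, 2, 2),
    n_coils=3,
    accel=2,
):
    """A small but fully featured acquisition model for operator tests."""
    if transforms is None:
        transforms = [RigidTransform((1.0, -2.0, 3.0), (2.5, -1.0, 4.0))]
    shape_low = tuple(s // f for s, f in zip(shape, factors))
    maps = make_synthetic_coil_maps(n_coils, shape_low)
    mask = make_undersampling_mask(shape_low, accel, 1).array if accel > 1 else None
    return AcquisitionModel(
        shape_high=shape,
        spacing_high=spacing,
        psf=PSFModel(fwhm, truncation_radius=truncation_radius),
        transforms=list(transforms),
        factors=factors,
        coil_maps=maps,
        mask=mask,
    )


def trivial_model(shape=(16, 16, 8), n_pairs=1):
    """Delta PSF, identity motion, unit factors, one uniform coil, full mask."""
    return AcquisitionModel(
        shape_high=shape,
        spacing_high=(1.0, 1.0, 1.0),
        psf=PSFModel((0.0, 0.0, 0.0)),
        transforms=[RigidTransform() for _ in range(n_pairs)],
        factors=(1, 1, 1),
        coil_maps=np.ones((1,) + shape, dtype=complex),
        mask=None,
    )


def complex_noise(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
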