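import numpy as np
import pytest
import SimpleITK as sitk

from trabseg.volume_core import BinaryVolume, DensityVolume, VoxelGrid

# ITK prints (harmless) sampling warnings during small-image registration
sitk.ProcessObject_SetGlobalWarningDisplay(False)


def make_volume(values, spacing=1.0, unit="mgHA_cm3", origin=(0.0, 0.0, 0.0)):
    values = np.asarray(values, dtype=np.float64)
    return DensityVolume(VoxelGrid(values.shape, spacing, origin), values, unit)


def make_mask(values, spacing=1.0, origin=(0.0, 0.0, 0.0)):
    values = np.asarray(values)
    return BinaryVolume(VoxelGrid(values.shape, spacing, origin), values.astype(np.uint8))


def random_volume(rng, shape=(12, 12, 12), lo=0.0, hi=800.0, spacing=1.0):
    return make_volume(rng.uniform(lo, hi, size=shape), spacing=spacing)


def random_mask(rng, shape=(10, 10, 10), p=0.3, spacing=1.0):
    return make_mask((rng.random(shape) < p).astype(np.uint8), spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def plate_case():
    """Identity-check plate phantom: t = 0.06 mm, g = 0.12 mm at 0.02 mm."""
    from trabseg.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(
        geometry="plate_stack",
        feature_size=0.06,
        gap_size=0.12,
        extent_mm=1.08,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def degraded_suite():
    """Realistic-scale degraded plate/rod phantoms (bias 0.2), 3 seeds each."""
    from trabseg.phantom import PhantomSpec, generate_phantom

    cases = []
    for geometry in ("plate_stack", "rod_lattice"):
        for seed in (1, 2, 3):
            cases.append(generate_phantom(PhantomSpec(geometry=geometry, seed=seed)))
    return cases
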