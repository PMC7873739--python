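import numpy as np
import pytest
import trimesh

from sacroplan.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_noiseless():
    """Scaled-down, noise-free phantom: exact calibration round-trips."""
    spec = PhantomSpec.small(scale=0.55, voxel_spacing=1.0, noise_sd=0.0, seed=7)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def small_phantom_noisy():
    spec = PhantomSpec.small(scale=0.55, voxel_spacing=1.0, noise_sd=15.0, seed=11)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def accuracy_phantom():
    """Scaled geometry at the clinical 0.6 mm voxel size: the drill bit
    (2.5 mm) must span several voxels for sub-degree axis fits."""
    spec = PhantomSpec.small(scale=0.55, voxel_spacing=0.6, noise_sd=0.0, seed=7)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def full_phantom():
    """Full-size phantom at the clinical 0.6 mm voxel size (no noise)."""
    spec = PhantomSpec(noise_sd=0.0, seed=3)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def sphere_volume():
    """Synthetic solid sphere (r = 10 mm) rendered into a 0.6 mm HU volume."""
    from sacroplan.volume import CtVolume

    r = 10.0
    sp = 0.6
    n = int(np.ceil(2 * (r + 3) / sp))
    ax = (np.arange(n) - (n - 1) / 2) * sp
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    dist = np.sqrt(X**2 + Y**2 + Z**2)
    # supersample-free analytic partial volume via smooth ramp one voxel wide
    frac = np.clip((r - dist) / sp + 0.5, 0.0, 1.0)
    hu = -100.0 + frac * 800.0
    origin = np.full(3, ax[0])
    return CtVolume(hu, sp, origin), r


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)
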