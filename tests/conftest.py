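import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from fluidvbm import PhantomSpec, ViscosityParams, apply_operator, make_phantom
from fluidvbm.volumes import ScalarVolume, VectorField


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def compact_deformation(shape=(16, 16, 16), seed=0):
    """Smooth vector field supported well inside the grid, with exactly zero
    component sums (central difference of a compact bump telescopes)."""
    rng = np.random.default_rng(seed)
    bump = np.zeros(shape)
    c = tuple(slice(s // 2 - 2, s // 2 + 2) for s in shape)
    bump[c] = rng.uniform(0.5, 1.0, size=(4, 4, 4))
    bump = gaussian_filter(bump, 1.2)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = slice(0, 3)
        bump[tuple(sl)] = 0.0
        sl[ax] = slice(-3, None)
        bump[tuple(sl)] = 0.0
    w = np.stack([np.gradient(bump, axis=i) for i in range(3)])
    for ax in range(3):
        sl = [slice(None)] * 4
        sl[1 + ax] = slice(0, 2)
        w[tuple(sl)] = 0.0
        sl[1 + ax] = slice(-2, None)
        w[tuple(sl)] = 0.0
    return VectorField(w)


@pytest.fixture
def interior_force():
    """Force field induced by a compact interior deformation: F = -L w.

    The Dirichlet (SOR) solution of L v = -F is then w itself, and the
    periodic Fourier solution agrees away from the boundary, which makes this
    the natural cross-solver fixture.
    """
    w = compact_deformation()
    visc = ViscosityParams(1.0, 0.0)
    F = VectorField(-apply_operator(w, visc).field)
    return F, w, visc


def smooth_random_force(shape=(16, 16, 16), seed=0, taper=4):
    """Generic smooth force, tapered to zero near the boundary faces."""
    rng = np.random.default_rng(seed)
    F = np.stack([gaussian_filter(rng.normal(size=shape), 2.0) for _ in range(3)])
    win = np.ones(shape)
    for ax, n in enumerate(shape):
        t = np.ones(n)
        ramp = np.linspace(0.0, 1.0, taper, endpoint=False)
        t[:taper] = ramp
        t[-taper:] = ramp[::-1]
        win *= t.reshape([n if i == ax else 1 for i in range(3)])
    return VectorField(F * win)


@pytest.fixture
def sphere_pair():
    """Target sphere and the same sphere translated by 3 voxels along x."""
    shape = (32, 32, 32)
    target = make_phantom(PhantomSpec(
        shape=shape, voxel_mm=2.0,
        structures=[((32.0, 32.0, 32.0), (10.0, 10.0, 10.0), 0.9)],
        smoothness_mm=4.0))
    subject = make_phantom(PhantomSpec(
        shape=shape, voxel_mm=2.0,
        structures=[((26.0, 32.0, 32.0), (10.0, 10.0, 10.0), 0.9)],
        smoothness_mm=4.0))
    return subject, target


@pytest.fixture
def small_volume(rng):
    return ScalarVolume(rng.uniform(0.0, 1.0, size=(8, 9, 10)), (2.0, 2.0, 2.0))
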