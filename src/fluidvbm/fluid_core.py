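"""Force field and solvers for the linearized Navier-Stokes system L v = -F.

The fluid model treats the subject image as a viscous body driven toward the
target by an external force F.  At equilibrium the internal viscous forces
balance F:

    mu * lap(v) + (mu + lam) * grad(div(v)) + F = 0,       L v = -F

with v the velocity field and mu, lam the viscosity constants.  Discretizing
with central differences (7-point Laplacian, central first differences for
divergence and gradient, zero-Dirichlet ghost cells outside the grid) turns
this into a sparse linear system per image, which can be

* solved explicitly by successive over-relaxation (``solve_sor``),
* solved with adaptive updates restricted to an active set (``solve_sora``),
* approximated by Gaussian convolution of the force (``solve_gaussian``), or
* inverted exactly in the discrete Fourier domain under periodic boundary
  conditions -- the eigenfunction-based "viscous kernel" (``solve_viscous_kernel``).

``apply_operator`` implements L itself and is the forward oracle every solver
is verified against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.sparse.linalg import spsolve_triangular

from .volumes import (
    DisplacementField,
    ScalarVolume,
    VectorFieldSample,
    _check_same_shape,
    sample_warped,
    spatial_gradient,
)

SOLVER_KINDS = ("sor", "sora", "gaussian", "viscous_kernel")


@dataclass
class ViscosityParams:
    """Viscosity constants of the fluid model.

    mu > 0 is the first (shear) viscosity; lam >= -mu with mu + lam > 0 keeps
    the operator elliptic.  Defaults mu=1, lam=0: the common fluid-registration
    choice, and the one that keeps the Fourier-domain system well conditioned.
    """

    mu: float = 1.0
    lam: float = 0.0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.mu + self.lam <= 0:
            raise ValueError(f"mu + lam must be > 0, got {self.mu + self.lam}")


@dataclass
class SolverSpec:
    """Choice of solver and its numerical knobs.

    relaxation is the SOR over-relaxation factor, in (0, 2); tolerance is a
    relative residual ||L v + F|| / ||F||; gaussian_sigma (voxels) applies to
    the Gaussian-kernel approximation only.
    """

    kind: str = "viscous_kernel"
    tolerance: float = 1e-3
    max_sweeps: int = 200
    relaxation: float = 1.5
    gaussian_sigma: float = 2.0

    def __post_init__(self):
        if self.kind not in SOLVER_KINDS:
            raise ValueError(f"kind must be one of {SOLVER_KINDS}, got {self.kind!r}")
        if not (0.0 < self.relaxation < 2.0):
            raise ValueError(f"relaxation must be in (0, 2), got {self.relaxation}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")


def compute_force(subject: ScalarVolume, target: ScalarVolume,
                  u: DisplacementField) -> VectorFieldSample:
    """Image-difference force: F(x) = [S(x-u(x)) - T(x)] * grad(S_w)(x).

    S_w is the warped subject; both it and its gradient are evaluated on the
    reference grid.  Sign convention: the solvers return v = (-L)^-1 F
    (positively aligned with F), and under the x - u(x) pullback the SSD
    cost E(u) = sum (S_w - T)^2 has per-voxel steepest-descent direction
    du_i = +(S_w - T) dS_w/dx_i, so this F makes the flow descend E and
    drive the warped subject toward the target.  (The one-voxel perturbation
    oracle in the tests pins this sign.)
    """
    _check_same_shape(subject.shape, target.shape, "compute_force subject/target")
    _check_same_shape(subject.shape, u.grid_shape, "compute_force subject/u")
    warped = sample_warped(subject, u)
    grad = spatial_gradient(warped)
    diff = warped.data - target.data
    return VectorFieldSample(diff[None] * grad.field, subject.voxel_size)


# ---------------------------------------------------------------------------
# Discrete operator: padded-array application and matching sparse matrix
# ---------------------------------------------------------------------------

def _central_diff(a: np.ndarray, axis: int) -> np.ndarray:
    """Central first difference with zero-Dirichlet ghost cells."""
    p = np.pad(a, 1)
    sl_hi = [slice(1, -1)] * 3
    sl_lo = [slice(1, -1)] * 3
    sl_hi[axis] = slice(2, None)
    sl_lo[axis] = slice(0, -2)
    return 0.5 * (p[tuple(sl_hi)] - p[tuple(sl_lo)])


def _laplacian(a: np.ndarray) -> np.ndarray:
    """7-point Laplacian with zero-Dirichlet ghost cells."""
    p = np.pad(a, 1)
    out = -6.0 * a
    for axis in range(3):
        sl_hi = [slice(1, -1)] * 3
        sl_lo = [slice(1, -1)] * 3
        sl_hi[axis] = slice(2, None)
        sl_lo[axis] = slice(0, -2)
        out += p[tuple(sl_hi)] + p[tuple(sl_lo)]
    return out


def apply_operator(v: VectorFieldSample, visc: ViscosityParams) -> VectorFieldSample:
    """Forward operator L v = mu*lap(v) + (mu+lam)*grad(div v), componentwise.

    Uses the same zero-Dirichlet central-difference discretization as the
    iterative solvers, which makes it their exact forward oracle.
    """
    mu, lam = visc.mu, visc.lam
    div = sum(_central_diff(v.field[j], j) for j in range(3))
    out = np.empty_like(v.field)
    for i in range(3):
        out[i] = mu * _laplacian(v.field[i]) + (mu + lam) * _central_diff(div, i)
    return VectorFieldSample(out, v.voxel_size)


_MATRIX_CACHE: dict = {}


def _diff_matrices_1d(n: int):
    c = sp.diags([np.full(n - 1, 0.5), np.full(n - 1, -0.5)], [1, -1], format="csr")
    s = sp.diags([np.ones(n - 1), np.full(n, -2.0), np.ones(n - 1)], [1, 0, -1],
                 format="csr")
    return c, s


def operator_matrix(shape, visc: ViscosityParams) -> sp.csr_matrix:
    """Sparse matrix of -L on the flattened (component-major) unknown vector.

    -L is symmetric positive definite under the zero-Dirichlet discretization,
    so the system (-L) v = F is solvable by SOR for any relaxation in (0, 2).
    Cached per (shape, mu, lam).
    """
    key = (tuple(shape), visc.mu, visc.lam)
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    nx, ny, nz = shape
    eye = [sp.identity(n, format="csr") for n in shape]
    c = [_diff_matrices_1d(n)[0] for n in shape]
    s = [_diff_matrices_1d(n)[1] for n in shape]

    def kron3(a, b, cmat):
        return sp.kron(sp.kron(a, b, format="csr"), cmat, format="csr")

    D = [
        kron3(c[0], eye[1], eye[2]),
        kron3(eye[0], c[1], eye[2]),
        kron3(eye[0], eye[1], c[2]),
    ]
    lap = (kron3(s[0], eye[1], eye[2]) + kron3(eye[0], s[1], eye[2])
           + kron3(eye[0], eye[1], s[2]))
    mu, lam = visc.mu, visc.lam
    blocks = [[None] * 3 for _ in range(3)]
    for i in range(3):
        for j in range(3):
            block = (mu + lam) * (D[i] @ D[j])
            if i == j:
                block = block + mu * lap
            blocks[i][j] = -block
    A = sp.bmat(blocks, format="csr")
    _MATRIX_CACHE[key] = A
    return A


def _sor_factors(shape, visc: ViscosityParams, omega: float):
    key = (tuple(shape), visc.mu, visc.lam, omega)
    cache = _MATRIX_CACHE.setdefault("sor_factors", {})
    if key in cache:
        return cache[key]
    A = operator_matrix(shape, visc)
    d = A.diagonal()
    M = (sp.tril(A, -1, format="csr") * omega + sp.diags(d)).tocsr()
    N = (sp.triu(A, 1, format="csr") * omega + sp.diags(d * (omega - 1.0))).tocsr()
    cache[key] = (A, M, N)
    return A, M, N


def _sor_sweeps(A, M, N, b, x, omega, tol, max_sweeps, bnorm):
    """Run SOR sweeps on A x = b until relative residual <= tol."""
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        x = spsolve_triangular(M, omega * b - N @ x, lower=True)
        res = np.linalg.norm(b - A @ x) / bnorm
        if res <= tol:
            converged = True
            break
    return x, converged, sweeps


def solve_sor(F: VectorFieldSample, visc: ViscosityParams,
              spec: SolverSpec) -> VectorFieldSample:
    """Explicit solution of L v = -F by successive over-relaxation.

    Lexicographic SOR sweeps (exact triangular solves on the assembled sparse
    operator) until ||L v + F|| / ||F|| <= spec.tolerance, or max_sweeps with
    a warning.  Velocity outside the grid is clamped to 0.
    """
    shape = F.grid_shape
    b = F.field.reshape(3, -1).reshape(-1)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return VectorFieldSample(np.zeros_like(F.field), F.voxel_size)
    A, M, N = _sor_factors(shape, visc, spec.relaxation)
    x = np.zeros_like(b)
    x, converged, _ = _sor_sweeps(A, M, N, b, x, spec.relaxation,
                                  spec.tolerance, spec.max_sweeps, bnorm)
    if not converged:
        warnings.warn(
            f"SOR stopped at max_sweeps={spec.max_sweeps} above tolerance",
            RuntimeWarning, stacklevel=2)
    return VectorFieldSample(x.reshape(3, *shape), F.voxel_size)


def solve_sora(F: VectorFieldSample, visc: ViscosityParams, spec: SolverSpec,
               active_threshold: float = 0.0) -> VectorFieldSample:
    """SOR with adaptive updates: sweeps touch only an active voxel set.

    The set is seeded by voxels whose force vector norm exceeds
    ``active_threshold`` (plus their 6-neighbors) and re-expanded from the
    global residual whenever the subsystem has converged but the global
    residual has not.  With active_threshold = 0 every voxel is active and
    the sweep schedule is identical to plain SOR.  The final residual check
    is always global.
    """
    shape = F.grid_shape
    nvox = int(np.prod(shape))
    b = F.field.reshape(-1)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return VectorFieldSample(np.zeros_like(F.field), F.voxel_size)
    A, M, N = _sor_factors(shape, visc, spec.relaxation)
    omega = spec.relaxation

    active = F.norms().reshape(-1) >= active_threshold
    struct = np.zeros((3, 3, 3), bool)
    struct[1, 1, :] = struct[1, :, 1] = struct[:, 1, 1] = True
    active = binary_dilation(active.reshape(shape), struct).reshape(-1)

    x = np.zeros_like(b)
    sweeps_left = spec.max_sweeps
    converged = False
    while sweeps_left > 0:
        if active.all():
            x, converged, used = _sor_sweeps(A, M, N, b, x, omega,
                                             spec.tolerance, sweeps_left, bnorm)
            sweeps_left -= used
            break
        idx = np.flatnonzero(np.tile(active, 3))
        A_sub = A[idx][:, idx].tocsr()
        d_sub = A_sub.diagonal()
        M_sub = (sp.tril(A_sub, -1, format="csr") * omega + sp.diags(d_sub)).tocsr()
        N_sub = (sp.triu(A_sub, 1, format="csr") * omega
                 + sp.diags(d_sub * (omega - 1.0))).tocsr()
        # right-hand side absorbs coupling to the frozen (inactive) unknowns
        b_sub = b[idx] - (A[idx] @ x) + A_sub @ x[idx]
        x_sub = x[idx]
        x_sub, _, used = _sor_sweeps(A_sub, M_sub, N_sub, b_sub, x_sub, omega,
                                     spec.tolerance, min(sweeps_left, 20),
                                     np.linalg.norm(b_sub) or 1.0)
        sweeps_left -= used
        x[idx] = x_sub
        r = b - A @ x
        if np.linalg.norm(r) / bnorm <= spec.tolerance:
            converged = True
            break
        # stalled on this set: grow it where the global residual lives
        r_norm = np.sqrt((r.reshape(3, nvox) ** 2).sum(axis=0))
        grow = r_norm > spec.tolerance * bnorm / np.sqrt(nvox)
        grow = binary_dilation(grow.reshape(shape), struct).reshape(-1)
        new_active = active | grow
        if new_active.sum() == active.sum():
            new_active[:] = True
        active = new_active
    if not converged:
        warnings.warn(
            f"SORA stopped at max_sweeps={spec.max_sweeps} above tolerance",
            RuntimeWarning, stacklevel=2)
    return VectorFieldSample(x.reshape(3, *shape), F.voxel_size)


def solve_gaussian(F: VectorFieldSample, spec: SolverSpec) -> VectorFieldSample:
    """Gaussian-kernel approximation: v = G_sigma * F, componentwise.

    The crudest of the kernel approximations to L^-1 (a demons-style
    regularizer); it carries no operator-residual guarantee and is kept for
    comparison with the explicit and eigenfunction solvers.
    """
    out = np.stack([
        gaussian_filter(F.field[i], spec.gaussian_sigma, mode="constant", cval=0.0)
        for i in range(3)
    ])
    return VectorFieldSample(out, F.voxel_size)


def solve_viscous_kernel(F: VectorFieldSample,
                         visc: ViscosityParams) -> VectorFieldSample:
    """Eigenfunction ("viscous kernel") solution of L v = -F in Fourier space.

    Under periodic boundary conditions the discrete operator is diagonalized
    by the DFT: at frequency w the system is A(w) vhat = Fhat with

        A(w) = mu * Lam(w) * I + (mu + lam) * s(w) s(w)^T,
        Lam(w) = sum_j 2 (1 - cos w_j),   s(w)_j = sin w_j,

    (the central-difference symbol is i*sin w_j, so the rank-one term
    d d^H is real).  A is inverted by Sherman-Morrison; the singular
    zero-frequency mode is set to 0, i.e. the zero-mean solution is returned.
    """
    shape = F.grid_shape
    if min(shape) < 4:
        raise ValueError(f"grid dimensions must be >= 4, got {shape}")
    mu, lam = visc.mu, visc.lam
    w = [2.0 * np.pi * np.fft.fftfreq(n) for n in shape]
    sin_w = np.meshgrid(*[np.sin(wi) for wi in w], indexing="ij")
    lam_sym = sum(2.0 * (1.0 - np.cos(wi))
                  for wi in np.meshgrid(*w, indexing="ij"))
    s2 = sum(s * s for s in sin_w)

    Fhat = np.stack([np.fft.fftn(F.field[i]) for i in range(3)])
    sF = sum(sin_w[j] * Fhat[j] for j in range(3))

    zero = lam_sym == 0.0  # the w=0 mode (A singular): zero-mean solution
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_mul = 1.0 / (mu * lam_sym)
        corr = (mu + lam) / (mu * lam_sym * (mu * lam_sym + (mu + lam) * s2))
    inv_mul[zero] = 0.0
    corr[zero] = 0.0
    vhat = np.empty_like(Fhat)
    for i in range(3):
        vhat[i] = inv_mul * Fhat[i] - corr * sin_w[i] * sF
    v = np.stack([np.real(np.fft.ifftn(vhat[i])) for i in range(3)])
    return VectorFieldSample(v, F.voxel_size)


def solve_velocity(F: VectorFieldSample, visc: ViscosityParams,
                   spec: SolverSpec, active_threshold: float = 0.0
                   ) -> VectorFieldSample:
    """Dispatch to the solver selected by ``spec.kind``."""
    if spec.kind == "sor":
        return solve_sor(F, visc, spec)
    if spec.kind == "sora":
        return solve_sora(F, visc, spec, active_threshold)
    if spec.kind == "gaussian":
        return solve_gaussian(F, spec)
    return solve_viscous_kernel(F, visc)
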