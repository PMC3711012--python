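# fluidvbm

Viscous fluid registration of gray-matter probability maps, Jacobian
modulation, and a minimal voxel-based morphometry (VBM) statistics stage —
with synthetic phantom cohorts carrying ground-truth atrophy so the whole
pipeline can be validated without patient data.

## The problem

VBM compares tissue probability maps across subject groups voxel by voxel.
Its sensitivity and localization depend critically on how well the maps are
registered to a common space.  Heavily regularized diffeomorphic methods
produce elegant, invertible warps but can under-fit atrophic brains, smearing
real group differences into broad amorphous blobs.  This package implements
the opposite trade-off: a classic high-degrees-of-freedom **viscous fluid
registration** applied as an extra step on top of coarsely aligned
gray-matter segments.  Diffeomorphism is deliberately not enforced; topology
is protected instead by regridding.

## The model

The subject map S is treated as a viscous fluid deforming onto a target T
under an image-difference force field.  The velocity field **v** solves the
linearized Navier–Stokes equilibrium

    μ ∇²v + (μ + λ) ∇(∇·v) + F = 0,

with viscosity constants μ, λ.  Displacements follow an Eulerian convention:
the warped image reads `S_w(x) = S(x − u(x))`.  Each iteration:

1. force: `F = (S_w − T) · ∇S_w` (the steepest-descent direction of the SSD
   cost under this convention);
2. velocity: solve `L v = −F` with one of four interchangeable solvers —
   exact successive over-relaxation (**SOR**), SOR with adaptive updates
   restricted to an active set (**SORA**), Gaussian-kernel convolution, or
   the eigenfunction-based **viscous kernel** (exact inversion of the
   discrete operator in the Fourier domain);
3. perturbation: `R = v − Σᵢ vᵢ ∂u/∂xᵢ` (material derivative);
4. time step: `ΔT = m / ‖R‖_max`, capping each iteration's displacement at
   m voxels;
5. Euler update `u ← u + R·ΔT`;
6. regrid when `det(I − ∂u/∂x)` drops below a threshold: save the field,
   resample the working subject, restart u from zero.  The composed warp
   keeps a strictly positive Jacobian determinant.

Warped maps are **modulated** by the Jacobian determinant so that tissue
*amount* (not just concentration) is compared; total probability mass is
conserved to interpolation accuracy.  The statistics stage smooths the
modulated maps (8 mm FWHM by default), masks at a relative threshold of 0.2,
fits a voxelwise two-group GLM with total intracranial volume (TIV) as
nuisance covariate, and thresholds at uncorrected p < 0.001 or a
family-wise-error level obtained by max-statistic permutation.

Registration consistency is scored with fiducial dispersion metrics: λ₁,
the standard-deviation-like spread of a landmark cluster along its main
error direction (mm), and R₁ = e₁/(e₁+e₂+e₃), the anisotropy of that error
(1/3 isotropic, 1 collinear).

## Worked example

Register a sphere phantom translated by 3 voxels back onto its original,
then check mass conservation under modulation:

```python
from fluidvbm import (FluidRegistration, PhantomSpec, RegistrationConfig,
                      SolverSpec, make_phantom, modulate)

target  = make_phantom(PhantomSpec(shape=(32,)*3, voxel_mm=2.0,
          structures=[((32.,)*3, (10.,)*3, 0.9)], smoothness_mm=4.0))
subject = make_phantom(PhantomSpec(shape=(32,)*3, voxel_mm=2.0,
          structures=[((26., 32., 32.), (10.,)*3, 0.9)], smoothness_mm=4.0))

cfg = RegistrationConfig(solver=SolverSpec(kind="viscous_kernel"),
                         max_iterations=200, max_step_m=0.3)
res = FluidRegistration(subject, target, cfg).fit()
print(res.summary())
```

prints

```
Viscous fluid registration results
----------------------------------
iterations run        : 26
stop reason           : cost_increase
initial SSD           : 65.0845
final SSD             : 0.33124
cost ratio final/init : 0.0051
regrid events         : 0
min Jacobian det      : 0.6072
max Jacobian det      : 1.7261
max displacement (vox): 3.199
```

The SSD mismatch drops to 0.5% of its initial value, the mean recovered
displacement inside the object is (2.71, 0, 0) voxels against a true
translation of (3, 0, 0), and the warp never folds (min Jacobian 0.61 > 0).
Modulating the warped map by the Jacobian restores the subject's total
probability mass to 0.3%: 463.5 before, 464.7 after.

`modulate`, `estimate_tiv`, `normalize_to_mean_tiv` and
`group_percent_change` implement the volume arithmetic used for hippocampal
group tables; `VBMModel(maps, design).fit()` runs the statistics stage and
its `summary()` reports the t threshold and suprathreshold count.  A `fluidvbm`
console script exposes `register`, `modulate`, `tiv`, `vbm` and `phantom`
subcommands over the same library.

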