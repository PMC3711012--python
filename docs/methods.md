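# Methods

## Fluid model and discretization

The registration treats the subject probability map as a compressible
viscous fluid.  At equilibrium the internal viscous stresses balance the
external image force:

    μ ∇²v + (μ + λ) ∇(∇·v) + F = 0        (L v = −F)

All fields live on the voxel grid; displacements are stored in voxel units
and millimetres enter only through the voxel size (I/O, fiducials,
smoothing kernels).  The operator L is discretized with the 7-point
Laplacian and central first differences for divergence and gradient,
composed, so the grad-div part is the product of two central-difference
stencils (a ±2 reach).  Ghost cells outside the grid hold zero velocity
(clamped boundary).  `apply_operator` and the sparse matrix used by the
iterative solvers are built from the same factors, which makes the forward
residual ‖Lv + F‖/‖F‖ an exact convergence measure.

**Viscosity defaults** μ = 1, λ = 0 (dimensionless).  Only the ratio
(μ+λ)/μ changes the shape of the flow; λ = 0 is the common
fluid-registration choice and keeps the Fourier-domain system well
conditioned.

**Force.** F = (S_w − T)·∇S_w with S_w the warped subject and the gradient
taken of the warped image on the reference grid.  Under the Eulerian
pullback `S_w(x) = S(x − u(x))` and with solvers returning v = (−L)⁻¹F
(positively aligned with F), this is the steepest-descent direction of the
sum-of-squared-differences cost: a one-voxel perturbation oracle in the
test suite pins the sign, and a 1D simulation shows the opposite sign
diverges immediately.

## Solvers

* **SOR** — exact lexicographic successive over-relaxation implemented as
  sparse triangular solves on the assembled matrix A = −L (symmetric
  positive definite under the clamped discretization, so SOR converges for
  any relaxation in (0, 2)).  Defaults: relaxation 1.5, relative-residual
  tolerance 1e−3, 200 sweep cap.  Convergence is always certified against
  the true residual.
* **SORA** — the same sweeps restricted to an active voxel set seeded where
  the force-vector norm exceeds a threshold (dilated by the 6-neighborhood)
  and solved as a block Gauss–Seidel subsystem; whenever the subsystem
  converges but the global residual has not, the set is grown where the
  residual lives (and to the full grid if growth stalls).  The final
  residual check is global.  With threshold 0 the schedule is identical to
  SOR.  The active-set schedule is a reconstruction validated only by
  equivalence with SOR.
* **Gaussian kernel** — componentwise Gaussian convolution of the force
  (a demons-style regularizer).  No residual guarantee; retained as the
  crudest kernel approximation.
* **Viscous kernel** — exact inversion of the discretized operator in the
  DFT domain under periodic boundary conditions.  At frequency ω the
  symbol is A(ω) = μΛ(ω)I + (μ+λ)s(ω)s(ω)ᵀ with Λ(ω) = Σⱼ2(1−cos ωⱼ) and
  s(ω)ⱼ = sin ωⱼ; A is inverted by Sherman–Morrison and the singular DC
  mode is zeroed (zero-mean solution).  This is the untruncated limit of
  the eigenfunction kernel rather than a finite convolution stencil.

Because SOR is clamped and the Fourier kernel periodic, the two agree only
where the solution is insensitive to the boundary condition.  Equivalence
tests therefore use forces induced by compact interior deformations
(F = −Lw with w supported away from the faces and zero component sums):
for that class the Dirichlet solution is w itself and the agreement bound
(relative L2 ≤ 1e−2 on the interior) is meaningful.  For generic forces the
two Green functions differ globally and no such bound is claimed.

## Outer loop

Per iteration: force → velocity → perturbation R = v − Σᵢ vᵢ ∂u/∂xᵢ
(central differences) → adaptive step ΔT = m/‖R‖_max → Euler update.  The
step cap m defaults to 0.3 voxels; the cap is exact by construction and
instrumented in the results object.  Iterations stop at `max_iterations`
(default 15, the short schedule appropriate for maps that are already
coarsely aligned; validation experiments that must fully converge use a
larger cap), when ‖R‖_max < 1e−4 (step tolerance), or when the SSD cost
would increase (the offending update is rolled back).  The cost trace is
non-increasing by construction.

**Regridding.** After each accepted update, if min det(I − ∂u/∂x) < 0.5
the current field is pushed onto a stack, the working subject is resampled
through it, and u restarts at zero.  The total warp is the interpolated
composition u_tot(x) = u_outer(x) + u_inner(x − u_outer(x)), folded from
the last field outward so the earliest saved field touches the original
subject.  The inner field is edge-extended (not zero-extrapolated) during
composition; zero extrapolation puts an artificial kink at the boundary
faces that central differencing reads as a fold.  The composed determinant
stays strictly positive on all test cases; inverse consistency is neither
sought nor claimed.

## Modulation and volume arithmetic

Modulation multiplies the warped map by det(I − ∂u/∂x); by the change of
variables this conserves total probability mass up to interpolation error
(≤ 2% on smooth phantoms, typically ≤ 0.5%).  TIV is the plain probability
mass of the native GM+WM+CSF segments times the voxel volume; skull-cleanup
refinements of dedicated TIV tools are out of scope, and the synthetic
segments are constructed so the plain sum is exact.  Regional volumes are
normalized to the mean control TIV by simple proportion; group percent
change is computed from unrounded means and reported at one decimal.

## VBM statistics

Smoothing uses σ = FWHM/(voxel·√(8 ln 2)) per axis with zero-padded
boundaries.  The analysis mask intersects, over the *unsmoothed* input
maps, the voxels exceeding 0.2 × that image's mean over strictly positive
voxels; masking before smoothing keeps the mask on tissue support instead
of the smoothing halo.  The GLM is voxelwise OLS on intercept + group +
centered TIV, contrast control − patient (one-sided, atrophy positive),
dof = n − rank; a collinear TIV column is dropped with a warning, and
zero-variance voxels report t = 0 and are flagged.  Family-wise error is
controlled by max-statistic permutation of the group labels (TIV held
fixed), using the (1−α) upper order statistic of the permutation max-t
distribution, with exact enumeration when fewer distinct assignments exist
than permutations requested.  This replaces random-field-theory correction
by design and is recorded in the output metadata.

## Synthetic data

The default brain phantom is a large ellipsoid (peak GM probability 0.25,
radii 0.42 × field of view) containing a distinct inner structure
(peak 0.9 total, radius 0.2 × FOV) whose boundary gives simulated atrophy
something to move; maps are lightly smoothed (2 mm) and clipped to [0, 1].
Cohort subjects are warps of this template by smooth random displacement
fields (Gaussian-filtered white noise, σ = 3 voxels, scaled to an RMS of
2–3 mm) plus additive Gaussian intensity noise (sd 0.05–0.1), mimicking
residual inter-subject variability after coarse normalization.  TIVs are
drawn independently (mean 1.5 L, CV 0.1).

**Simulated atrophy** applies an analytic radial contraction: sampling is
scaled outward by c inside the target region and the displacement decays
linearly over a taper shell (≤ 5 voxels), so the ground-truth Jacobian is
positive whenever (c−1) < taper/core.  c starts at (1−f)^(−1/3) and is
refined by bisection until the probability mass inside the region drops by
the requested fraction f (±0.1% of the original mass), within the
topology-safe range.  The region mask (inner structure + 1 voxel) is
returned as ground truth.

What the generator does **not** emulate: real segmentation errors,
anatomically structured (non-stationary) covariance, partial-volume
profiles, multi-structure atrophy, or scanner effects.  Passing tests
therefore demonstrate correctness of the algorithms under controlled
conditions, not clinical performance.

## Validation experiment sizes and choices

* Solver equivalence runs on 16³ grids; translation recovery, topology and
  mass-conservation phantoms on 32³; atrophy detection on 48³ (the
  smoothing halo is ~3 voxels wide regardless of grid, so the truth region
  must be ≳10 voxels in radius for a Dice comparison to be informative,
  and the atrophy's influence zone must still fit inside the phantom brain).
* Statistical calibration uses 200 independent null cohorts at 24³ with
  n = 8+8 and 199 permutations.  Calibration cohorts use purely additive
  Gaussian inter-subject noise (jitter 0): the nominal-rate claim being
  verified presumes Gaussian errors, and anatomical jitter makes voxel
  noise skewed at structure boundaries — the same reason parametric
  p-values are approximate on real VBM data.  The voxelwise-rate check uses
  a CI over simulations (in-mask voxels are spatially correlated, so a
  pooled binomial CI would be wrong); the family-wise check is a genuine
  200-trial binomial.
* Fiducial experiments place 20 landmarks on the inner-structure surface
  (spherical Fibonacci lattice); landmark tracking solves x − u(x) = q by
  fixed-point iteration (5 steps) with trilinear field interpolation.
  Jittered subjects stand in for the coarse pre-alignment; the fluid step
  is required not to increase the median λ₁ across clusters, and in
  practice reduces it by ~20–25%.

## Known limitations

* The fluid step assumes gross alignment has already been done; there is
  no multi-resolution pyramid and no linear registration.
* The Gaussian-kernel solver is a documented approximation with no
  residual contract.
* The regrid schedule (threshold 0.5, push/resample/reset) and the SORA
  active-set rule follow the general fluid-registration literature; other
  reconstructions are possible.
* Uncorrected parametric p-values are exact only under Gaussian errors;
  on cohorts with anatomical jitter they are mildly anticonservative in the
  extreme tail, while the permutation threshold remains valid under
  exchangeability.
* λ₁ is defined as the square root of the leading covariance eigenvalue
  (standard-deviation units) and degenerate clusters report R₁ = 1/3;
  these conventions are frozen here and used consistently.
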