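# Methods

This note records the models implemented in `xlct`, the assumptions behind
them, the defaults that matter, and what the synthetic studies do and do not
demonstrate.

## Imaging model

Cone-beam X-ray luminescence CT (CB-XLCT) excites X-ray-luminescent
nanophosphors (Y₂O₃:Eu³⁺ in the canonical setup) inside a scattering object
and records the emitted visible/NIR light at the boundary from many view
angles. The forward chain is linear in the nanoparticle concentration
n(r):

1. **Excitation.** X-ray intensity follows Lambert–Beer,
   X(r) = X(r₀) exp(−∫ μ_t ds), integrated along the straight ray from the
   focal spot. For the homogeneous cylinder the path length is the analytic
   ray–cylinder intersection; heterogeneous μ_t maps would require sampled
   quadrature (not needed for the cylinder studies). The focal spot sits
   20 cm from the rotation axis by default; since the phantom is homogeneous
   the cone geometry only changes path lengths through the cylinder.
2. **Emission.** S(r) = Γ·X(r)·n(r). The light yield Γ and the phantom's
   X-ray attenuation (default μ_t = 0.3 cm⁻¹) are not identifiable from
   max-normalized reconstructions — they set a global scale that cancels —
   so Γ defaults to 1 in arbitrary units.
3. **Transport.** The diffusion approximation
   −∇·(D∇Φ) + μ_a Φ = S with D = 1/(3(μ_s′+μ_a)) and Robin boundary
   condition Φ + 2κD(ν·∇Φ) = 0 (κ = 1, index-matched, unless configured).
   Valid for μ_s′ ≫ μ_a; the simulation medium (μ_a = 0.02, μ_s′ = 10 cm⁻¹)
   is deep in that regime.
4. **Detection.** Boundary exitance J = Φ/(2κ) at camera-facing surface
   nodes is splatted orthographically onto the detector with an
   area × cosine (Lambertian) weight and bilinear pixel interpolation,
   followed by a Gaussian point-spread blur (default σ = 1 mm, configurable)
   that models finite camera resolution and — numerically — washes out the
   boundary-node lattice so images reflect the surface radiance rather than
   the mesh texture. Free-space lens optics between surface and camera are
   deliberately not modelled; the orthographic splat + PSF is the package's
   explicit approximation for the unreported camera geometry. The object
   rotates between views, implemented as rotating the source/camera
   direction in the phantom frame.

### Discretization

Light transport is discretized with P1 finite elements on a structured
tetrahedral cylinder mesh (concentric-ring layers, Delaunay-triangulated
disks, prisms split by the minimum-vertex-index rule, which guarantees a
conforming watertight mesh). Ring point counts are multiples of 8 with
alternate rings staggered by half a step: the point set is then invariant
under 90-degree rotations and axis mirrors, so the discrete operator
respects the scene symmetries (to within triangulation tie-breaking, a few
percent on projections) — which both reduces orientation bias and makes the
training-time symmetry augmentation physically valid. System matrix: stiffness(D) + mass(μ_a) +
surface-mass/(2κ). Solvers: sparse LU for meshes up to 20k nodes (the
factorization is reused across the many right-hand sides of dataset
generation and weight-matrix assembly), Jacobi-preconditioned CG (relative
residual ≤ 1e−8, checked) for larger single solves.

P1 elements carry no discrete maximum principle, so point-like sources
produce small negative fluence undershoots (order 1e−3 of the maximum on
coarse meshes). The same undershoot appears in the weight matrix W; W is
*not* clipped, because the package guarantees W·x equals the direct forward
chain to machine precision, and MLEM — which requires a nonnegative system
matrix — clips its own copy.

### Weight matrix

W maps voxel concentrations to all stacked detector pixels (view-major,
row-major). Assembly uses reciprocity: one factorized solve per boundary
node yields K₀ = R A⁻¹, and each view's block is G_v K₀ M diag(ΓX_v) B /
(2κ), where B is the trilinear voxel→node interpolation and G_v the splat
matrix. A direct column-by-column assembly (one forward solve per voxel) is
retained as a cross-check; the two agree entrywise to ~1e−15 relative on
coarse meshes, and W·x matches the direct chain to the same precision.

## Synthetic data

The generator reproduces the canonical simulation conditions: a 3.0 cm ∅ ×
2.3 cm cylinder (μ_a = 0.02, μ_s′ = 10 cm⁻¹); two or three cylindrical
targets of 3 or 4 mm diameter and 4 mm height at 50 mg/mL; target centres
uniform in ±10 mm (±8 mm for the mouse-geometry recipe); pairwise
edge-to-edge distances (EED) constrained to [0.3, 2.5] mm by rejection
sampling (10,000-attempt budget, failures raise); 24 views at 15° steps on
a 128² detector; truth rasterized to a 128×128×7 grid at 1 mm axial
resolution. Because the axial window of the 7 output slices is unreported,
it is centred at phantom mid-height and targets receive only ±1 mm axial
jitter so they always lie inside the slab.

Training projections are noise-free by default; zero-mean white Gaussian
noise at a stack-wide SNR (30/25/20/15 dB) is injected in evaluation
sweeps, matching how the noise study is described. Whether training data
should carry noise is unreported; a config flag (`snr_db` in `SampleSpec`)
enables noisy-training augmentation.

Per-sample max-normalization (projections and truth each divided by their
maximum) happens at load time, not on disk, so stored samples keep physical
units.

**Scaled-down study conditions.** CPU-sized runs use a 48×48×5 grid
(0.625 mm in-plane, 1 mm axial), 12 views at 30°, a 48² camera, a 0.2 cm
mesh (≈2.8k nodes), and axial jitter ±0.5 mm (so 4 mm targets fit the 5 mm
slab). These are first-class configurations, not test shortcuts; every
physical parameter (optics, targets, EED range, concentrations) is
unchanged.

## Classical reconstruction

All four baselines solve y = Wx with x ≥ 0 on the *support-restricted*
problem: voxel columns outside the cylinder are structurally zero and
detector rows without signal carry no information, so they are removed
before solving and the solution is embedded back. Before solving, y is
divided by its maximum and W by its spectral norm (power iteration). This
normalization is what makes the quoted step size and regularization weight
meaningful for this package's arbitrary photon-yield units; DICE and CNR
are invariant to it.

* **ADFISTA** — FISTA with nonnegative soft-threshold prox, gradient step
  0.01, and an adaptive stop (relative iterate change < 1e−6, cap 2000
  iterations; the original stopping rule is unreported, so this standard
  form is used). A safeguard halves the step and restarts momentum if the
  objective diverges, since stability at a fixed step depends on ‖W‖.
* **T-FISTA** — the same iteration with λ = 0.1 and exactly 300 iterations.
* **ADMLEM** — multiplicative MLEM under a Poisson model, 800 iterations;
  negative (noise-induced) measurements are clipped to zero with a warning;
  all-zero columns are frozen. The Poisson log-likelihood is monotone per
  iteration (tested).
* **MAP (GMRF) + ICD** — minimizes ‖Wx−y‖²/(2σ²) + (1/(2p²))Σ b(x_i−x_j)²
  over x ≥ 0 with a 6-connected neighbourhood (uniform b = 1/6), exact
  per-voxel coordinate-descent updates in fixed raster order, and
  closed-form re-estimation of σ² (mean squared residual) and p² (2×prior
  energy / n) after each sweep. The exact hyperparameter-estimation scheme
  of the cited literature is unreported; this standard alternating ML form
  is used. Because the hyperparameters move between sweeps, convergence is
  judged on the iterate, not on objectives computed under different (σ², p²).

On the scaled conditions the baselines behave as the qualitative literature
ordering suggests: MLEM produces compact but mislocalized blobs (DICE
≈ 0.4), the L1 methods produce sparse speckle whose half-max region
overlaps the 4 mm targets poorly, and alternating-GMRF MAP oversmooths.

## Deep reconstruction

The network maps the projection stack (views as the depth axis of a
single-channel 3D volume) to the 3D concentration volume: five (full scale)
convolutional encoder blocks [3D conv 3³ → batch norm → LeakyReLU(0.2) →
max pool], two fully connected layers (bottleneck 1024), and a mirrored
decoder of zero-insertion-upsampling + convolution blocks [→ BN → ReLU]
with optional channel-attention ("dual-sampling": parallel global
average/max descriptors through a shared 2-layer MLP gating the channels —
the cited module's exact structure is unpublished) and optional encoder
skip connections (trilinearly resized to the decoder stage and
concatenated). Pooling: (2,2,2) while the view axis stays even
(24→12→6→3), then (1,2,2); the decoder upsamples only spatially and holds
the output depth (7 full scale, 5 scaled) from the FC reshape onward, since
24 views and 7 slices are not power-of-two compatible.

The output activation is configurable. Full scale defaults to ReLU. The
scaled preset uses a sigmoid head with its bias initialized at the
sparse-background prior (−3): with targets occupying ~2% of the volume, a
final ReLU can die into the all-zero solution, which at small step budgets
is an inescapable optimum; the sigmoid head keeps gradients alive and its
range (0,1) matches max-normalized truth.

### Objective

For reconstruction x_r, truth x_t and their target-region crops x_r′, x_t′
(the bounding box of the per-sample ROI mask, grown to at least the 11 px
SSIM window):

  L = MSE(x_r, x_t) + MSE(x_r′, x_t′) + 2·[L_SSIM(x_r, x_t) + L_SSIM(x_r′, x_t′)]

with L_SSIM = 1 − MSSIM, MSSIM the mean over all positions of the
Gaussian-windowed (11×11, σ = 1.5, C₁ = 0.01², C₂ = 0.03² on unit dynamic
range) SSIM computed per axial slice — volumes are anisotropic (1 mm axial
vs sub-mm in-plane), so 2D windows per slice are the appropriate choice.
The window convolution is evaluated separably (two 1D passes), which is
exact for a Gaussian. MSE is implemented as the mean of squared
differences.

**Data augmentation.** The cylinder geometry admits exact symmetries:
rotating a scene by 90° equals cyclically shifting the view stack by a
quarter turn of views, and mirroring x → −x equals remapping view i to
(n/2 − i) mod n with the detector u axis flipped; the truth volume
transforms by the corresponding exact grid operation. Training can sample
the 8-element dihedral group per batch element (`augment_dihedral`, on in
the scaled preset), multiplying effective data diversity at zero simulation
cost. The augmented projections agree with fresh simulations to within the
FEM symmetry residual (few percent), the volumes exactly; on the scaled
study this raises held-out DICE by ~0.08.

Training: Adam; full-scale defaults batch 64, 200 epochs, initial LR 2e−5
halved after 5 epochs without validation improvement; best-validation
weights retained. `composite_from_epoch`/`composite_lr` define an optional
two-phase curriculum: the MSE terms alone drive the first epochs, then the
full composite takes over (optionally at a different learning rate). The
logged and validated loss is always the full composite. The curriculum
exists because the MSSIM of a mostly-empty volume is maximized by an
all-zero reconstruction unless the predicted targets are already accurate:
at CPU-scale step counts (a few hundred) the composite-from-scratch
objective collapses training into that flat optimum — measured here as
validation DICE pinned at 0 — whereas thousands of small steps over
thousands of samples (the full-scale regime, LR 2e−5) never visit it. The
scaled preset therefore runs an 8-epoch MSE warm-start at LR 1e−3 followed
by full-composite training at the method's own full-scale learning-rate
scale (2e−5), under which reconstruction quality is stable while the
composite objective keeps decreasing. The full-scale default trains the
composite from the first step.

All gradients come from the package's own reverse-mode autodiff engine
over numpy arrays; every operation's backward pass is verified against
central finite differences, and the composite loss gradient is checked to
1e−4 relative as an end-to-end identity.

### Scaled training conditions

Tests and the acceptance study train on 300 training / 50 validation
samples with `scaled_train_config()`: batch 8, 12 epochs — 8 MSE epochs at
LR 1e−3 followed by 4 full-composite epochs at 2e−5 — with dihedral
augmentation on (~1 s per step on one CPU, ~7 minutes total). On held-out
two-target scenes at 30 dB this reaches a mean DICE of ~0.44 against
T-FISTA's ~0.02, and the seed-0 study resolves the symmetric 1 mm-gap pair
into two half-max components — though that outcome sits at the resolution
limit of the 0.625 mm grid and is seed-sensitive. These sizes are the
package's chosen scaled-study conditions; the full-scale recipe (8000
samples split 6000/2000, batch 64, 200 epochs) is declared in
`full_scale_phantom_recipe()` and is what the published-scale numbers would
require (hours on data-centre GPUs).

## Evaluation

* **DICE** 2|ROI_r ∩ ROI_t|/(|ROI_r|+|ROI_t|), with ROI_r the region at or
  above a relative threshold (default half of maximum) of the
  max-normalized reconstruction — the binarization rule for continuous
  reconstructions is otherwise unreported; both-empty is defined as 1.
* **CNR** |μ_ROI − μ_BCK| / √(w_ROI σ²_ROI + w_BCK σ²_BCK) with
  volume-proportional weights; the background is every phantom-interior
  voxel outside the true target region.
* **Profiles** are trilinear samples of the normalized volume along a
  segment.
* Experiment recipes: resolution (EED 2.0/1.5/1.0 mm symmetric pairs),
  noise (30/25/20/15 dB), multi-target (three random targets), each
  emitting per-case CSV and aggregate JSON; aggregates are means over
  cases with per-case values retained.

## What the synthetic studies show — and what they do not

The generator and evaluator exercise the full physics chain, so passing
tests demonstrate: correct diffusion FEM against an analytic kernel,
exact operator/adjoint consistency, correct solver behaviour against
independent oracles (NNLS, Poisson likelihood), loss/metric identities,
and that — under matched scaled conditions — the trained network recovers
closely spaced targets better than the fixed-budget L1 baseline and
degrades gracefully with noise. They do not demonstrate performance on
real detector data: the simulator omits free-space optics, camera PSF and
EM gain, spectral effects, heterogeneous tissue, and any
simulation-to-measurement domain gap (the in vivo and physical-phantom
arms of the original study). Training and evaluation share the same
forward model (an "inverse crime" shared by all purely simulated studies
of this design), which flatters every method equally but especially
learned ones.

## Numerical choices and degenerate inputs

* Mesh tolerance: boundary-face centroids lie within one target edge of
  the analytic surface; degenerate tets (< 1e−12 cm³) abort meshing.
* FEM undershoot tolerance: fluence ≥ −1e−9·max for physical sources;
  weight-matrix undershoot ≈ −3e−3·max on the coarse test mesh.
* All-zero volumes: normalization returns them unchanged with a warning;
  DICE of two empty regions is 1; CNR with zero pooled variance is 0 for
  equal means and flagged +∞ otherwise.
* Noise at infinite SNR is the identity; the realized SNR is within
  ±0.5 dB of request on a 24×128×128 stack.
* Determinism: every random step (placement, noise, seeds of per-sample
  generation via `SeedSequence.spawn`, network init, batch shuffling) is
  seeded; repeated runs are bit-identical. The ICD sweep order is fixed
  raster order.

## Known limitations

* The orthographic Lambertian splat is a stand-in for unreported camera
  optics; absolute radiometry is meaningless, only relative images are
  used.
* The alternating GMRF hyperparameter estimation can oversmooth (a known
  pathology of joint ML estimation); the reference scheme is unreported.
* The scaled network uses three encoder blocks instead of five; the
  five-block full-scale network is constructible and shape-verified but
  not trainable in CPU-scale budgets.
* P1 FEM accuracy near point-like sources is limited (the physics oracle
  therefore compares at r ≥ 0.3 cm).
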