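# xlct

Simulation and reconstruction toolkit for **cone-beam X-ray luminescence
computed tomography (CB-XLCT)** — a hybrid modality in which a cone-beam
X-ray source excites luminescent nanophosphors (e.g. Y₂O₃:Eu³⁺) inside a
scattering object and a camera records the emitted light at the boundary
from many view angles. Reconstructing the 3D nanoparticle distribution from
those boundary images is a severely ill-posed inverse problem.

The package is written for researchers studying reconstruction algorithms
for diffuse optical/X-ray hybrid imaging. It provides, end to end:

* **Physics-based forward model** — Lambert–Beer cone-beam X-ray excitation
  `X(r) = X(r₀)·exp(−∫μ_t ds)`, emission `S = Γ·X·n`, light transport by the
  diffusion approximation `−∇·(D∇Φ) + μ_a Φ = S` with Robin boundary
  condition `Φ + 2κD(ν·∇Φ) = 0` solved with P1 finite elements on a
  tetrahedral cylinder mesh, and orthographic boundary-to-camera projection.
  The measurement operator `y = Wx` is assembled by reciprocity (one
  factorized solve per boundary node) and verified to machine precision
  against the direct forward chain.
* **Synthetic training data** — randomized two/three-cylindrical-target
  scenes (∅3–4 mm × 4 mm, 50 mg/mL, edge-to-edge distances 0.3–2.5 mm,
  centres within ±10 mm) with seeded, bit-reproducible generation; the
  full-scale recipe is 8000 samples of 24×128×128 projection stacks mapping
  to 128×128×7 volumes, split 6000/2000.
* **Four classical reconstructors** of
  `argmin_{x≥0} ‖Wx−y‖² + λ‖x‖_β`: adaptive-stop FISTA (step 0.01),
  fixed-budget T-FISTA (λ=0.1, 300 iterations), Poisson ADMLEM (800
  iterations), and GMRF-prior MAP minimized by voxel-wise iterative
  coordinate descent with alternating hyperparameter estimation.
* **A 3D encoder–decoder network** (conv/BN/LeakyReLU/pool encoder, 2-layer
  FC bottleneck, transposed-conv decoder with channel-attention
  "dual-sampling" gates and skip connections) trained with the composite
  objective

  `L = MSE(x_r,x_t) + MSE(x_r′,x_t′) + 2·[(1−MSSIM(x_r,x_t)) + (1−MSSIM(x_r′,x_t′))]`

  where the primed quantities are target-region crops and MSSIM is the mean
  Gaussian-windowed (11×11, σ=1.5) structural similarity per axial slice.
  The network runs on the package's own numpy reverse-mode autodiff engine
  (no GPU frameworks needed); every operation's gradient is
  finite-difference verified.
* **Evaluation** — DICE of the half-maximum region against the true targets,
  contrast-to-noise ratio with volume-proportional weights, line profiles,
  and experiment recipes (resolution sweep EED 2.0/1.5/1.0 mm, noise sweep
  30/25/20/15 dB, multi-target).

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices, and `examples/` for short narrative scripts, one per
capability.

## Worked example

`examples/04_train_network.py` generates a small scaled-scale dataset
(48×48×5 grid, 12 views), trains the network with the two-phase recipe (MSE
warm-start, then the full composite objective) plus exact symmetry
augmentation, and compares it with fixed-budget FISTA on held-out scenes:

```
dataset: 80 train / 20 val samples
epoch   1: train 4.1120 val 4.1812 lr 1.00e-03
...
epoch  10: train 4.0406 val 4.0689 lr 2.00e-05
training loss 4.112 -> 4.041; best validation 4.061
network  mean DICE over 5 held-out cases: 0.357  (per case: 0.24, 0.35, 0.47, 0.35, 0.38)
tfista   mean DICE over 5 held-out cases: 0.036  (per case: 0.02, 0.05, 0.04, 0.06, 0.01)
higher DICE = better overlap between the half-max region of the
reconstruction and the true targets
```

Even this miniature run (about four minutes on one CPU) shows the ordering
the method is built around: the learned reconstructor recovers target shape
far better than the fixed-budget L1 baseline, whose half-max region on this
diffuse problem is sparse speckle. The full scaled study in the test suite
(300 training samples, 12 epochs) reaches a mean held-out DICE of ~0.44 and
resolves two 4 mm targets separated by 1 mm into two distinct half-max
components.

## Command line

```bash
xlct simulate --preset scaled --n 100 --seed 7 --out data/
xlct build-weights --preset scaled --out W.npz
xlct reconstruct --method tfista --weights W.npz --proj stack.tif --out vol.nii.gz
xlct train --data data/ --out model.npz
xlct evaluate --recon vol.nii.gz --truth data/sample_00000.h5 --report report.json
xlct experiment --experiment resolution --methods tfista,network --model model.npz --out out/
```

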