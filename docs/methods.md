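# Methods

`legeit` implements a complete simulation-to-evaluation pipeline for
post-processing electrical impedance tomography (EIT) images of the human
lower leg: a parametric tissue phantom generator, a linearized 16-electrode
forward model, a hybrid total-variation (HTV) pre-reconstruction, and a
boundary-attention recurrent-residual U-Net (BAM-R2UNet) trained as a
conditional Wasserstein GAN with a six-term anatomy-prior loss.

## The inverse problem

EIT injects small currents through boundary electrodes and records the
resulting boundary voltages; the goal is the interior conductivity map
σ(x). The voltage–conductivity map is smooth, severely ill-posed and
nonlinear, so model-based reconstructions of a leg cross-section are
blurred and artifact-laden — boundaries between skin, fat, muscle and bone
smear out. The package's approach is two-stage: a physics-based
pre-reconstruction that preserves the measurement information, followed by
a learned image-to-image post-processor that restores anatomy.

## Phantom model

Phantoms are 64×64 maps (S/m) of a disc of radius R = 30 px (configurable;
the maximal disc leaving a margin for electrodes). Anatomy is concentric:
skin (1–3 px, 0.30–0.60 S/m), subcutaneous fat (5–10 px, 0.30–0.55 S/m),
muscle interior (0.80–1.20 S/m). Inside the muscle: an eccentric tibia
(cortical shell 0.05–0.15 S/m around cancellous bone 0.10–0.25 S/m), a
lateral fibula (cortical), 2–3 vessels (1.20–1.60 S/m), 1–2 nerve bundles
(0.08–0.20 S/m), and 0–3 pathologies — edema (≈0.80), tumor (≈0.30),
hematoma (≈0.15), near-insulating foreign bodies (≈0.01 S/m). Each
structure's geometry and conductivity are drawn per phantom from these
ranges with a per-phantom seed, so datasets are bit-reproducible. Values
are generated directly inside [0, 2] S/m; no post-hoc rescaling is applied.
Bone/vessel/anomaly radii (5–7 / 1–3 / 2–6 px) are package choices made so
each structure spans several pixels at 64×64.

The background outside the disc is a homogeneous 1.0 S/m reference medium;
it doubles as the linearization point of the forward model.

What the generator does *not* emulate: out-of-plane (3D) current
spreading, frequency-dependent tissue spectra, anatomical atlases,
electrode contact impedance, and correlated hardware noise. Passing tests
therefore demonstrate correctness of the method under the stated
two-dimensional, point-electrode, white-noise conditions, not clinical
performance.

## Forward model

A 2D finite-element discretization of the unit disc (linear triangles,
~700 elements, 64 boundary nodes) with point electrodes at 16 uniform
angular positions. The adjacent-adjacent protocol drives each neighbouring
electrode pair (1 mA nominal) and measures every neighbouring pair not
touching a driven electrode: 16 × 13 = 208 measurements in a frozen
drive-major order. Baseline voltages v0 and the sensitivity matrix J come
from one factorized solve of the homogeneous system; J uses the
adjoint-field identity (−∇u_d·∇u_m per element, mapped to pixels by
containing element, scaled by pixel area). Boundary voltages for a phantom
are then v = v0 + J(σ − σ_ref). The full nonlinear FEM re-solve is kept as
an independent test oracle; the linearization reproduces its voltage
changes within 10% for contrasts up to 5%.

Reciprocity of the discrete system (swap drive and measurement pairs)
holds to solver precision (~1e-15, asserted at 1e-6).

Measurement noise is zero-mean Gaussian, rescaled after drawing so the
realized ratio satisfies SNR = 10·lg(RMS(V)/RMS(N)) exactly. This
amplitude-ratio convention (factor 10, not the conventional power-form 20)
is deliberate and matches the stated noise model; `snr_convention="power"`
switches to the conventional form. Dataset noise tags cycle
clean/30/45/55 dB with sample index and are frozen at build time.

## HTV pre-reconstruction

The pre-reconstruction solves, in difference imaging form,

    min_x ‖Δv − J x‖² + α‖L x‖² + β‖x‖₁,

with L the diagonal Noser matrix (Jacobian column norms, equalizing the
center-vs-boundary sensitivity imbalance). The L1 term is smoothed to
√(x²+ε²), ε = 1e-4, and minimized by majorize–minimize IRLS; because both
regularizers are diagonal, each inner solve reduces via the Woodbury
identity to a 208×208 system, making a solve a few hundred ms. The MM
construction guarantees a non-increasing objective trace (asserted over
random cases). Iteration cap 30, relative-objective tolerance 1e-6;
non-convergence returns the best iterate with a flag. α = 3e-3 and
β = 3e-4 (β scaled by the mean squared column norm of J) were chosen once
by an L-curve/quality sweep on a held-out synthetic batch and frozen.
Outputs are mapped back to the 64×64 grid and clipped to [0, 2].

## Generator and critic

The generator is a four-stage encoder/decoder U-Net whose basic block
combines a recurrent first convolution — h₀ = Conv1(x),
h_i = Conv1(h_{i−1} + x), t = 2 shared-weight applications — a second 3×3
convolution, a boundary attention module, and a 1×1-projected residual
connection (applied unconditionally), all with batch norm and leaky
rectifier (slope 0.2). Stage widths are 32/64/128/256 with a 512-channel
bottleneck (dropout 0.1); the decoder mirrors with kernel-2/stride-2
transposed convolutions, skip concatenation and 1×1 fusion. The output
head is 3×3 conv → 1×1 conv → sigmoid × 2, confining outputs to [0, 2] at
any input resolution divisible by 16.

The boundary attention module (BAM) fuses three branches computed from the
same feature map:

- spatial: 1×1 reduction (ratio 8) → 3×3 depthwise → 3×3 dilated (rate 2)
  → 1×1 → sigmoid map Ms;
- channel: global average pool → bottleneck MLP (ratio 8) → sigmoid
  vector Mc;
- edge: per-channel (grouped) 3×3 convolution initialized to the Laplacian
  stencil and trainable, |response| thresholded at its per-channel mean,
  then sigmoid → map Me.

Fusion is BAM(x) = BN(α·x·(1+Ms)·Mc + β·x + γ·Me·x) with learnable scalars
initialized 0.5/0.3/0.2 (unconstrained — no simplex projection; the batch
norm sits on the fused sum). The adaptive threshold is
Me = sigmoid(|e| − mean(|e|)) with the mean per channel per sample. Each
branch can be disabled independently for ablations.

The bottleneck uses a single recurrent block by default
(`bottleneck_blocks=1`): with two 512-channel blocks the generator's
budget would be ~18 M parameters, whereas the reference budget for this
architecture family is ~12.6 M, which the single-block layout reproduces
(~13.0 M at base 32). Resolution-adapted configurations scale the base
width linearly with resolution (16/24/32/48 at 32/48/64/96 px), which
makes the parameter count grow ≈ quadratically with resolution
(3.3/7.3/13.0/29.2 M), and the multiply–add count is reported by direct
layer enumeration.

The critic is a conditional PatchGAN: the HTV image and the candidate
reconstruction are concatenated on channels and passed through five 4×4
convolutions (strides 2,2,2,2,1; widths 64→512→1; instance norm on the
middle layers; no output nonlinearity), giving a 3×3 score map at 64×64 —
each score judges a local patch conditioned on the input.

## Losses

Generator prior (weights 100/30/20/5/10/2):

- pixel: mean |ŷ−y| + 0.5 mean (ŷ−y)²;
- edge: mean L1 between Sobel gradient-magnitude maps
  (√(gx²+gy²+1e-8) for differentiability at zero);
- layer: Σ over four concentric rings |mean(ŷ·M_k) − mean(y·M_k)|, rings
  skin [R−3, R), fat [R−10, R−3), muscle [0.35R, R−10), core [0, 0.35R) —
  bounds chosen so the four masks partition the disc exactly;
- total variation: anisotropic forward differences, no wraparound;
- SSIM: 1 − mean SSIM over valid 11-tap Gaussian windows (σ = 1.5);
- histogram: L1 between ascending-sorted pixel vectors, per image.

All norms are mean-reduced per image and batch-averaged so the stated
weights remain scale-comparable across resolutions; `reduction="sum"`
recovers bare norms. The adversarial terms are the standard WGAN-GP forms:
critic loss E[D(x,G(x))] − E[D(x,y)] + 10·E[(‖∇_ŷ D(x,ŷ)‖−1)²] at uniform
convex interpolates, generator loss −E[D(x,G(x))] + L_total.

## Training

Adam (β₁ = 0.5, β₂ = 0.999), generator lr 1e-4, critic lr 4e-4, batch 16,
five critic updates per generator update, gradient clipping at global norm
1.0 for both models, cosine annealing of both learning rates to 1e-6 at
the final epoch, 120 epochs at full scale. Kaiming-normal init for the
generator (fusion scalars and Laplacian kernels keep their structured
init), N(0, 0.02) for the critic. Augmentation (right-angle rotations,
horizontal flips, σ = 0.01 Gaussian perturbation of the network input
only) is re-sampled every epoch with seeded draws. The checkpoint with the
best validation SSIM is retained; no early stopping. Runs are bit-exactly
reproducible under a fixed seed on one device.

## Numerical engine

The networks run on the package's own NumPy reverse-mode autodiff engine
(`legeit.autodiff`, `legeit.nn`): convolution is im2col + GEMM as a single
taped op that recomputes the patch matrix in its backward pass
(checkpointing), and every backward closure is itself built from engine
ops, so gradients are twice-differentiable — the gradient penalty's
parameter gradient differentiates through the critic's recorded backward
pass. First- and second-order gradients are verified against central
finite differences in float64. Float32 is used for training.

## Desk-scale problem sizes

CPU execution budgets the experiment sizes: the packaged scaled experiment
(`legeit.experiments.run_scaled_experiment`) trains the 32×32
resolution-adapted configuration at reduced width (base 8, critic base 16,
batch 8, 25 epochs, 224 samples, ~550 generator updates) and evaluates
held-out samples re-noised at 45 dB. All method-level settings (n_critic,
loss weights, optimizer family, schedules, noise model) are the reference
ones; the problem size shrinks, and the generator's initial learning rate
is raised to 3e-4 for the shortened schedule — the reference 1e-4 is
calibrated to a ~50× larger update count, and a cosine anneal from 3e-4
reaches the same 1e-6 floor while doing its productive learning within the
desk-scale budget. The critic keeps its reference rate. The acceptance script and test suite assert
the qualitative headline at this scale — the trained generator improves on
its own HTV input in mean SSIM and mean RMSE — rather than the
full-scale metric values, which require the 4800-sample, 120-epoch
configuration.

## Known limitations

- Point electrodes and a linearized forward map; no complete-electrode
  model or contact impedance.
- Difference imaging about a homogeneous reference; absolute imaging is
  out of scope.
- The desk-scale training demonstrates improvement over the
  pre-reconstruction, not the converged quality of a full-scale run.
- The phantom family is a single leg geometry with circular layers;
  generalization to other anatomies is untested by design.
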