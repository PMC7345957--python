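# Methods

`sctmorph` implements indirect multimodal registration: instead of
registering multi-contrast MR to CT directly — where no robust intensity
similarity exists — it synthesizes a CT-like volume (sCT) from the MR with
a conditional adversarial autoencoder, registers the sCT to the real CT
with a phase-based diffeomorphic deformable algorithm, and applies the
resulting displacement field to the original MR contrasts. Because the sCT
inherits the MR's geometry, the one field simultaneously registers the MR
to the CT and undoes whatever deformation corrupted the MR at acquisition
time.

## Synthesis model

The synthesis network has four subnetworks sharing one parameter set:

- **Encoder E.** Each of the three MR contrasts (fat, water, R2) passes
  through its own three-convolution stem before channel concatenation
  (late fusion); a symmetric down-sampling path with residual blocks maps
  the fused features to latent statistics (mu, delta), with
  delta = softplus(conv) kept non-negative.
- **Generator G.** Decodes a sampled latent z_bar = mu + delta * z through
  an up-sampling path mirrored against E, with same-resolution skip
  concatenations and residual blocks carrying dropout (rate 0.5, disabled
  at inference). "Deconvolution" is realized as nearest-neighbour 2x
  upsampling followed by a 3x3 convolution, which avoids checkerboard
  artifacts. All convolutions are Conv–InstanceNorm–ReLU; instance
  normalization suits per-image translation tasks.
- **Discriminator D / classifier C.** A shared convolutional trunk with two
  heads: a sigmoid real/fake probability and a softmax over the three head
  tissue classes (soft tissue, air, bone). C sees both real and synthetic
  patches; patch class labels are the majority tissue class of the
  reference label map under the patch. The trunk's first and last blocks
  skip normalization: the raw intensity scale is informative at the input,
  and instance norm over the near-singleton spatial extent of the deepest
  features would erase them (at 1x1 its output is exactly the bias),
  cutting the adversarial gradient to the generator.

The objective is `L_total = L_adv + lambda * L_l1` with `lambda = 100`:
non-saturating GAN binary cross-entropy plus the auxiliary 3-class
cross-entropy, and the mean absolute error against the reference CT. At
this weighting the training is close to supervised L1 regression with a
light adversarial sharpening term, which is what makes 200-step desk-scale
runs converge. No KL penalty is applied by default (`kl_weight = 0`,
config-exposed): the printed objective contains none, and we implement what
is printed while flagging the gap.

The network stack (reverse-mode autodiff, im2col convolutions, instance
norm, Adam) is implemented in numpy inside the package (`sctmorph.nn`) and
is 2D; volumes are synthesized patch-wise (default 16x16 patches, stride 8,
boundary-clamped) with overlaps averaged on recombination and latent noise
disabled (z_bar = mu), so inference is deterministic.

## Registration

Registration follows the Morphons family: local phase, not intensity, is
the matching signal, which buys invariance to affine intensity changes and
contrast inversions. A bank of K directional quadrature filters (K = 4 in
2D at 0/45/90/135 degrees, K = 6 in 3D along non-antipodal icosahedron
vertices) with a log-normal radial profile (center frequency rho0 = pi/3
rad/voxel, bandwidth 2 octaves) is applied in the frequency domain.

Each iteration at each pyramid level:

1. **Update.** For each filter k the complex cross-spectral product
   q_f conj(q_m) of fixed and warped-moving responses carries the local
   phase difference (angle) and the certainty c_k = A_f A_m (magnitude).
   The product is Gaussian-averaged (sigma_system = 2 voxels) — a circular
   average in which unrelated texture self-cancels rather than voting for
   zero displacement — and the per-voxel displacement solves the weighted
   least squares system min_u sum_k c_k (n_k . u - dphi_k/rho0)^2. The
   normal matrix is damped by 1e-6 tr(M) (relative conditioning) plus
   alpha * mean(tr(M)) (global damping, alpha = 0 by default), and voxels
   with negligible trace get zero update.
2. **Accumulation.** The update, weighted by c_u/(c_acc + c_u), is composed
   onto the accumulated field in the pull-back order
   new_d(x) = inc(x) + d_acc(x + inc(x)); certainty accumulates as
   (c_acc^2 + c_u^2)/(c_acc + c_u).
3. **Regularization.** Certainty-weighted normalized Gaussian convolution
   (sigma = 1.5 voxels) of the accumulated field. The certainty enters with
   exponent gamma = 0.25: the raw amplitude product spans orders of
   magnitude and would otherwise slave entire neighbourhoods to the nearest
   strong edge.
4. **Warping.** The moving image is re-warped with cubic spline
   interpolation (config `interp_order = 3`). Linear interpolation blurs
   the moving image in a displacement-dependent way, which biases the phase
   differences at edges and empirically caps warp-recovery accuracy around
   65–70% error reduction; cubic interpolation removes most of that bias
   (75–78% across seeds). The public `warp` default remains linear —
   monotone interpolation cannot ring when the field is later applied to
   salt-and-pepper-corrupted MR.

The loop runs 40 iterations per scale (or until the mean incremental step
drops below 5e-4 voxels) over a Gaussian pyramid (3 levels in 2D, 4 in 3D,
factor 2). The field lives in voxel units on the fixed grid; upsampling
between scales rescales the vectors. Diffeomorphism is diagnosed, not
enforced: `jacobian_determinant` reports det(I + grad d) and stays positive
on all phantom problems at default settings.

**Cross-modality preset.** A synthesized moving image shares its anatomy
with the real fixed image but not its fine texture. Matched-texture
defaults then over-fit the spurious interior signal; the
`RegistrationConfig.cross_modality()` preset (15 iterations,
sigma_regularize = 3, gamma = 0.5, alpha = 0.4) damps weakly supported
updates and is the pipeline default for the sCT-to-CT stage. On phantom
cases it recovers 25–45% of the mean ground-truth deformation inside the
head while never degrading it — conservative by design, since the field is
subsequently applied to the patient's MR.

## Evaluation metrics

- **Mutual information** from a 64-bin equal-width joint histogram, in
  bits; reported per MR contrast against the CT before and after
  registration.
- **SLPD**, the sum over voxels and filter directions of |sin(dphi_k)|.
  The magnitude of sin(dphi) is summed — signed values would cancel and
  contradict the lower-is-better reading — and the sum is not normalized,
  so values scale with image size.
- **MAE / Pearson CC** between sCT and real CT for synthesis fidelity.
- **Endpoint error** against ground truth is the mean magnitude of
  compose(true_field, recovered_field) over the head mask: the residual
  deformation the image still experiences. The zero-field baseline is the
  mean |true_field|, so "reduction" is the fraction of corruption undone.
  This formulation avoids explicit field inversion.

## Synthetic phantoms

No clinical data ships with the package; a seeded generator emulates paired
multi-contrast acquisitions. Each case is an ellipsoidal head — a bone
shell enclosing soft tissue with 2–3 embedded air cavities — rendered in
four modalities from one label map with deliberately inverted class
contrasts (bone bright on CT, dark on all MR; soft tissue bright on "fat",
dimmer on "water" and "R2"), per-class Gaussian noise (sigma 0.02) and a
smooth ±10% multiplicative bias field. The corrupted MR is the clean MR
warped by a random smooth diffeomorphic field (max amplitude 3 voxels,
smoothness 8 voxels, min Jacobian forced above 0.1 by amplitude halving)
plus 2% salt-and-pepper noise. All randomness flows from one integer seed
through named SeedSequence sub-streams.

What the phantom does *not* emulate: anatomical detail, MR physics
(sequence-dependent contrast, field inhomogeneity beyond a smooth bias),
CT beam hardening, partial-volume mixtures at boundaries, or resolution
anisotropy. Passing results demonstrate the machinery end to end —
synthesis fidelity on held-out geometry, sub-voxel recovery of known
fields, metric improvements from repair — not clinical performance.

## Study conditions and problem sizes

Phantoms are 64x64; the synthesis model trains on 16x16 patches (stride 8)
pooled from five clean, aligned training cases with seeds distinct from the
test case — the analogue of leave-one-out training on healthy subjects —
for 800 Adam steps (batch 8, lr 1e-3), reaching L1 ≈ 0.07 on unit-scale
intensities and held-out sCT correlation ≈ 0.92. The test case's sCT is
synthesized from its *corrupted* MR, the realistic input. The smoke test
for training dynamics uses 32 patch pairs and 200 steps, where the L1 loss
falls to ~10% of its first-step value and classifier accuracy saturates.

## Numerical choices and degenerate inputs

- FFT (periodic) filtering with no apodization; boundary artifacts carry
  low certainty and are further down-weighted by the certainty machinery.
- Normalized-convolution denominator guarded at 1e-8 x max(certainty);
  structureless regions output zero displacement.
- Phase differences are wrapped to (-pi, pi] by construction of arg().
- Displacement fields must be finite; volumes reject NaN/Inf intensities
  and non-positive spacings at construction.
- Patch recombination averages overlaps, except that voxels whose
  contributions all agree keep the exact value (bit-exact round trips).
- Probabilities in adversarial losses are clamped at 1e-7 before logs.
- Training aborts with a diagnostic on any non-finite loss.

## Known limitations

- The synthesis stack is 2D; 3D volumes are registered and warped natively,
  but synthesis operates on 2D lattices (or slices).
- Salt-and-pepper intensities are repaired only geometrically; no
  inpainting is applied by default (an optional median filter flag exists
  in the pipeline config, off by default).
- Diffeomorphism is diagnosed via the Jacobian determinant, not enforced
  by projection.
- The cross-modality registration preset trades sub-voxel accuracy for
  robustness; on matched-texture problems the default preset is roughly
  twice as accurate.
- Rigid/affine pre-alignment is out of scope; inputs are assumed globally
  aligned, as in same-subject acquisitions.
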