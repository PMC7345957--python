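# sctmorph

Synthetic-CT guided multimodal MR–CT deformable registration and repair.

## The problem

Deformable registration between multi-contrast MR and CT of the same
subject is hard because no robust intensity similarity exists across the
modalities — bone is bright on CT and dark on MR, soft-tissue contrast
inverts between sequences — and MR acquisitions may additionally arrive
geometrically corrupted (unknown deformation, impulse noise). `sctmorph`
sidesteps the multimodal similarity problem by making it monomodal:

1. **Synthesis.** A conditional adversarial autoencoder maps the three MR
   contrasts (fat, water, R2) to a synthetic CT (sCT). The model couples a
   variational encoder–generator pair E/G (latent sample
   `z̄ = μ + δ·z`, symmetric encoder–decoder with skip concatenations and
   residual blocks, late fusion of the contrasts) with a discriminator D
   and an auxiliary three-class tissue classifier C sharing one trunk. The
   objective is `L_total = L_adv + λ‖y − G(E(x))‖₁` with `λ = 100`.
2. **Registration.** The sCT is registered to the real CT with a
   phase-based diffeomorphic Morphons-style algorithm: directional
   quadrature filters measure local phase differences Δφ_k; per voxel the
   update solves `min_u Σ_k c_k (n̂_k·u − Δφ_k/ρ₀)²` with certainty
   weights `c_k = A_f A_m`; updates are accumulated by diffeomorphic
   composition `D₁ ⊕ D₂ = (Δ₁∘Δ₂) − Id` and regularized by
   certainty-weighted normalized Gaussian convolution, coarse to fine.
3. **Repair.** The resulting displacement field is applied unchanged to the
   original (corrupted) MR contrasts, registering them to the CT and
   undoing the acquisition-time deformation in the same step.

Alignment is scored with mutual information
`MI = Σ p(f,m) log₂ p(f,m)/(p(f)p(m))` and the sum of local phase
differences `SLPD = Σ_x Σ_k |sin Δφ_k|`; synthesis fidelity with MAE and
Pearson correlation. Since no clinical data ships with the package, a
seeded phantom generator produces paired multi-contrast head-like volumes
(soft tissue / air / bone) with known ground-truth deformation and
salt-and-pepper corruption. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
import numpy as np
from sctmorph import (PhantomSpec, generate_phantom, build_model, train,
                      TrainConfig, PipelineConfig, run_pipeline,
                      evaluate_case, training_patches)

# "other subjects": clean, aligned training cases
data = []
for s in (101, 102, 103, 104, 105):
    c = generate_phantom(PhantomSpec(shape=(64, 64), seed=s,
                                     deform_amplitude=0, sp_noise_fraction=0))
    data += training_patches(c.mr, c.ct, c.labels, 16, 8)
model = build_model(seed=7)
train(model, data, TrainConfig(steps=800, seed=7))

# held-out corrupted case: deformed + salt-and-pepper MR
case = generate_phantom(PhantomSpec(shape=(64, 64), seed=202))
result = run_pipeline(case.mr_corrupted, case.ct, model, PipelineConfig(seed=7))
report = evaluate_case(case, result)

m = result.metrics
print(f"sCT vs CT:  MAE={m['sct_mae']:.3f}  CC={m['sct_cc']:.3f}")
for n in ("fat", "water", "r2"):
    print(f"{n:5s}  MI {m[f'mi_ct_{n}_before']:.3f} -> {m[f'mi_ct_{n}_after']:.3f}"
          f"   SLPD {m[f'slpd_ct_{n}_before']:.0f} -> {m[f'slpd_ct_{n}_after']:.0f}")
e = report["endpoint_error"]
print(f"deformation undone: {100*e['reduction']:.0f}% "
      f"(residual {e['mean']:.2f} of {e['baseline_mean']:.2f} voxels)")
```

Output:

```
sCT vs CT:  MAE=0.123  CC=0.743
fat    MI 1.228 -> 1.401   SLPD 9622 -> 9350
water  MI 1.288 -> 1.425   SLPD 9515 -> 9282
r2     MI 1.170 -> 1.293   SLPD 9635 -> 9063
deformation undone: 36% (residual 0.55 of 0.87 voxels)
```

The MI of every registered contrast against the CT rises and the SLPD
falls: the field estimated on the sCT↔CT pair transfers to the MR it was
synthesized from. The sCT correlation here is computed against the
*aligned* CT, so it includes the deformation the pipeline then removes;
roughly a third of the mean ground-truth corruption inside the head is
undone by the deliberately conservative cross-modality registration preset.

A command-line surface wraps the same functionality:

```bash
sctmorph phantom --shape 64,64 --seed 7 --out case/
sctmorph register --fixed case/ct.nii --moving case/mr_corrupted_fat.nii \
                  --out field.nii --moved moved.nii
sctmorph evaluate --a case/ct.nii --b moved.nii --metrics mi,slpd,mae,cc
```

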