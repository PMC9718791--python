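# martian

Metal artifact reduction (MAR) for kilovoltage CT by **two-stage
adversarial image translation**, with a seeded synthetic paired-modality
phantom pipeline for development and testing.

## The problem

Metal implants produce streaks, dark bands and value bias in kV CT.
Supervised artifact-correction networks need (contaminated, artifact-free)
image pairs — which cannot be acquired: no artifact-free kV scan of an
implant patient exists. Radiotherapy workflows, however, often acquire a
second modality that barely sees metal artifacts: megavoltage (MV) CT,
where the photoelectric effect that drives metal's kV attenuation has
vanished. This package implements the two-network strategy built on that
observation:

* **Stage 1** translates MV slices into synthetic artifact-free kV slices
  (GAN; trained only on slices whose true kV max ≤ 3000 HU, i.e.
  metal-free),
* **post-processing** restores implants by intensity override (voxels
  where the measured kV > 3000 HU are copied in) and refines alignment
  with mono-modal deformable registration,
* **Stage 2** learns the actual artifact correction from (measured
  contaminated kV, refined synthetic kV) pairs, and is the only network
  used at inference.

Both generators minimize

    L = L_adv + 10 · [ (1/N) Σ |G(M_i) − K_i| + (1 − SSIM(G(M), K)) ]

with a residual no-skip generator (3 down / 8 residual / 3 up) and a
5-block sigmoid discriminator. Because the clinical cohort behind this
design is private, a synthetic generator produces paired studies — clean
kV ground truth, sinogram-domain metal-corrupted kV, and a deformed
low-contrast MV-like channel — that stand in for it. See
`docs/methods.md` for the full model description and its limitations.

The neural networks and their training run on a small numpy autodiff
engine included in the package (`martian.nn`), so everything works on a
plain CPU scientific Python stack; registration is backed by SimpleITK,
projection/reconstruction by scikit-image.

## Worked example

```bash
martian run --desk-scale --seed 0 --out run0
```

simulates 48 three-slice studies at 64×64, registers MV to kV, trains
both stages (10 epochs each), post-processes, and evaluates on held-out
studies — about 12 minutes on one CPU. The printed report (also in
`run0/evaluate/report.csv`) contains rows like:

```
mv_vs_kv             all       SSIM 0.6046  MAE    99.6 HU (n=30)
stage1_vs_kv         all       SSIM 0.6589  MAE   116.9 HU (n=30)
stage1_post_vs_kv    all       SSIM 0.7802  MAE    89.0 HU (n=30)
artifact_vs_kv       all       SSIM 0.9124  MAE    35.1 HU (n=30)
stage2_vs_kv         all       SSIM 0.7239  MAE   108.2 HU (n=30)
```

Reading it: the raw MV channel is far from the clean kV (low SSIM, low
contrast); stage-1 translation improves structural similarity; override +
refinement improve it further — the monotone ordering that motivates
using the refined output as stage-2 training targets. `artifact_vs_kv` is
the measured kV itself against the clean ground truth (perfect on
metal-free slices, degraded on artifact slices); `stage2_vs_kv` is the
corrected output. Per-category rows (`metal_free`, `metal_containing`,
`high_density_no_severe_artifact`) break the same comparisons down by
slice type. At desk scale (10 epochs, 16-channel networks) the stage-2
output's fidelity is limited by its training-target quality — clinical
conclusions require full-scale training.

Other entry points: `martian simulate`, `martian preprocess`,
`martian register`, `martian postprocess`, `martian evaluate` — each a
thin wrapper over the library (`martian.phantom_sim`, `martian.io_prep`,
`martian.registration`, `martian.postprocess`, `martian.evaluation`,
`martian.training`, `martian.pipeline`).

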