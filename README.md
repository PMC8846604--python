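# echostrain

Cardiac strain imaging from radio-frequency (RF) ultrasound: multi-level
2-D normalized-cross-correlation (NCC) block matching with **Bayesian
regularization of the correlation surfaces** — spatial (SBR), spatial-then-
temporal (STBR-1) and simultaneous spatiotemporal (STBR-2) — feeding a
Lagrangian myocardial strain pipeline, plus a synthetic RF speckle phantom
with analytic ground truth so the whole system can be validated without
animal or patient data.

It is written for researchers in ultrasound elastography who want a
reproducible, inspectable reference implementation of SMI-domain Bayesian
regularization and its effect on displacement and strain quality.

## The method

Block matching compares a kernel of pre-deformation RF data with candidate
windows of the post-deformation frame, producing a similarity-metric image
(SMI): the zero-normalized cross-correlation over integer (axial, lateral)
lags `u`.  Adding one and normalizing turns each SMI into a discrete prior
`Pr(u_x)` over displacements at block `x`.  Regularization multiplies this
prior by likelihoods built from the neighboring blocks' PDFs,

    Pr(u_x | u_N) ∝ Pr(u_x) · Π_{x' ∈ N} Pr(u_{x'} | u_x),
    Pr(u_{x'} | u_x) ∝ max_{v, |v − u| ≤ 3σ} Pr(v) · exp(−‖v − u‖²_σ / 2),

where the Gaussian width σ is coupled to the maximum expected strain through
the inter-block spacing (`σ_u = σ_ε × spacing`, the **strain regularization
sigma**).  The neighborhood `N` is the four adjacent blocks (SBR), the past
and future SMIs of the same block computed from a four-frame window
(temporal stage of STBR-1, width `σ_t`), or both at once (STBR-2).  The MAP
lag of the posterior, refined to sub-sample precision with a 2-D
windowed-sinc interpolant, is the displacement estimate.

Displacements are estimated coarse-to-fine over a decimation pyramid with
align-and-stretch companding between levels, median filtered, accumulated
along tracked material points from end-diastole, converted to the Lagrangian
strain tensor **E** by a least-squares affine fit of accumulated displacement
versus reference position, and rotated into wall coordinates to give radial
(`e_r = rᵀEr`) and longitudinal (`e_l = lᵀEl`) strain per mesh point, per
frame, and per wall segment.

Validation statistics: strain bias `E[ε_true − ε_est]`, normalized strain
error `Δε = Σ|ε_true − ε_est| / Σ|ε_true| × 100`, total temporal relative
error (TTR, the same ratio along segmental strain curves), the elastographic
SNR `SNR_e = μ/σ` of strain in a local mesh window, and the strain filter
`E(SNR_e | ε)`.

## A worked example

`examples/03_bayesian_regularization.py` tracks one frame pair of a beating
annular-wall phantom corrupted to 5 dB sonographic SNR:

```
NCC (no regularization) : wall median error   22.1 um, 95th pct  283.0 um
SBR                     : wall median error    7.2 um, 95th pct   23.6 um
```

The 95th-percentile error is the signature of correlation false peaks: at
5 dB roughly one block in twenty locks onto a noise peak several samples
away, and pooling each block's surface with its four neighbors' PDFs removes
nearly all of them (283 → 24 µm).  The other examples generate a calibrated
phantom (`01`), recover a rigid shift exactly (`02`), run the full
Lagrangian strain pipeline and print per-method TTR (`04`), and build a
strain filter (`05`).  Each example runs in seconds to a couple of minutes
and prints what the numbers mean.

A thin CLI mirrors the pipeline stages:

```bash
echostrain phantom --config scene.yaml --out seq.h5 --seed 1
echostrain track   --in seq.h5 --out disp.h5 --regularizer stbr2
echostrain strain  --in disp.h5 --mesh mesh.csv --out strain.h5
echostrain run     --config pipeline.yaml --out results/ --seed 1
```

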