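# Methods

## Scope and model overview

`echostrain` estimates myocardial displacement and Lagrangian strain from
sequences of 2-D RF ultrasound frames.  The processing chain is

1. **RF up-sampling** — 2-D windowed-sinc interpolation (Hann window,
   8-sample half-width), default factors 1 (axial) : 2 (lateral).
2. **Decimation pyramid** — per-level anti-aliased decimation
   (`scipy.signal.resample_poly`), default axial factors [3, 2, 1] and
   lateral [2, 1, 1], coarse → fine.
3. **2-D NCC block matching** — zero-normalized cross-correlation of a
   pre-frame kernel against the post frame over a per-level search range,
   yielding one similarity surface (SMI) per block.
4. **Bayesian regularization** (optional) — SMIs become PDFs (add one,
   normalize); the posterior at each block multiplies its prior by
   likelihoods from the spatial and/or temporal neighborhood.
5. **Sub-sample MAP** — integer argmax refined on a 0.01-lag grid of the
   2-D windowed-sinc interpolant.
6. **Companding** — the estimate is interpolated to the sample grid and the
   post frame re-aligned before the next finer level.
7. **Strain** — median filtering (5×5), Lagrangian accumulation on a
   transmural × arc mesh from end-diastole, least-squares strain tensor
   (0.5 mm × 1.0 mm kernel), rotation into wall coordinates, segmental
   curves over six equal arc segments.

## Assumptions

* Linear-array geometry: axial = depth (axis 0), lateral = A-line (axis 1);
  displacements are post-relative-to-pre, in samples/lines with exact mm
  conversions carried on every object.
* In-plane motion only; speckle moves with tissue; fully developed speckle.
* Smoothness: neighboring blocks differ in displacement by at most
  ~3·σ_ε·spacing; velocity varies smoothly across adjacent frames
  (the four-frame window gives each block past/present/future SMIs — the
  minimal temporal neighborhood).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| axial kernel lengths | 8, 5, 3 | wavelengths | long kernels stabilize coarse NCC; short ones preserve strain resolution at the finest level |
| lateral kernel lengths | 13, 11, 9 | A-lines | lateral speckle is broad; kernels must span several correlation lengths |
| search half-ranges | (10,5,2) ax, (5,4,3) lat | level samples/lines | must exceed residual inter-frame motion at each level |
| kernel overlap | 25% ax, 50% lat | % | sets block-grid density (and σ coupling) |
| σ_ε | 0.05 axial/lateral | strain | maximum expected *inter-frame* strain; σ_u = σ_ε × block spacing |
| σ_t | 0.1 axial/lateral | strain (coupled like σ_ε) or lags | temporal continuity width; see below |
| iterations | 1 | — | one pass; more passes widen the effective neighborhood and risk over-regularization |
| likelihood floor | 1e-12 | — | keeps log-domain products finite when a truncation window is empty |
| median filter | 5×5 | blocks | removes isolated false-peak outliers before accumulation |
| LS strain kernel | 0.5 × 1.0 | mm | neighborhood of the affine displacement fit |
| SNR_e window | 5 × 9 | mesh points (transmural × arc) | local μ/σ of strain |
| mesh | 2400 points (40 × 60) | — | spacing well below the LS kernel so every fit is over-determined |

**Choosing σ_t.** The temporal width trades continuity against responsiveness
to velocity change between consecutive frame pairs, so its optimum depends on
how finely the cycle is sampled: densely sampled cycles (hundreds of frames)
tolerate strong continuity (σ_t ≈ 0.01) while coarsely sampled ones need a
looser width (σ_t ≈ 0.1).  The default phantom cycle has 12 frames, so 0.1
is the default; both regimes are exposed in `RegularizationParams`, along
with a `coupling_mode` that either converts σ_t to lag units with the same
block-spacing rule as σ_ε (default) or takes it as lags directly.

## The synthetic phantom

The generator emulates what matters to NCC-based tracking:

* **Speckle** — uniformly placed point scatterers with N(0, 1) reflectivity,
  default 220/mm² (≥ 10 per PSF resolution cell → fully developed speckle),
  kept in a guard margin of two PSF widths beyond the field of view.
* **PSF** — separable: Gaussian envelope × cosine carrier axially (round-trip
  spatial frequency 2f₀/c), Gaussian laterally.  Defaults: 8 MHz center,
  78.84 MHz sampling, 50% fractional bandwidth, 0.15 mm lateral sigma,
  0.2 mm pitch.  The sampling rate keeps the carrier at 0.3 cycles/sample
  after the coarsest (÷3) decimation; lower rates alias the carrier away and
  make the coarse pyramid level unusable.  The lateral sigma is a realistic
  focused-array value; much broader PSFs make the lateral correlation peak
  wider than any reasonable search window and lateral displacement becomes
  unidentifiable regardless of the estimator.
* **Motion** — rigid shift, uniform strain ramp, or a cyclic annular wall
  that thickens radially and shortens along its arc with a sin(πf/T) time
  course, returning exactly to identity at cycle end.  Ground-truth
  displacement is the analytic map; ground-truth strain is its numerical
  symmetric gradient, so strain and displacement are consistent by
  construction.
* **Noise** — white Gaussian, variance calibrated so the reference-ROI
  signal/noise power ratio equals the requested sonographic SNR; a two-band
  variant applies different SNRs to the upper/lower halves of the frame to
  mimic depth-dependent attenuation.

What the phantom does **not** emulate: out-of-plane motion, anisotropic
fiber mechanics, phased-array/sector geometry, attenuation within a band,
reverberation or shadowing.  Passing tests therefore demonstrate the
estimator's behavior under controlled speckle decorrelation and additive
noise, not under every in vivo artifact; in vivo data typically *increases*
the advantage of temporal regularization because out-of-plane decorrelation
behaves like extra noise.

## Numerical choices

* **NCC** clips to [−1, 1]; zero-variance kernels or windows define the
  correlation as 0 at that lag and flag the block.
* **Sub-sample refinement** evaluates the separable Hann-windowed sinc
  interpolant on a 0.01-lag grid within ±1 lag of the integer peak.  The
  refinement window half-width is 4 lags: on the small truncated surfaces a
  search region provides, an 8-lag sinc is dominated by the asymmetric far
  tail of broad lateral peaks and biases the estimate by up to ~0.25 lines,
  while 4 taps track broad and narrow peaks to ≤ 0.05 lags (the RF
  up-sampler keeps the 8-sample half-width).  A peak value ≥ 1 − 1e−9 means
  the windows are bit-identical, so refinement is skipped — this is why
  noiseless integer translations are recovered exactly.  Boundary maxima are
  returned unrefined and flagged; flat surfaces return lag 0 with a
  degenerate flag.  Ties break to the lowest Euclidean lag magnitude, then
  the smallest axial lag.
* **Companding** rounds the bilinearly interpolated displacement to integer
  sample shifts: integer gathers introduce no resampling error, and the
  sub-sample remainder is recovered at the next level.  Because each block's
  residual SMI then has its own integer lag origin, the regularizers accept
  per-block *lag references* and shift neighbor likelihoods by the exact
  integer reference difference, so the smoothness prior always acts on total
  displacement rather than on the companding staircase.
* **Block grid** is inset by (kernel half-width + search) so every surface
  is computed on full windows; the outermost few blocks still overlap the
  frame-edge transients of the interpolation filters and are excluded from
  benchmark statistics (`EDGE_MARGIN_BLOCKS`).
* **Posteriors** accumulate in the log domain and renormalize to sum 1;
  updates are synchronous.  The likelihood truncation window is per-axis
  (|Δ| ≤ 3σ), matching the separable anisotropic Gaussian.  The truncation
  window is centered on the candidate lag (the defining inequality can be
  read as centered on either the candidate or the neighbor's variable; the
  candidate-centered reading keeps the likelihood a function on the
  candidate grid).
* **Degenerate inputs**: all-(−1) SMIs become uniform PDFs; missing temporal
  neighbors degrade STBR to SBR for that time (flagged at the pipeline
  level); mesh points leaving the displacement grid freeze and are excluded;
  LS fits with < 6 usable neighbors or rank-deficient neighborhoods are
  flagged; SNR_e points with σ below 1e−12 are excluded.
* **Strain measure** is infinitesimal (symmetric displacement gradient),
  matching the least-squares estimator lineage; a `finite=True` option adds
  the quadratic term for large deformations.

## Desk-scale problem sizes

All validation runs use deliberately small problems so the full suite runs
on one CPU in minutes: ~8–10 mm fields of view (≈ 820 × 48 RF samples),
12-frame cardiac cycles, 2400-point meshes, 10-seed medians for the noise
experiments.  These sizes were chosen once, from the physics (kernel sizes
in wavelengths, mesh spacing below the LS kernel, cycle sampling coarse
enough that temporal regularization is non-trivial), and are not tuned to
any particular outcome.  The noise-robustness conclusions are directional —
orderings of methods under identical conditions — not reproductions of any
full-scale study's absolute error values.

## Known limitations

* Lateral displacement precision is fundamentally coarser than axial (no
  lateral carrier); at very low SNR the lateral component dominates the
  error budget even after regularization.
* The cyclic-wall motion prescribes exact radial strain but its longitudinal
  strain varies slightly across the wall thickness (polar kinematics); the
  ground truth accounts for this by differentiating the actual map.
* A single temporal iteration only samples adjacent frame pairs; longer
  temporal contexts would require more than four input frames.
* The segment layout (six equal arc-length segments, base → apex → base)
  assumes an open-wall contour pair; closed contours are not supported.
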