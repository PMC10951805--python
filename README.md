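# col0rme

Super-resolution reconstruction for fluorescence-fluctuation microscopy:
sparse emitter localization in the covariance domain followed by
intensity and smooth-background estimation on the recovered support.

## The problem

Standard widefield or TIRF movies of blinking/fluctuating fluorophores
are diffraction-limited: each camera frame is a blurred (PSF Ψ),
down-sampled (q×q block binning S), background-contaminated and noisy
view of the underlying fluorophore distribution,

    y_t = S Ψ x_t + b + n_t ,   t = 1 … T,

with A = S∘Ψ mapping a q-times finer reconstruction grid (L×L, L = qM)
to the M×M camera grid. Because standard dyes blink *independently*,
the second-order temporal statistics of the movie carry sub-diffraction
information: the frame covariance satisfies

    R_y = A diag(x) Aᵀ + s I ,

where x ≥ 0 is the per-fine-pixel fluctuation variance (nonzero exactly
where emitters sit), the constant-in-time background cancels out, and
s = σ² is the variance of the (approximately Gaussian) noise. This
package is for microscopists and method developers who want
super-resolved maps *with real intensity values and an estimated
background* from ordinary blinking data — no special dyes or
single-molecule activation required.

## The method

**Step I — support estimation.** Solve, in the covariance domain,

    min_{x ≥ 0, s ≥ 0}  ½‖vec(R_y) − (A⊙A)x − s·vec(I)‖² + λ R(x)

by alternating a sparse solve in x with the closed-form noise update
s = max(0, trace(R_y − A diag(x)Aᵀ)/M²). Here A⊙A is the column-wise
Khatri–Rao product and R is CEL0 (continuous exact ℓ0 relaxation,
minimized by iteratively reweighted ℓ1 with FISTA inner solves), the ℓ1
norm (FISTA), or isotropic TV (Condat–Vũ primal–dual). λ is set as a
fraction γ of the closed-form λ_max (smallest λ giving an empty
support); for CEL0 an algorithmic-restart scheme re-initializes on
pixels adjacent to the current support to enrich it at fixed λ.

**Step II — intensity and background.** On the recovered support Ω, fit
the temporal mean frame ȳ by

    min_{x, b}  ½‖ȳ − A x − b‖² + μ‖∇_Ω x‖² + β‖∇b‖²  (+ soft constraints)

with ∇_Ω the 8-neighborhood gradient restricted to Ω and b a smooth
nonnegative background on the camera grid; nonnegativity and the
off-support constraint enter as ι-weighted quadratic penalties handled
by closed-form proximal maps. μ is chosen automatically by the
discrepancy principle: Newton iterations drive the residual
‖ȳ − A x(μ) − b(μ)‖² to the expected noise energy ν·M²·ŝ/T, with the
derivative dx/dμ obtained by differentiating the optimality conditions.

A self-contained simulator generates ground-truthed test data: filament
phantoms, two-state blinking with exponential dwell/bleach times,
Gaussian PSF, block binning, constant background, Poisson shot noise,
camera gain (quantum efficiency 0.7 × gain 6 = 4.2) and Gaussian read
noise, with low-background (LB) and high-background (HB, 2500
photons/pixel/frame) presets.

## Worked example

```python
from col0rme.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(
    preset="LB", coarse_size=8, q=4,
    regularizer="l1", gamma=0.05, mu=1.0,
    n_frames=500, seed=1,
))
print(report["effective"], report["metrics"])
```

prints (seed 1):

```
lambda        90223.7      # 0.05 x lambda_max = 1804474.4
noise_variance 1330392.6   # estimated Gaussian noise variance
support_size  329          # fine-grid pixels localized
jaccard_index 0.42         # tolerance sqrt(2) fine pixels (35.4 nm)
psnr_db       15.77        # intensity image vs ground truth
noise_variance_rel_error 0.024
```

The stack is a simulated 8×8-pixel, 500-frame LB acquisition; the
reconstruction lives on the 32×32 fine grid (q = 4, 25 nm pitch). The
Jaccard index counts one-to-one matched emitter pixels within the
8-neighborhood tolerance; the 2.4% noise-variance error shows the joint
(x, s) fit separating fluctuation signal from noise. One coarse pixel's
intensity equals the sum of its q² fine pixels.

The same pipeline runs from the shell:

```bash
col0rme simulate --preset HB --frames 500 --seed 1 --out data/
col0rme run --input data/stack.tif --reg l1 --gamma 0.05 --auto-mu --q 4 --out rec/
col0rme evaluate --est rec/support.csv --truth data/emitters.csv --tolerance-nm 35
```

Estimator classes (`SupportEstimator`, `IntensityEstimator`, `Col0rme`)
follow scikit-learn conventions (`fit`, fitted `*_` attributes,
`get_params`/`set_params`) and compose with sklearn tooling.

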