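# Methods

## Model

Frames `y_t ∈ R^{M×M}` are modeled as `y_t = S Ψ x_t + b + n_t`: PSF
convolution `Ψ` on the q-times-finer grid (L = qM), flux-conserving
q×q block binning `S`, a temporally constant but spatially smooth
background `b`, and i.i.d. zero-mean Gaussian noise of variance `s`.
The Gaussian noise term stands in for the camera read noise *plus* the
(signal-level-averaged) Poisson contribution; this approximation is
good when photon counts are moderately large and is the reason the
estimated `s` exceeds the pure read-noise variance by roughly
`gain² × mean photon count` on data with strong background.

Emitters sit at fine-pixel centers and blink independently, so the
frame covariance is `R_y = A diag(x) Aᵀ + s I` with `A = S∘Ψ` and `x`
the per-pixel fluctuation variance. Vectorized, the signal part is
`(A⊙A) x` with `A⊙A` the column-wise Kronecker (Khatri–Rao) product.
All vectorization is row-major; molecules, grids and kernels use
0-based indexing.

Key assumptions, in decreasing order of importance: (1) temporal
*stationarity* of the blinking statistics over the analyzed window;
(2) emitter independence; (3) constant-in-time background; (4)
spatially invariant Gaussian PSF. Violations of (1) — notably
photobleaching — are the dominant error source in practice (see
Limitations).

## Operators

Convolution uses reflective (Neumann) boundaries by default,
implemented as symmetric padding + FFT convolution; the adjoint is the
exact transpose (full correlation followed by fold-back of the
padding), so all adjoint identities hold to machine precision. A
periodic mode is available for speed; it makes all operator columns
translates of one another, so the column norms — which CEL0 and the
λ_max formulas need — degenerate to a constant.

The covariance-domain iterations only touch the operator through
`G = (AᵀA)^{∘2}` (the Khatri–Rao Gram), `c = (aᵢᵀ R_y aᵢ)ᵢ` and the
column norms `ηᵢ = ‖aᵢ‖²`. These are precomputed once per problem from
a cached dense `A` (M²×L²). We deliberately materialize `A` inside the
solvers: it is q² times *smaller* than the empirical covariance R_y
itself, so any problem whose covariance fits in memory affords it, and
the Gram turns every FISTA iteration into a single BLAS matvec. Size
guards (L² ≤ 16384 for `A`, ≤ 8200 for `G`) reject inputs that should
be cropped or tiled; the public operator API (forward, adjoint,
covariance lifting and its adjoint) remains matrix-free.

## Step I solvers

The alternation is: solve the regularized problem in `x` at fixed `s`,
then update `s = max(0, trace(R_y − A diag(x)Aᵀ)/M²)` (the closed-form
minimizer), until the joint objective changes by less than 1e-5
relative (at most 20 alternations). Inner solvers run to 1e-6 relative
objective change, at most 500 iterations. A monotone safeguard keeps
the previous iterate if an inner solve failed to decrease the joint
objective (relevant only for the truncated primal–dual TV iterations),
so objective traces are nonincreasing by construction, not by luck.

* **ℓ1**: FISTA with the nonnegative soft-threshold prox and restart on
  objective increase; step = 1/Lipschitz with the Lipschitz constant
  from a 50-step seeded power iteration on `G`.
* **CEL0**: iteratively reweighted ℓ1 (10 outer iterations, warm
  started); weights are the slope of the CEL0 branch at the current
  iterate, `ηᵢ√(2λ) − ηᵢ²|xᵢ|`, zero beyond the saturation point
  `√(2λ)/ηᵢ` — the standard majorize–minimize construction, so the
  CEL0 objective is nonincreasing across outer iterations.
* **TV**: isotropic TV with one-sided forward differences and Neumann
  boundaries, solved by a Condat–Vũ scheme (smooth fidelity by
  gradient, TV by dual ball projection, nonnegativity in the primal
  prox) with steps satisfying `1/τ − σ‖D‖² ≥ L_f/2`, `‖D‖² ≤ 8`. TV is
  provided for piecewise-constant scenes but excluded from
  localization claims: its supports are not pixel-precise, and support
  extraction uses a relative threshold (1e-2) instead of exact zeros.

`λ_max` uses the fidelity gradient at the origin (`s = 0`, the
initialization): `max c⁺` for nonnegative ℓ1 and `max (c⁺)²/(2η²)` for
CEL0. The zero-solution contract (`x(λ ≥ λ_max) = 0`) holds exactly
for the x-subproblem and is preserved by the full alternation because
the `s`-update only shrinks the gradient at the origin. Note that at
λ as large as 0.5·λ_max the *joint* alternation may still collapse to
`x = 0` (the noise term absorbs weak signal); the subproblem does not.
Tie-breaks in the λ_max argmax fall to the lowest index.

**Restarting (CEL0).** At fixed λ the solver is re-run with `x⁰`
placed on the pixels 8-adjacent to (but outside) the union support
found so far, at magnitude equal to the mean nonzero variance; the
final variance image is the elementwise maximum over restarts, the
support their union. Stops when a restart adds nothing or after 10
restarts (default). The adjacency re-initialization magnitude is our
documented choice.

## Step II

Alternate accelerated proximal-gradient solves in `x` (data + μ-smooth
term by gradient; ι-penalties by the closed-form prox: negative
entries shrink by 1/(1+2τι), off-support entries additionally by the
same factor) and in `b` (data + β-smooth term; one-sided quadratic
prox). Step sizes exclude ι by construction — that is the point of
keeping the penalties in the prox. Initialization `x⁰ = 0`,
`b⁰ = min(ȳ)` (a lower bound on the background). The support gradient
uses each unordered 8-neighbor pair once, weighted by the inverse
pixel distance; on the full grid the axial pairs reproduce the
standard forward-difference energy and the diagonal pairs complete the
isotropic stencil. The background gradient is the standard 2-point
forward difference with Neumann boundaries on the coarse grid. An
empty support degenerates gracefully to a background-only fit.

Defaults: `ι = 1e5 × max|ȳ|` (constraints effectively hard while the
prox stays well-conditioned), `β = 100` (background curvature strongly
penalized relative to the per-pixel misfit; configurable — any "large"
value gives a near-smooth background, which is the stated intent).
The data term is the unweighted squared norm; a noise-covariance
weighting would be a natural alternative but is not implemented.

## Parameter selection

λ is specified as `γ·λ_max`, `γ ∈ (0, 1]`. μ is selected by the
discrepancy principle: find μ with
`h(μ) = ‖ȳ − A x(μ) − b(μ)‖² − ν·E = 0`, where `E = M²·ŝ/T` is the
expected noise energy of the temporal mean and ν = 1 by default (the
Step-I estimate ŝ is precise enough not to need a safety margin).
Newton steps use `h′(μ) = −2 rᵀ A (dx/dμ)` with `dx/dμ` from the
quadratic problem obtained by differentiating the x-subproblem
optimality conditions at fixed background (curvature of the active
ι-penalties on the diagonal), solved by the same accelerated
proximal-gradient machinery. Safeguards: a log-spaced bracket scan
(both directions, up to 12 decades) around the heuristic start
`μ₀ = E/‖ȳ‖²`, geometric bisection whenever a Newton step leaves the
bracket or fails to reduce |h|. If `h > 0` for every μ — the support
cannot explain the data down to the noise level — the selection
reports the sampled curve in an error rather than returning a
meaningless μ; the pipeline then falls back to the best sampled μ.

## Synthetic data

The generator emulates a realistic blinking acquisition: spline
filament phantoms rasterized one fine pixel wide; emitters placed along
them at 10.7 emitters per camera pixel; 500 photons per fully-on
emitter per frame; continuous-time two-state blinking (exponential
dwells, means τ_on = 20 ms, τ_off = 40 ms) with an absorbing
exponential bleaching clock (mean 20 s), integrated to per-frame
on-fractions (a `binary_states` switch mimics simulators with discrete
per-frame states); 100 fps; Gaussian PSF of FWHM 229 nm (NA 1.4,
525 nm emission) on 100 nm camera pixels; constant background (LB
preset 50, HB preset 2500 photons/pixel/frame); Poisson shot noise;
camera conversion 0.7 (QE) × 6 (gain) = 4.2; additive Gaussian read
noise whose s.d. is derived, per stack, from a 16 dB signal-to-
Gaussian-noise ratio unless set explicitly. All randomness flows from
one seed; identical seeds give bit-identical stacks.

What the generator does *not* emulate: drift, vignetting, sCMOS
fixed-pattern noise, spatially varying PSFs, correlated emitters.
Passing tests on these data therefore demonstrate the estimator
mechanics (operators, optimization, selection rules), not robustness
to those real-data effects.

## Problem sizes and numerical choices

The test and reference problems use 4×4 to 16×16 camera grids with
q = 2–4 (fine grids up to 64×64) and 100–2000 frames — sizes chosen so
that every solver path, including the 20-point μ-grid comparisons and
10-seed repetition studies, runs in seconds to a couple of minutes.
Power iterations are seeded (50 steps, 2% safety margin on the
Lipschitz estimate); FISTA uses standard momentum with restart on
objective increase; IRL1 runs 10 warm-started outer iterations;
degenerate inputs (all-zero variance images, empty supports,
zero-emitter scenes) return well-defined results with warnings where
the spec of the quantity is vacuous.

## Limitations

* **Bleaching vs stationarity.** With the default 20 s bleaching time,
  windows beyond a few seconds are visibly nonstationary: all emitters
  share a downward intensity trend, which adds positive cross-emitter
  terms to the empirical covariance that the diagonal model
  `A diag(x) Aᵀ + sI` cannot represent. This biases the noise-variance
  estimate upward (tens of percent at 10 s windows on dense scenes)
  and can make localization *worse* with more frames. Short windows,
  slower bleaching, or detrending restore the model. The alternative
  convention of running the bleaching clock only during on-states
  (photophysically plausible, ~3× slower effective bleaching at 1/3
  duty) is not the default.
* **Scaled-down γ-robustness.** The flatness of final PSNR under
  underestimated λ relies on the support staying a superset of the
  truth; on desk-scale scenes the overestimation regime begins near
  γ ≈ 0.1, earlier than on full-size images.
* The quadratic cost in pixel count (M²×M² covariance) limits the
  method to modest fields of view; crop or tile larger inputs.
* Stable (Gale–Shapley) matching in the Jaccard index is deterministic
  but can drop a pair relative to the maximum-cardinality matching
  when preference chains conflict; tests pin this behavior.
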