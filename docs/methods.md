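# Methods

This note records the model as implemented, the numerical choices made
where the formulation is silent or where the literal formulation fails, and
what the synthetic tests do and do not establish.

## Model

Observed intensity is modelled in the log domain as
`J̃ = Ĩ + b̃ + n`: a piecewise-constant tissue image (value `c_i` on region
Ω_i), a smooth additive log-bias `b̃`, and zero-mean Gaussian noise with a
per-region variance `σ_i²`. For every pixel y, the pixels of its circular
neighbourhood `O_y` (truncated Gaussian window ω; σ = 4 px, radius
r = 15 px, i.e. a 31×31 mask with cells beyond Euclidean distance r set to
exactly zero, normalised to unit sum) are classified by MAP: Gaussian
likelihood `N(c_i + b̃(y), σ_i²)` times a spatial prior `p_i(y)`. Summing
the window cost over all centres gives a double-sum energy; the partition
is represented by one level-set function (N = 2) or two (N = 3, 4), with
the length term ν·L and distance regulariser μ·R added per function.

Minimisation is coordinate descent: `c_i`, `σ_i`, `b̃`, `p_i` have
closed-form minimisers (window-weighted means/variances/fractions,
implemented as ratios of convolutions), and φ follows the explicit-Euler
gradient flow driven by evidence fields `e_i(x)` — the window-integrated
MAP cost of assigning x to region i. One iteration is: update (c, σ);
one φ step; update b̃; update p.

## Parameters

| parameter | default | meaning / units |
|---|---|---|
| `kernel_sigma`, `kernel_radius` | 4, 15 px | window width and truncation radius; set the scale below which the bias is allowed to vary and above which structures must vary |
| `epsilon` | 1 px | arctan-Heaviside/delta smoothing width in the flow |
| `dt` | 0.1 | Euler step of the gradient flow |
| `mu` | 1.0 | signed-distance regulariser weight |
| `nu` | 0.001·255² | contour-length weight, **8-bit intensity scale** (see below) |
| `c0` | 2 | amplitude of the binary-step initialisation |
| `intensity_floor` | 1.0 | raw intensities below this are excluded from the log transform (label 0, zero weight in all window sums) |
| `bias_warmup` | 100 iters | b̃ held at 0 before closed-form bias updates begin |
| `max_iterations`, `stable_iterations` | 500, 10 | stop when the hard label map is unchanged for 10 consecutive post-warm-up iterations *and* the bias update has settled (max change < 1e-4), or at the budget |
| variance floor | 1e-3 log units | lower bound on σ_i (noise-free degenerate regions) |
| prior floor | 1e-6 | lower bound on p_i before logs |

### The ν scale

ν = 0.001·255² stems from energies whose data term is an unnormalised
squared intensity difference, i.e. O(255²) per pixel. Here the data term
is σ-normalised — `(J̃−b̃−c_i)²/2σ_i²` is O(1–10) — so that value
over-weights the length term by orders of magnitude and contracts any
contour to a point regardless of image content (verified on phantoms at
every contrast tried). The same 0.001·range² rule applied to the O(5)
log-intensity range gives ν ≲ 1; `nu=1.0` is the package's recommendation
for log-domain work and is what all recovery results use. The config
default keeps the 8-bit-scale constant for compatibility.

## Numerical choices

* **Memberships in the statistics.** The region memberships are defined as
  indicator functions of the partition; the smoothed Heaviside `H_ε` is an
  approximation introduced so the variational derivative of the flow
  exists. This implementation keeps that division of labour: the
  closed-form updates and the energy use the exact indicators of the
  current sign pattern, while `H_ε`/`δ_ε` appear only in the flow. The
  reason is quantitative: `H_ε` with ε = 1 at the binary init |φ| = 2
  equals 0.85/0.15, and the arctan tails decay only as 1/(πx), so every
  region's statistics would mix in ~15% of its complement. The variance
  updates are the casualty — σ estimates inflate to the between-region
  spread (~0.4–0.65 log units instead of ~0.06), the evidence contrast
  collapses, and the contour dies against the length term. With indicator
  statistics the estimates are consistent and recovery is exact. The
  smoothed convention remains available
  (`statistics_memberships="smoothed"`); in that self-consistent setting
  the full objective decreases monotonically across iterations (tested),
  but segmentation quality is poor for the reason above.
* **Bias warm-up.** Updating b̃ while the partition is still wrong lets the
  window-ratio bias absorb the residuals of mislabelled pixels; the
  evidence cliff at the true boundary is then permanently blurred and the
  fit settles in a "fat region" equilibrium (inflated σ plus a bias bump
  holding a 1–2 px halo). Holding b̃ = 0 for `bias_warmup` iterations lets
  the contour lock onto the raw intensity evidence first — tissue contrast
  (~1 log unit) dominates bias variation (~0.5) — after which the bias
  converges to the true field. Defaults to 100; recovery runs use 200.
* **Convolutions.** All window sums are FFT convolutions (zero padding);
  ratio-form statistics therefore renormalise themselves at image borders
  and around masked pixels, whose fields are zeroed on both numerator and
  denominator sides. FFT round-off (~1e-12) is far inside the 1e-8
  agreement the brute-force oracle tests demand.
* **Discretisation.** Central differences with replicate boundaries for
  gradients and curvature (gradient-magnitude guard 1e-10), 5-point
  Laplacian, unit pixel area, no CFL adaptation, no reinitialisation ever
  (the μ term alone maintains |∇φ| ≈ 1 near the zero set — tested).
* **Hard labels.** Output labels are argmax over exact memberships, ties
  to the lowest region index; excluded pixels carry label 0.
* **Gauge.** E is invariant under b̃ → b̃+κ, c_i → c_i−κ. The optimisation
  runs unnormalised; results are reported with b̃ normalised to zero mean
  over the valid mask and constants shifted oppositely, so `exp(c_i)` is
  on the raw intensity scale and `exp(b̃)` has mean ≈ 1.
* **Degenerate regions.** A region whose window mass vanishes keeps its
  previous constants/σ with a warning; prior and variance floors keep the
  logs and divisions finite.

## Synthetic phantoms

The generator composes a piecewise-constant image (discs, rectangles,
annuli over a background), a smooth positive bias field with mean exactly
1, and Gaussian noise under three formation models: `J = I·b + n`,
`J = (I+n)·b`, and `log J = log I + log b + n`. "±40%" bias means
min = 0.6·max. `noise_sd` is in the units of the domain where the noise
enters; the default recovery phantoms use the log-additive model with
sd 10/127.5 ≈ 0.078 log units — the equivalent of sd 10 at 8-bit
mid-scale, since d(log J) = dJ/J.

Default recovery worlds: a single disc (constants 60/180) and three discs
plus background (40/100/160/220), 128×128, ±40% quadratic bias. Disc radii
are 13–14 px, at the window scale, for an identifiability reason spelled
out below. Seeds are placed inside each object (`suggest_seeds`), matching
the manual near-object initialisation the method expects on real images.

### What a green recovery test establishes — and what it does not

The log-additive phantom satisfies the model assumptions exactly
(homoscedastic log-noise, additive log-bias), so recovery there tests the
estimator, not robustness. The multiplicative-noise models are
deliberately mismatched (their log-noise is heteroscedastic, varying with
I·b); the fit still finds the regions but boundary accuracy and bias
correlation degrade — tests cover them as mismatch probes, not as
headline numbers. None of the phantoms have anatomy-like texture, partial
volume effects, or non-Gaussian noise.

### Identifiability and the window scale

The bias field in this model is constrained only by window averaging: any
structure wider than the window diameter can be explained equally well as
"bias". For objects much wider than 31 px the absorbed solution (one
region, bias mimicking the object) attains *lower* energy than the true
segmentation, and no schedule rescues it — this is a property of the
model class, not a bug. Usable scale separation is
bias scale ≫ window ≳ structure scale; the kernel radius is the knob to
move when your objects are larger.

## Known limitations

* Global per-region σ_i: spatially varying noise (e.g. multiplicative
  noise after log transform) is not represented.
* Explicit Euler with the δ_ε throttle makes contours crawl when far from
  their targets — hundreds of iterations for tens of pixels; initialise
  near the objects.
* At most four regions (two level-set functions); 2-D only.
* The MAP spatial prior, being a window fraction, systematically
  disfavours regions thinner than the window; very thin structures
  segment with reduced overlap.
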