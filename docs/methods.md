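# Methods

## Model

`rrwm` models delayed-estimation performance as the outcome of a
cost-minimizing allocation of encoding precision. Precision is quantified
as Fisher information J of the encoded circular feature; a memory error
ε follows a Von Mises distribution whose concentration κ satisfies
J = κ·I₁(κ)/I₀(κ). Precision fluctuates across items and trials:
J ~ Gamma with mean J̄ and scale τ (shape J̄/τ), so τ→0 recovers equal
precision, and at fixed J̄ larger τ raises the kurtosis of the predicted
error distribution more than its variance. The predicted error density is
the Von Mises marginalized over this gamma.

For a "local" task (the response depends only on the probed item) the
expected total cost of a display with probing probabilities p₁…p_N is

    C(J̄₁…J̄_N) = Σᵢ pᵢ·c̄(J̄ᵢ; τ) + λ·Σᵢ J̄ᵢ,

where c̄(J̄; τ) = ∫c(ε)·p(ε; J̄, τ)dε is the expected behavioral cost of
reporting an item encoded at mean precision J̄, and the second term is the
expected neural cost, linear in invested precision (unit coefficient α is
fixed to 1; only the ratio λ/α is identifiable). The sum separates over
items, so the optimal allocation solves one scalar problem per item:

    J̄_opt(p) = argmin_J̄  p·c̄(J̄; τ) + λ·J̄.

Set size enters only through the probing probability (p = 1/N in equal-
probability designs); incentive weights uᵢ enter through the item
relevance rᵢ = uᵢpᵢ, which takes the place of pᵢ everywhere.

Behavioral cost families: the default power law |ε|^β (free exponent
β > 0); the parameter-free |ε|, ε², and −cos ε; a binary-feedback cost
(0 below a feedback threshold θ_fb, 1 above — evaluated exactly through
the Von Mises CDF, never by quadrature across the discontinuity); and a
two-parameter saturating family c(ε; s, γ) = 1 − exp(−(|ε|/s)^γ). The
saturating form is this package's own choice of a smooth error-to-cost
map that rises like a power law and saturates at 1; any other
cost(|ε|; a, b) can be plugged in through the same interface.

### Regimes and thresholds

The probing-probability axis splits into at most three regimes: below p₀
the optimum is J̄ = 0 (not encoding at all), between p₀ and p∞ it is
finite and increasing, above p∞ the objective decreases without bound
(in practice only when λ = 0, since every implemented cost is bounded).
From the boundary first-order condition, p₀ = λ/|c̄′(0)| and
p∞ = λ/|c̄′(∞)|.

Two facts about c̄′(0) matter numerically:

* On the equal-precision branch, κ ≈ √(2J) at small J makes c̄′(0)
  diverge, so p₀ = 0: it is never optimal to leave an item unencoded.
  The finite-difference derivative detects this divergence by its growth
  rate (magnitude growing ≥2× per decade of step shrinkage, or exceeding
  10⁸), not by a fixed magnitude cut alone.
* With precision variability the 50-bin discretized c̄ is artificially
  flat at the origin (every equal-probability quantile of a gamma with
  shape → 0 collapses to 0), so finite differences of the discretized
  model cannot estimate c̄′(0). The implementation instead uses the
  analytic continuous-mixture limit
  c̄′(0) = (1/τ)∫(E[c|J] − c₀)e^(−J/τ)dJ/J, evaluated by generalized
  Gauss–Laguerre quadrature (weight x^(−1/2)e^(−x), 96 nodes).
  The ratio-form threshold then agrees with a direct bisection probe of
  the optimizer to ~5% relative; the residual is the 50-bin
  discretization bias of the likelihood approximation, not an optimizer
  error. Note that with variability the expected cost is *not* globally
  concave-in-benefit: |c̄′| first rises over an onset region near J̄ = 0
  and only then diminishes. This violation of diminishing returns at the
  origin is exactly what allows p₀ > 0 for the variable-precision family
  (threshold values around 0.02–0.15 at fitted-scale parameters); at
  τ = 10⁻³ it leaves a small but real threshold of order λ√τ.

### Alternative allocation policies

Besides the rational policy the package implements, behind one display
interface: a fixed total divided equally; a power law in set size
J̄ = J₁·N^(−a); allocation proportional to probing probability
(pᵢ·J̄_total); optimal division of a *fixed* total (solved by
water-filling: bisection on the shared multiplier with per-item inversion
of rᵢ|c̄′(J)| restricted to the decreasing branch past the onset peak);
and a nonparametric table with one free J̄ per condition.

## Numerics

* κ↔J mapping: Newton iterations on the Bessel-ratio identity with
  dJ/dκ = κ(1 − r²), r = I₁/I₀, started from the exact small- and
  large-J asymptotics; relative tolerance ~1e−12, vectorized and
  overflow-safe via exponentially scaled Bessels.
* Predicted densities use the 50-bin equal-probability discretization of
  the gamma (central quantiles at levels (i−½)/50); 50 vs 500 bins moves
  densities by <1e−3. τ below 1e−6 switches to a point mass.
* Expected costs: trapezoid rule on [0, π] with 2,000 points, doubled by
  symmetry (the periodic trapezoid rule, spectrally accurate for smooth
  integrands). Cached fast paths used inside fitting tabulate
  E[c(ε)|κ] over log κ (built with 256-node Gauss–Legendre, which
  handles the |ε|^β endpoint singularity better than the trapezoid rule)
  and gamma quantiles over log shape; both tables are accurate to ~1e−5
  relative, far below any fit's statistical resolution.
* Per-item optimization: a 200-point log-grid scan over J̄ ∈ [1e−6, 1e5]
  with explicit comparison against the J̄ = 0 boundary (ties go to 0),
  refined either by a bounded search on the exact quadrature (public
  default) or by parabolic interpolation of the grid (fast path used
  during fitting, within ~1% of exact). A minimum still descending at
  the upper window edge is flagged unbounded.

## Fitting

The likelihood of a trial is the predicted error density at the probed
item's J̄, resolved per condition by the model variant (memoized over the
few unique probing probabilities per design). Maximum likelihood uses a
coarse log-space grid over the free parameters (β, λ, τ, or the
variant's J̄_total/J₁/a) followed by Nelder-Mead from the best grid
points, with positive parameters fitted in log space. The nonparametric
variant exploits that conditions decouple given τ: an outer
one-dimensional search over τ with exact inner per-condition fits. Model
comparison reports AIC (2k − 2 log L; the nonparametric variant counts
one parameter per condition plus τ) and interleaved five-fold
cross-validation: fold k holds out trials k, k+5, k+10, … in 1-based
presentation order, refits on the remaining 80% (adding the full-data
estimate as one extra optimization start), and sums held-out log
likelihoods. Comparison tables report the subject mean ± s.e.m. of
AIC_ref − AIC_alt (negative favors the reference model) and of
cv_ref − cv_alt (positive favors the reference model).

## Synthetic data

The generator draws trial tables from the same generative chain the
likelihood assumes: allocate J̄ per item under a chosen policy, pick the
probed item with probability proportional to pᵢ (items with pᵢ = 0 are
never probed), draw J from the gamma, draw ε from the Von Mises. Nine
built-in designs mirror classic delayed-estimation layouts (equal-
probability designs at set sizes up to 8; a 3:1 cueing design; two
cue-validity designs specified directly by their unique probed-item
probabilities, since the likelihood depends on the display only through
the probed item's p). Defaults of hundreds of trials per condition match
the scale of the original experiments. What the generator does *not*
emulate: response-device artifacts, swap/non-target reports, sequential
dependencies, lapses. Passing recovery tests therefore show that the
pipeline is consistent and identifiable under the model's own
assumptions, not that real data are free of these extra processes.

Recovery settings chosen for the harness: parameter recovery uses the
equal-probability eight-set-size design with 375 trials/condition
(n = 3,000) at fitted-scale generator values (β = 0.61, λ = 8.8e−3,
τ = 7.4). Model recovery uses the 3:1 cueing design (unequal p is
required: with equal probabilities the proportional policy is
mathematically identical to the fixed-equal policy) with 300
trials/condition and a power-law generator exponent a = 1.5 — away from
a = 1, where the power law collapses onto the fixed-total model and the
two are not identifiable even in principle.

## Change detection (global task)

For whole-display change detection the behavioral cost is the error
probability of a Bayes-optimal observer and the objective
R·p(error|J̄) + λ·ΣJ̄ couples all items (R is the reward per correct
trial; only R/λ matters). Each item is measured in both displays with
independent Von Mises noise at precision Jᵢ, so the observed change
δᵢ follows the VM-difference density
I₀(κ√(2+2cos δ))/(2π I₀(κ)²) under "no change" and is uniform under a
change at that item; the optimal rule reports "change" iff
(1/N)Σᵢ(1/2π)/f(δᵢ) > 1. Unencoded items contribute exactly 1 to the
rule and are treated analytically. This two-measurement observer is the
standard optimal-observer construction for the task family and is the
variant that reproduces the encode-nothing/encode-one/encode-both
regime pattern at rewards 0.05/0.20/0.35 with λ = 0.01.

p(error) is computed by deterministic quadrature wherever tractable —
any allocation at N = 2 (a midpoint product rule reduced to sorted
suffix sums), and single-encoded-item allocations at any N — because
regime boundaries sit within ~1e−4 of each other in objective value,
below Monte Carlo resolution at the default 2×10⁵ samples. Remaining
cases use Monte Carlo with common random numbers (one fixed uniform
array pushed through each candidate's inverse CDF; change trials on a
fixed half of the sample with the changed item cycling
deterministically). Optimization searches (K, J) under the conjecture
that all encoded items share one precision; at N = 2 a dense quadrant
grid search is available as an audit and confirms the conjecture
(optima are equal-entry or one-zero) across the reward range.

## Known limitations and documented regimes

* At (λ = 0.01, β = 2, τ↓0) the total invested resource N·J̄_opt(1/N)
  *increases* monotonically over N = 1..8 (J̄_opt ≈ √(p/λ) in this
  regime, so the total grows like √N); the non-monotonic total with an
  interior peak appears at fitted-scale parameters (small β, large τ,
  small λ), e.g. N_peak = 3 at (β = 0.106, λ = 3.2e−3, τ = 8.2) and
  N_peak = 4 at (β = 0.356, λ = 5.8e−3, τ = 18.1).
* At (λ = 0.08, τ = 30) with the binary-feedback cost and p = 1/5, the
  predicted expected |error| stays at π/2 for extreme feedback
  thresholds and is nearly flat in between — investment is never
  clearly worthwhile at this probing probability, consistent with the
  interpretation that threshold manipulations of this strength produce
  no measurable precision effect.
* Problem sizes in the test suite (3,000 trials per synthetic subject
  for parameter recovery, 20 simulated subjects per generator for model
  recovery, 900 trials per subject in the cueing design) were chosen as
  the scale of the original experiments.
* Subject-level fitting only; no hierarchical pooling. Encoding is
  assumed unbiased; no swap errors; no sensory-input precision ceiling
  or hard resource cap.
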