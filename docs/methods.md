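# Methods

## Model

A test of `k` polytomous items is observed; item `i` has ordered
categories `0..m_i`. Scores are assumed conditionally independent given
a scalar latent trait Θ, with adjacent-category odds

    P(Y_i = a | θ) / P(Y_i = a−1 | θ) = exp{α_i (θ − δ_ia)},

the generalized partial credit model: α_i is the item's scaling
(discrimination) and δ_ia the threshold at which categories a−1 and a
are equally likely. Integrating Θ out over an *unspecified* population
density, the marginal probability of a full score pattern y in a
subpopulation defined by a finite pattern set B has the closed form

    P(Y = y | B) = τ_B exp{β'x̃ + K(α'ỹ)},

where x̃ stacks per-item category indicators minus those of a reference
pattern y0, ỹ_i = y_i − y0_i, β_is = −α_i Σ_{a≤s} δ_ia, and K is the
conditional cumulant-generating function (CGF) of Θ given Y = y0,
truncated at an even order v:

    K(u) = Σ_{r=1}^{v} λ_r u^r / r!.

For r ≤ v−1 the λ_r are the conditional cumulants of Θ given y0; λ_v is
a Lagrange-remainder coefficient, not a cumulant. The only
distributional assumption is thus a finite truncation order — latent
skewness and kurtosis are estimated, and misspecification of a latent
density cannot bias the item parameters.

## Convexity constraints

A CGF is convex, so K″(u) = Σ λ_{c+2} u^c / c! must be non-negative on
the whole line. This holds iff v−2 = 2q is even and K″ is a sum of two
squared polynomials, K″ = p1² + p2², with deg p1 = q and
deg p2 ∈ {q−1, q}. Writing p1 = ε1't, p2 = ε2't in the power basis, the
coefficients of K″ are the convolution sums

    h_c = Σ_{j+j'=c} (ε1_j ε1_j' + ε2_j ε2_j'),   λ_{c+2} = c!·h_c,

and the ε's are the free shape parameters. The constraint is
*structural*: any ε value yields a valid convex CGF, so the optimizer
is unconstrained and every solution is "proper" (consistent with a real
random variable; all moment inequalities hold automatically).

Identification: λ1 = 0 (location), λ2 = 1 (scale, enforced by fixing
the constant terms (ε10, ε20) on the unit circle, default (3/5, 4/5)
with (1/√2, 1/√2) available), and the latent direction by Σ α_i ≥ 0
(flipping θ → −θ maps α → −α, ε_j → (−1)^j ε_j and leaves the
likelihood unchanged). The default deg p2 = q−1 is the parsimonious
choice; deg p2 = q adds one shape parameter. Free-parameter count:
Σm_i + k + q + deg p2. At v = 2 both polynomials are constants
(deg p2 = max(q−1, 0) = 0), there are no free shape parameters, and the
model is the conditionally normal GPCM with linear homoscedastic
posterior (EAP = u, posterior variance 1).

## Estimation

Given pattern frequencies n_y, the multinomial log-likelihood is

    l = n ln τ_B + β'ñ + Σ_y n_y K(α'ỹ),   ñ = Σ_y n_y x̃_y,

computed entirely in log space (log-sum-exp for ln τ_B; log weights in
the bundled example span ±17). The support B defaults to the observed
set O, so the normalizer has at most as many addends as there are
distinct patterns regardless of the number of items; the full product
space is available for small designs.

The gradient is analytic: for β it is the exponential-family "observed
minus expected" sufficient-statistic difference; for α and the free ε
it follows by the chain rule through K′(u) and the h-convolutions, and
is cross-validated against central finite differences in the test
suite. Optimization is quasi-Newton BFGS from the always-feasible
normal start (β = 0, α = 1, ε free = 0), gradient tolerance 1e−6, with
cold restarts (a fresh Hessian approximation from the stopping point)
when the line search stalls on ill-conditioned sub-problems; restarts
never change the answer when the first run already converged, they only
rescue stalled runs.

On concavity: the log-likelihood is log-concave in the natural
coordinates — (β, λ) enter the log weights linearly, so at fixed α the
usual exponential-family argument applies, and the maximized value is
unique (confirmed here by multi-restart tests). Note that concavity is
a statement about (β, λ, α), not about the auxiliary ε coordinates: the
quadratic ε → λ map curves the parameterization, so the likelihood need
not be concave along straight ε segments even though its maximum value
is unaffected. This matters only for interpreting optimizer
diagnostics, not for the estimates.

Standard errors invert a dedicated observed-information matrix: central
finite differences of the analytic gradient (relative step 1e−5),
symmetrized, with a singularity check that reports the approximate null
direction (useful for under-identified toy designs such as a single
dichotomous item, where β and α act only through β + K(α)). The
optimizer's internal Hessian approximation is deliberately not used —
it accumulates update noise. Interpretable item parameters are
back-transformed (δ_i1 = −β_i1/α_i, δ_is = (β_i,s−1 − β_is)/α_i,
ω_is = −β_is/(s α_i); λ_r = (r−2)! h_{r−2}) with delta-method standard
errors via a numerical Jacobian (central step 1e−6 relative) against
the full free-parameter covariance.

## Person and population quantities

The conditional MGF of Θ given any pattern y is a tilt of the
reference-pattern MGF, so the conditional cumulants are derivative
evaluations of the fitted CGF: κ_j|y = K^(j)(α'ỹ). The EAP person
score is κ_1|y = K′(u) — strictly increasing in u because K″ > 0 — and
the posterior variance κ_2|y = K″(u) ≥ 0 by construction. Cumulants of
order above v are zero under the truncated CGF.

Population moments of Θ in B follow from the law of total expectation:
conditional non-central moments (standard cumulant-to-moment
conversions) are averaged over patterns, weighted by the *fitted* model
probabilities P̂(y|B) — the plug-in MLE; observed-frequency weighting is
available for sensitivity analysis. Converting the pooled non-central
moments back to cumulants uses the standard identities; for the fourth
cumulant a non-standard variant replacing −3(μ′2)² by −3(μ′2)³ is kept
behind `kappa4="cubed"` (`--as-printed`) solely for comparability with
outputs computed that way; the default is the standard identity.

## Goodness of fit

The split-sample LR test randomly assigns *patterns* (not persons) to
two disjoint halves O1, O2, refits on each half with its own observed
support, and refers

    LR = 2[(l̂1 + n1 ln(n1/n)) + (l̂2 + n2 ln(n2/n)) − l̂]

to chi-squared with df = (free parameters) + 1. Each half is refitted
with its own most frequent pattern as reference; the maximized
log-likelihood is invariant to that choice (tested). Nested LR
comparisons against the nominal-response generalization — unrestricted
per-category scalings η_is in the CGF argument, recovering the partial
credit structure at η_is = α_i·s — use df = Σm_i − k.

## Synthetic data

The generative simulator draws θ per person from a pluggable density —
normal(μ, σ), a two-component normal mixture, or a shifted gamma
standardized to mean 0 and variance 1 (skewness 2/√shape) — then item
scores independently from the adjacent-category model, consuming one
seeded stream in person-major order for bitwise reproducibility.
Non-normal shapes are included because the whole point of the
distribution-free fit is robustness to them. Pattern-level sampling
from a fitted model is a single multinomial draw over the support,
which is the exact generative process *conditional on B* and therefore
the right oracle for parameter-recovery tests; it does not exercise
patterns outside B, so recovery tests say nothing about support
misspecification. The simulator emulates complete responses only — no
missingness, no local dependence, no multidimensionality — so passing
recovery tests demonstrate correctness of the estimator under the
model, not robustness to violations of it.

## Test-suite problem sizes and numerical choices

The bundled worked example (85 patterns, n = 493, 28 parameters) fits
in well under a second; suite-level simulations use a k=3 design with
27 patterns (n = 20,000 for recovery and information checks; 40
replicates at n = 2,000 for the chi-squared calibration of the split
LR, whose mean is checked within 25% of df — the Monte-Carlo slack at
that replicate count), and n = 50,000 for the large-sample recovery of
the example model. Factorials are exact integers up to v; polynomial
evaluation uses Horner's scheme; pattern ordering is lexicographic
everywhere so normalizer sums are reproducible term-for-term.

## Limitations

- Odd truncation orders and positive-semidefinite moment-matrix
  formulations of non-negativity are not supported (sum-of-two-squares
  covers the univariate case exactly).
- The association-parameter generalizations other than the
  nominal-response model, Pearson/saturated-model tests, multigroup,
  multidimensional and longitudinal extensions are out of scope.
- Missing item scores are rejected, not imputed.
- Standard errors rest on a finite-difference Hessian; like any
  numerical information matrix they degrade near identification
  boundaries (e.g. α_i → 0, where thresholds are undefined).
- With the parsimonious second polynomial (deg p2 = q−1) the shape
  class is anchored at the fixed (ε10, ε20); the full-degree choice
  deg p2 = q is closed under rotations of (p1, p2) and is the safer
  option when comparing fits across different reference patterns.
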