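# Methods

## Model class and likelihood

`fracinfo` works with mean-and-covariance structure models for p
observed variables: a parameter vector θ (length q) maps to implied
moments μ(θ) and Σ(θ). Three families are built in.

* **Saturated** (`make_saturated_model`): θ = (μ, vech Σ), q = p + p(p+1)/2,
  zero degrees of freedom. This is the "h1"/unstructured model.
* **Regression path model** (`make_regression_model`): bivariate
  Y = α + βX + E with θ = (μ_X, φ_X, α, β, ψ). It has q = 5 = number of
  moments, so it is a saturated *re*parametrization — but β is a genuine
  parameter with its own FMI, which is the point of keeping the path
  form rather than deriving β from saturated moments.
* **Simple-structure CFA** (`make_cfa_model`, `make_two_factor_model`):
  Σ(θ) = ΛΦΛ' + Θ with each indicator loading on one factor, Θ diagonal,
  μ free. Identification is std.lv: latent variances fixed at 1, so all
  loadings are free and the off-diagonals of Φ are factor correlations.

Data are assumed multivariate normal with an ignorable (MCAR/MAR)
missingness mechanism. Under those assumptions the observed-data
log-likelihood is the sum of per-case marginal normal densities over
each case's observed subvector. The package groups cases by missingness
pattern g and stores per-pattern sufficient statistics (n_g, x̄_g, S_g
with ML divisor n_g), giving the algebraically identical form

    logL = Σ_g n_g [ −(p_g/2) log 2π − ½ log|Σ_g(θ)|
                     − ½ tr(Σ_g(θ)⁻¹ (S_g + d_g d_g')) ],   d_g = x̄_g − μ_g(θ).

One likelihood evaluation costs O(#patterns · p³) independent of N,
which is what makes the N = 10⁶ pseudo-population fits routine.
All-missing rows contribute nothing to the likelihood and are dropped
with a warning and a count.

**FIML fitting** maximizes this by L-BFGS-B on an internally transformed
scale (log for variances, atanh for factor correlations), with the
objective scaled per case so tolerances are sample-size independent. The
fit is declared converged when the numeric per-case gradient max-norm at
the optimum is ≤ 1e-5; anything else is reported as `converged=False`
(never an exception), so simulation harnesses can count failures.
Starting values come from the EM solution of the saturated model mapped
to the structured parameters — exact moment inversion for the
regression model; loadings from square roots of average within-block
covariances, correlations from cross-block averages, with neutral
fallbacks (loading 0.5, correlation 0.3) when the moments give no usable
signal.

**Saturated EM** estimates the unstructured (μ, Σ). The E-step is
written against the pattern sufficient statistics (the conditional
expectations of the missing sums are linear in the observed ones), so an
iteration also costs O(#patterns · p³). Iteration stops when the maximum
absolute change in (μ, Σ) is ≤ 1e-10 (cap 10,000 iterations); the
per-iteration log-likelihood trace is retained and is non-decreasing. A
log-likelihood-based stopping rule is deliberately *not* used by
default: near the optimum the log-likelihood is flat to machine
precision while the moments can still be ~1e-5 away, and that residual
error is exactly what breaks the three-variant identity for saturated
models. With complete data EM returns the sample moments in one step.

## The three FMI variants

For parameter j, FMI is δ_j = 1 − (J_X⁻¹)_jj/(J_Y⁻¹)_jj, where J_Y is
the observed-data information and J_X the (hypothetical) complete-data
information, both q×q and on the total-sample scale. Missing
information J_{X|Y} = J_X − J_Y is never formed explicitly. All
standard errors are "observed-information" standard errors — with MAR
data the expected-information alternative is inconsistent, and mixing
the two types in one ratio is what historically produced wildly negative
FMI estimates.

The three variants differ in how the information pair is constructed:

* **delta1 (numeric Hessian).** J_Y is the negative central-difference
  Hessian of the observed-data log-likelihood at θ̂, on the untransformed
  parameter scale (FMI is defined for the reported parameters, not for
  the optimizer's internal scale). J_X is the negative Hessian of the
  complete-data log-likelihood of a pseudo-sample of size N whose sample
  moments are fixed at the implied moments μ(θ̂), Σ(θ̂).
* **delta2 (analytic, structured).** The dominant analytic term:
  J = Δ(θ̂)' G Δ(θ̂), where Δ is the Jacobian of the stacked moments
  (μ, vech Σ) with respect to θ and G is the unstructured ("h1")
  observed information in moment coordinates, evaluated at the implied
  moments. The term involving second derivatives of the model map is
  dropped; it vanishes at the optimum of a correctly specified model.
* **delta3 (analytic, unstructured).** Same sandwich, but every
  moment-dependent part of the computation — the h1 weights on the
  observed side and both the pseudo-sample moments and the h1 weights on
  the complete side — uses the EM (saturated) estimates instead of the
  implied moments. Δ stays at θ̂: the model Jacobian is a function of
  the structured parameters, and there is no unstructured analogue of
  it. (The alternative reading, which would also move Δ, has no defined
  meaning for a structured model; this choice was made once and is noted
  here rather than asserted as the only possible reading.)

The **h1 information** G is accumulated analytically per pattern. With
Ω = Σ_g⁻¹, d = x̄_g − μ_g, A = S_g + dd' and D the duplication matrix of
the pattern:

    mean block            n_g Ω
    mean–cov cross block  n_g (d'Ω ⊗ Ω) D
    cov block             ½ n_g D'[(ΩAΩ ⊗ Ω) + (Ω ⊗ ΩAΩ) − (Ω ⊗ Ω)]D

each embedded into the full (μ, vech Σ) coordinates through the
pattern's selection map. The *normative definition*, enforced by the
test suite on randomized incomplete datasets, is that G equals the
negative numeric Hessian of the saturated observed-data log-likelihood
at the same moments; the formulas above are the exact fast path. At the
complete-data MLE the cross block vanishes and the blocks reduce to the
familiar N Σ̂⁻¹ and ½N D'(Σ̂⁻¹ ⊗ Σ̂⁻¹)D.

vech is lower-triangular, column-major, diagonal included, everywhere.
Model Jacobians use central differences with step 1e-5·max(1, |θ_j|)
(validated by step-halving); Hessians use step 1e-4·max(1, |θ_j|) with a
four-point cross stencil and symmetrization. For the saturated model the
Jacobian is the identity and is returned exactly.

**Validity classification.** If either information matrix fails a
positive-definiteness check, every parameter of that variant is reported
`undefined` (matching the NA accounting of the simulation harness) —
matrices are never pseudo-inverted. A finite-sample δ̂_j < 0 is retained
for diagnostics but flagged `negative`; WIF is reported only for
`ok` parameters (δ ∈ [0, 1)). Truncating negatives to zero would bias
Monte-Carlo summaries, so it is never done.

## Simulated designs

The generators reproduce two study populations:

* **Regression**: X ~ N(0,1), Y = 0.4·X + E, Var(E) = 1 − 0.4² = 0.84
  (so σ_E = 0.92 and Var(Y) = 1).
* **Two-factor**: two factors correlated at φ = 0.4, four indicators
  each, all loadings λ = 0.49, error variances 1 − λ² = 0.7599 so every
  indicator has unit variance. The generation statement "indicators,
  factors and errors standard normal" cannot hold simultaneously with
  λ = 0.49; unit *indicator* variance is the reading adopted (errors
  N(0, 1 − λ²)), which reproduces the published population FMIs of both
  the loading and the factor correlation, whereas unit *error* variance
  does not.

Missingness is organized in **blocks** that share one Bernoulli draw per
case. In the regression design the single block is {X}, conditioned on
the fully observed Y. In the two-factor design the blocks are {X2, X4}
(driven by C_X = X1 + X3) and {Y2, Y4} (driven by C_Y = Y1 + Y3): the
two incomplete indicators of a factor are jointly missing or jointly
observed, while the two blocks are conditionally independent. The
block-shared draw is a deliberate design decision: an exact
expected-information computation over all missingness masks shows that
independent per-variable draws would give loading population FMIs of
0.23/0.45/0.65 at rates 0.2/0.4/0.6 under MCAR, while block-shared draws
give 0.20/0.40/0.60 — and the latter, together with the matching factor
correlation and MAR values, is the regime the published study numbers
describe.

Mechanisms: under MCAR each block is missing with probability π_mis.
Under MAR the conditioning sum is standardized by its *theoretical*
population SD (1 for Y; √(2 + 2λ²) for C_X, C_Y), making it exactly
standard normal, and compared with percentile cutoffs derived from
π_c = (π_mis − π₁)/(π₂ − π₁) with π₁ = 0.9, π₂ = 0.1:

* linear MAR: cutoff Φ⁻¹(π_c); miss w.p. π₁ above, π₂ below;
* nonlinear MAR: cutoffs ±Φ⁻¹(0.5 + 0.5π_c); π₁ outside, π₂ inside.

Both satisfy π₁(1 − π_c) + π₂ π_c = π_mis exactly, so the marginal
missing rate is the target by construction (rates 0.2/0.4/0.6 give
linear cutoffs 1.15/0.32/−0.32 and nonlinear cutoffs
±1.53/±0.89/±0.49). Conditioning variables are never given missingness
— that would make the mechanism MNAR — and the simulator enforces this.
Each dataset derives generation and missingness from disjoint substreams
of one master seed, so mechanisms can be swapped on identical complete
data.

What the generator does **not** emulate: non-normal data, MNAR or weak
(more probabilistic) MAR mechanisms, missingness on conditioning
variables, and item-level idiosyncrasies of real questionnaires.
Passing tests therefore certify the estimators under the normal-MAR
regime in which their theory lives, not robustness beyond it.

## Monte-Carlo harness and evaluation criteria

Pseudo-population FMIs are computed from a single N = 1,000,000
simulated sample per cell; the three variants must agree within 0.005
there (they do, as theory predicts for a true model), and the
unstructured values are used as δ_pop. Per condition (model × mechanism
× rate × N), `run_condition` executes n_rep replications (seed =
base_seed + replicate index, so results are independent of execution
order), computes all three FMI variants, and summarizes over the
`ok` replicates only:

* raw bias: mean(δ̂) − δ_pop;
* RMSE: √(mean (δ̂ − δ_pop)²);
* 95% ETI width: the distance between the 2.5th and 97.5th
  linear-interpolation quantiles of the δ̂ draws.

Failure taxonomy: a non-converged fit marks the whole replicate
`undefined`; a converged fit with non-positive-definite information
marks that variant `undefined`; a converged fit with δ̂ < 0 is
`negative`. Counts of each category are reported next to the summaries.

Problem sizes used by the shipped tests and the acceptance script:
population cells at N = 10⁶ (one dataset per cell, shared across
checks), and 300 replications for the finite-sample cell
(N = 500, MCAR, rate 0.2) — enough for RMSE/ETI to be stable to well
within the comparison tolerances while keeping the default suite fast.

## Known limitations

* Only simple-structure CFA is supported (no latent regressions,
  residual covariances, or multi-group models); identification is
  std.lv only.
* No robust/sandwich standard errors, no expected-information option,
  no multiple-imputation FMI, and no bootstrap uncertainty for the FMI
  estimates themselves.
* The atanh transform keeps each factor correlation in (−1, 1) but does
  not enforce joint positive definiteness of Φ for models with three or
  more factors; inadmissible trial points are absorbed by the
  optimizer's penalty path instead.
* Numeric Hessians (delta1) are the slowest component for large q; the
  analytic variants are exact and orders of magnitude faster, which is
  one reason delta3 is attractive in simulation work.
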