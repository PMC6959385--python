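# Methods

## Model

The package studies the perturbed underdamped Langevin dynamics

    dq = M⁻¹p dt − μ J₁ ∇V(q) dt,
    dp = −∇V(q) dt − ν J₂ M⁻¹p dt − Γ M⁻¹p dt + √(2Γ) dW,

with symmetric positive definite mass M and friction Γ, antisymmetric J₁, J₂
and scalar strengths μ, ν. The perturbation drift is divergence-free with
respect to the Gibbs measure π̂ ∝ exp(−V(q) − ½p·M⁻¹p), so π̂ is invariant for
every (μ, ν, J₁, J₂); what changes is the *nonequilibrium character* of the
dynamics and with it the statistical efficiency of time averages.

Efficiency is measured by the asymptotic variance σ²_f: the time average
π_T(f) satisfies √T(π_T(f) − π(f)) → N(0, 2σ²_f). Equivalently σ²_f is the
one-sided integral of the stationary autocovariance of f along the dynamics.
All conversions in the package (replicate scaling, autocorrelation
integration) use this convention consistently; it is fixed by the exactly
solvable cases below (e.g. σ² = γ for f(q) = q in one dimension).

## Exact theory for Gaussian targets

For V(q) = ½q·Sq the dynamics is the OU process dX = −BX dt + √(2Q) dW̄ with

    B = [[μJ₁S, −M⁻¹], [S, (Γ + νJ₂)M⁻¹]],   Q = blockdiag(0, Γ),

and stationary covariance Σ∞ = blockdiag(S⁻¹, M); the Lyapunov identity
BΣ∞ + Σ∞Bᵀ = 2Q holds identically for all admissible parameters and is
asserted on construction. For a quadratic observable f(q) = q·Kq + l·q + c the
Poisson equation −𝓛χ = f − π(f) has the quadratic solution
χ(x) = x·Cx + D·x + const with

    BᵀC + CB = K̄,    BᵀD = l̄,
    σ²_f = 2 Tr(C Σ∞ K̄ Σ∞) + D·Σ∞ l̄,

K̄ = blockdiag(K, 0), l̄ = (l, 0). **Side convention.** Substituting χ into the
generator 𝓛 = −Bx·∇ + ∇ᵀQ∇ produces the Sylvester equation with Bᵀ acting on
the left as written above (one sometimes sees the transposed variant
BC + CBᵀ = K̄; for symmetric C the variance formula is insensitive to the
transposition, but the substitution-derived form is the one that satisfies the
generator identity, which we enforce by a finite-difference oracle in the
tests and by the hand-solved one-dimensional cases σ²(q) = γ,
σ²(q²) = γ + 1/γ). Constant terms balance automatically through
2 Tr(QC) = Tr(K̄Σ∞), a consequence of the Lyapunov identity; observables are
centered internally so the constant c never influences σ².

The Sylvester equation is solved by `scipy.linalg.solve_sylvester`
(Bartels–Stewart); solvability requires min Re σ(B) > 0, checked with margin
1e−12. Residuals above 1e−8 (relative) raise rather than warn.

### Curvature at zero

In the unit-covariance equal-perturbation setting (S = M = I, Γ = γI,
J₁ = J₂ = J, μ = ν) the derivative ∂σ²/∂μ vanishes at μ = 0 and

    ∂²μ σ²|₀ = (−2γ³ + 4γ)|Jl|² + (γ − 4/γ³ − γ³ − 1/γ)(Tr(JKJK) − Tr(J²K²)).

Since Tr(JKJK) − Tr(J²K²) = ½Tr([J,K]²) ≥ 0, the curvature is strictly
negative for γ > √2 whenever [J, K] ≠ 0 or Jl ≠ 0: the reversible sampler is a
local *maximum* of the asymptotic variance. For γ ≤ √2 the formula is still
evaluated but no sign claim is made. The implementation cross-checks the
closed form against five-point finite differences of the Sylvester route.

### Spectra

Under the same setting the drift spectrum has the closed form
σ(B) = {μλ ± √((γ/2)² − 1) + γ/2 : λ ∈ σ(J)} — equal perturbations move
eigenvalues along the imaginary axis only, so the spectral bound (convergence
rate) is independent of μ. The generator spectrum is the set of sums
{−Σ nⱼλⱼ} truncated at a user-chosen total order, always containing 0 (the
invariant measure). Numerically computed eigenvalues of defective
configurations (e.g. the double roots at γ = 2) are only √ε-accurate, so the
internal consistency check between closed form and brute-force eigenvalues
uses a loose 1e−6 matching there, while tests assert 1e−10 agreement on
generic (non-degenerate) instances.

### Large-perturbation limit and kernel projection

As μ → ∞ (with μ = ν and the coupling below), σ²_f(μ) → σ²_{Πf}(0) ≤ σ²_f(0),
where Π is the L²(π)-orthogonal projection onto ker(Jq·∇). For quadratic
observables in unit coordinates the projection is computed exactly: the linear
part is projected onto ker J (SVD null space) and the quadratic part onto the
commutant {K′ symmetric : [J, K′] = 0} under the trace inner product — which
is proportional to the L²(π) inner product of centered Gaussian quadratics —
via an SVD-based null space of the map K′ ↦ JK′ − K′J restricted to an
orthonormal symmetric basis (singular values below 1e−10 of the largest
treated as zero). The isotropic part (Tr K/d)·I always survives; observables
with [J, K] = 0 and l ∈ ker J are untouched by the perturbation at *every* μ,
not just in the limit.

### General covariance: whitening and coupling

For arbitrary SPD S the recommended coupling is

    M = S,   Γ = γS,   J₂ = S·J₁·S,   μ = ν.

The transform q̃ = S^{1/2}q, p̃ = S^{−1/2}p maps the dynamics onto the
unit-covariance case with J̃ = S^{1/2}J₁S^{1/2}, K̃ = S^{−1/2}KS^{−1/2},
l̃ = S^{−1/2}l, leaving σ²_f invariant; the limit theorem and the optimal
construction are applied in whitened coordinates. Matrix square roots use the
symmetric eigendecomposition with no eigenvalue clipping (inputs must be SPD).
Departing from the coupling is allowed in the integrator but the limit and
transform operations refuse it (the theorems do not apply).

Preconditioning: M = cS, Γ = 2cS makes every coordinate of the (whitened)
drift critically damped with decay rate 1/√c, uniform across coordinates.
Small c converges faster but is stiffer; c trades convergence against step
size.

## Optimal perturbations for quadratic observables

For f₀(q) = q·K₀q with Tr K₀ = 0 the construction finds symmetric A and
antisymmetric J with [A, J] = K₀, which exhibits f₀ ∈ im(Jq·∇) and hence a
vanishing large-μ variance limit. Steps: (i) find orthogonal U with
U K₀ Uᵀ zero-diagonal; (ii) pick distinct reals a (default 1, 2, …, d, which
keeps the entries of the intermediate matrix O(‖K₀‖)); (iii) set
J̄ᵢⱼ = (UK₀Uᵀ)ᵢⱼ/(aᵢ − aⱼ), J = UᵀJ̄U, A = Uᵀdiag(a)U.

The zero-diagonal similarity is built by an iterative Givens scheme: while a
diagonal entry exceeds tolerance, rotate the plane spanned by the most
positive and most negative entries (both exist by tracelessness) by the angle
that zeroes the smaller-magnitude entry of the pair. A rotation touches only
its two rows/columns, so zeroed entries stay zeroed and the scheme terminates
in at most d − 1 rotations (a 10·d² cap guards pathological inputs). The
rotation angle uses the cancellation-free quadratic-root form; the naive root
loses ~5 digits when the off-diagonal entry dominates.

The constructed J is far from unique (U and a are free). The binding
contracts, and the only things tests assert, are the certificate
‖[A, J] − K₀‖ and the optimality of the variance limit: with the whitened
construction and the coupling above, the limit equals the unperturbed variance
of the trace part f₁(q) = q·K₁q, K₁ = (Tr(S⁻¹K)/d)·S, which no antisymmetric
perturbation in this family can beat.

## Splitting integrator

The sampler for general potentials is a BAOAB-type scheme with two extra RK4
sub-steps integrating the position-perturbation ODE q̇ = −μJ₁∇V(q) for ½Δt
each, placed on either side of the O-step (B, A, RK4, O, RK4, A, B). Choices:

* **Exact O-step.** The momentum OU part dp = −(Γ + νJ₂)M⁻¹p dt + √(2Γ)dW is
  solved exactly: p ← Ep + Lξ with E = exp(−Δt(Γ + νJ₂)M⁻¹) and LLᵀ =
  M − EMEᵀ. This conditional covariance preserves N(0, M) for *all*
  admissible (M, Γ, ν, J₂) — the identity EMEᵀ + LLᵀ = M follows from
  (Γ + νJ₂)M⁻¹M + M[(Γ + νJ₂)M⁻¹]ᵀ = 2Γ and is asserted to 1e−12 at
  construction. The scalar-friction formula √(I − e^{−2ΓΔt}) is the M = I,
  ν = 0 special case.
* **RK4 rather than an implicit symplectic step** for the J₁-flow: the flow
  conserves V exactly (∇V·J₁∇V = 0), RK4 conserves it to O(h⁵) per step, and
  explicitness wins at the step sizes used. (For *linear* flows RK4's energy
  error is accidentally O(h⁶); the order test uses a quartic potential.)
* The two RK4 half-steps are kept separate rather than merged, for literal
  fidelity to the scheme at negligible cost.
* With μ = ν = 0 the scheme reduces *bit-exactly* to standard BAOAB (the RK4
  sub-steps add exact zeros and the O-step matrices coincide).
* Time averages are left-Riemann sums of f evaluated at the end-of-step
  position q_{n+1}; burn-in is given in time units and rounded down to whole
  steps. Which intra-step position enters the accumulator is a genuine free
  choice; the end-of-step position is the simplest consistent one.
* Divergence guard at ‖q‖∞ > 1e8 (configurable); errors name the step.
* RNG: one `numpy` Generator per replicate, seeded `base_seed + replicate`.
  The replicate runner vectorises all replicates through the same step loop
  (noise pre-generated per replicate in stream order), so it reproduces the
  single-trajectory path up to last-ulp differences in batched BLAS calls.
* No Metropolis correction: the scheme is used unadjusted, so estimates carry
  an O(Δt²) discretisation bias, which at the default Δt is well below the
  replicate noise of the experiments shipped here.

An Euler–Maruyama integrator for the overdamped (large-friction/small-mass)
limit dq = −[(νJ₂ + Γ)⁻¹ + μJ₁]∇V dt + (νJ₂ + Γ)⁻¹√(2Γ) dW is included for
qualitative comparison only; a coupling test with shared Brownian increments
checks that the scaled dynamics approaches it as the scale separation shrinks.

## Diffusion-bridge benchmark

The nonlinear benchmark is the path measure of dX = −∇U(X)dt + √(2/β)dW,
U(x) = ½(x² − 1)², conditioned on X(0) = X(1) = 0, discretised on d interior
grid points with spacing δ = 1/(d + 1):

    V(x) = (β/2) δ Σᵢ G(xᵢ, β) + ½ x·Sx,
    G(x, β) = ½U′(x)² − U″(x)/β,
    S = (β/2) δ A_δ,   A_δ = tridiag(−1, 2, −1)/δ².

Two conventions deserve note. First, A_δ is taken positive definite
(A_δ ≈ −Δ), which the role of S as a precision matrix forces; with the
opposite sign convention for A_δ the Gaussian term appears with a minus sign.
Second, the G above is the continuum form; its gradient contribution per
coordinate is (β/2)δ(U′U″ − U‴/β). An alternative reading with the ½
distributed over both terms, G = ½(U′² − U″/β), differs only by rescaling β in
the curvature term and is switchable (`half_bracket=True`) for reproduction
studies; either way the implemented gradient is the exact derivative of the
implemented V, enforced by finite-difference tests. Endpoints are fixed at
zero on the unit interval with an equidistant grid; general endpoints and
multidimensional wells are out of scope (custom potentials plug in through the
two-function value/gradient contract).

The bridge experiment applies the full recommended pipeline: S from the
Gaussian reference, M = S, Γ = γS, J₁ adapted to the squared-norm observable
by the whitened commutator construction, J₂ = S·J₁·S, initial conditions
q₀ = (1, …, 1), p₀ = 0, burn-in T₀ = 1.

## Estimators

* Replicate route (primary): the across-replicate variance of π̂(f) times
  (T − T₀)/2 estimates σ²_f; its standard error uses the Gaussian-χ²
  approximation σ̂²√(2/(N − 1)) — about 25% relative noise at N = 32, 20% at
  N = 50. The sweep tables report the raw across-replicate std of π̂(f)
  (normalisation conventions differ across the literature; the raw std is the
  directly comparable one at fixed T).
* Autocorrelation route (secondary): biased (1/n) FFT autocovariances
  integrated by the trapezoid rule over a fixed lag window (half weight at lag
  0 and at the edge). The window is not adaptive; the shipped tests use
  windows of 5–8 time units where the worked examples' autocovariances have
  decayed to noise level. Batch-means and spectral estimators are out of scope.

## Study conditions and what the tests show

Scaled-down experiment sizes are the package defaults: the Gaussian
end-to-end check uses d = 2, T = 500, Δt = 0.01, 32 replicates; the bridge
benchmark preset uses d = 15, T = 20, Δt = 1e−3, T₀ = 1, N = 50 replicates,
with γ spanning under- to over-damped regimes (0.1, 1.0, 5.0) and μ ∈ {0, 5}.
A `paper` preset (d = 100, T = 100, Δt = 1e−4, N = 500) preserves the
full-fidelity configuration; it takes hours on one CPU. Friction for the
theory-scan illustration defaults to γ = 2.5, a choice (the value is tied to
the autocorrelation illustration, where it is stated).

Stochastic checks are seeded and interpreted conservatively: the bridge
direction check ("the adapted perturbation does not increase replicate
spread at γ = 0.1") is asserted as a majority over three seed batches, and
the γ-stability check compares ranges of replicate stds across γ between the
μ = 0 and μ = 5 columns. At these scales the *systematic* γ-sensitivity of the
unperturbed sampler exceeds replicate noise only when γ spans about a decade
or more, hence the preset grid above.

Synthetic inputs (random SPD matrices with spectrum in [0.5, 2], unit-norm
antisymmetric matrices, O(1) quadratic observables) exercise the generic,
well-conditioned regime. They do not probe near-singular precisions,
near-commuting (J, K) pairs with tiny commutators, or high dimensions
(d ≤ ~15 in tests), so passing tests certify correctness of the formulas and
algorithms, not numerical behaviour at extreme conditioning.

## Known limitations

* Exact σ² machinery covers quadratic observables only; other observables go
  through simulation.
* Only perturbation pairs coupled by J₂ = S·J₁·S are analysed; fully general
  (J₁, J₂) optimisation is open.
* No Metropolis adjustment, adaptive step sizes, higher-order stochastic
  integrators, or generalised (memory-kernel) Langevin dynamics.
* Convergence-rate constants (hypocoercivity prefactors) are not computed;
  only spectral bounds of the drift are reported.
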