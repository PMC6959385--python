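# nrlangevin

Design, run and evaluate **nonreversible (perturbed) underdamped Langevin
samplers** for computing expectations under a Gibbs measure
π(q) ∝ exp(−V(q)) — the canonical-ensemble sampling problem at the heart of
molecular dynamics and Bayesian computation.

## The idea

Standard underdamped Langevin dynamics augments the position q with a momentum
p and samples π ⊗ N(0, M):

    dq = M⁻¹p dt,
    dp = −∇V(q) dt − ΓM⁻¹p dt + √(2Γ) dW.

Adding carefully chosen *antisymmetric* (skew-symmetric) drift perturbations
keeps the invariant measure intact while breaking detailed balance:

    dq = M⁻¹p dt − μ J₁ ∇V(q) dt,
    dp = −∇V(q) dt − ν J₂ M⁻¹p dt − ΓM⁻¹p dt + √(2Γ) dW,

with J₁ᵀ = −J₁, J₂ᵀ = −J₂ and scalar strengths μ, ν. Nonreversibility can
dramatically reduce the **asymptotic variance** σ²_f — the CLT constant of the
time-average estimator π_T(f), with √T(π_T(f) − π(f)) → N(0, 2σ²_f).

For a Gaussian target V(q) = ½q·Sq everything is exactly computable: the
dynamics is an Ornstein–Uhlenbeck process dX = −BX dt + √(2Q) dW̄, and for
quadratic observables f(q) = q·Kq + l·q + c the Poisson equation −𝓛χ = f − π(f)
has a quadratic solution given by a Sylvester equation,

    BᵀC + CB = K̄,   BᵀD = l̄,   σ²_f = 2 Tr(C Σ∞ K̄ Σ∞) + D·Σ∞ l̄,

with K̄ = blockdiag(K, 0), l̄ = (l, 0), Σ∞ = blockdiag(S⁻¹, M). The package
implements this theory together with its structural consequences:

* σ²_f(μ) has a **local maximum at μ = 0** (zero slope, explicitly negative
  curvature for γ > √2 unless f is invariant under the rotation field Jq·∇);
* the **large-μ limit** is σ²_{Πf}(0), where Π projects onto ker(J₁Sq·∇) — so
  observables orthogonal to that kernel are sampled with vanishing variance;
* equal strengths μ = ν with the coupling M = S, Γ = γS, J₂ = S·J₁·S shift the
  drift spectrum along the imaginary axis only, leaving the convergence rate
  untouched (closed form σ(B) = {μλ ± √((γ/2)² − 1) + γ/2 : λ ∈ σ(J)});
* a **constructive algorithm** produces the observable-adapted optimal J for
  quadratic observables via a commutator certificate [A, J] = K₀;
* critically damped preconditioning M = cS, Γ = 2cS equalises per-coordinate
  decay rates at 1/√c.

For general potentials the package provides a BAOAB-type splitting integrator
extended with RK4 sub-steps for the J₁ position perturbation and an exact
(momentum-marginal-preserving) O-step for the J₂ friction perturbation, plus a
discretised double-well diffusion-bridge potential as a hard nonlinear
benchmark, replicate/autocorrelation estimators of σ²_f, and a CLI.

## Worked example

The classic 2-d test case: unit Gaussian target, observable
f(q) = q·Kq + l·q with K = diag(2, 1), l = (1, 1), and J = [[0, 1], [−1, 0]].

```python
import numpy as np
import nrlangevin as nr

target = nr.GaussianTarget.standard(2)
obs = nr.QuadraticObservable(K=np.diag([2.0, 1.0]), l=np.array([1.0, 1.0]))
J = np.array([[0.0, 1.0], [-1.0, 0.0]])

curve = nr.theory_scan(target, J, obs, gamma=2.5, mu_grid=[0, 1, 2, 5, 10])
for mu, s2 in zip(curve.mu_values, curve.sigma2_values):
    print(f"mu={mu:4.1f}  sigma2={s2:.6f}")
print("limit:", curve.limit_value)
```

prints

```
mu= 0.0  sigma2=19.500000
mu= 1.0  sigma2=14.010976
mu= 2.0  sigma2=13.215648
mu= 5.0  sigma2=13.057346
mu=10.0  sigma2=13.050511
limit: 13.049999999999997
```

the exact asymptotic variance of the time-average estimator as a function of
the perturbation strength μ at friction γ = 2.5: the unperturbed sampler
(μ = 0) is worst, and σ²(μ) decays monotonically here toward the theoretical
limit σ²_{Πf}(0) = 13.05, the variance of the kernel projection
Πf = 1.5|q|² of the observable. A Monte-Carlo cross-check with the splitting
integrator (γ = 2, μ = ν = 1, 32 replicates of length T = 500 at Δt = 0.01):

```python
pert = nr.PerturbationConfig.unit(2, 2.0, mu=1.0, J=J)
cfg = nr.IntegratorConfig(dt=0.01, n_steps=50_000, burn_in_time=2.0,
                          pert=pert, seed=7000)
ens = nr.run_replicates(nr.Potential.gaussian(target), cfg, [obs], 32)
est, se = nr.replicate_asymptotic_variance(ens[:, 0], 498.0)
print(f"sampled sigma2 = {est:.2f} +/- {se:.2f}   (exact: 12.4375)")
```

```
sampled sigma2 = 15.22 +/- 3.87   (exact: 12.4375)
```

consistent with the exact Sylvester value within one standard error (a
32-replicate variance estimate carries ~25% relative noise).

The observable-adapted optimal perturbation is one call:

```python
res = nr.optimal_J_unit(np.diag([2.0, 1.0]), a=np.array([1.0, 2.0]))
print(res.J1)        # [[ 0.  -0.5], [ 0.5  0. ]]
```

and `nr.optimal_J_general(K, S)` handles arbitrary SPD precision matrices,
returning the coupled pair (J₁, J₂ = S·J₁·S).

## Command line

```bash
nrlangevin theory-scan --j1 J.txt --obs obs.txt --gamma 2.5 --out scan.csv
nrlangevin optimal-j --k K.txt --s S.txt --out-j1 J1.txt --out-j2 J2.txt
nrlangevin sample --target gaussian --config run.toml --replicates 32 --out est.csv
nrlangevin bridge --preset scaled --gammas 0.1,1.0,5.0 --mus 0,5 --out sweep.csv
nrlangevin acf --series series.txt --dt 0.01 --window 500 --out acf.csv
```

Matrices are whitespace-delimited text; sweep CSVs carry a `#` config echo so
every row is regenerable from its header and seed.

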