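"""Splitting integrator for perturbed underdamped Langevin dynamics.

The scheme extends BAOAB (half momentum kick **B**, half position drift **A**,
exact Ornstein--Uhlenbeck momentum refresh **O**, then A and B again) with two
extra fourth-order Runge--Kutta sub-steps integrating the position perturbation
ODE q̇ = −μJ₁∇V(q) for half a step each, on either side of the O-step:

    B  p ← p − ½Δt ∇V(q)
    A  q ← q + ½Δt M⁻¹p
    R  q ← RK₄(½Δt) of q̇ = −μJ₁∇V(q)
    O  p ← E p + L ξ,  E = exp(−Δt (Γ + νJ₂)M⁻¹),  L Lᵀ = M − E M Eᵀ
    R  q ← RK₄(½Δt)
    A  q ← q + ½Δt M⁻¹p
    B  p ← p − ½Δt ∇V(q)

The O-step uses the exact conditional covariance M − E·M·Eᵀ of the momentum OU
process, which preserves N(0, M) for every admissible (M, Γ, ν, J₂); when M = I
and ν = 0 it reduces to the familiar amplitude √(I − e^{−2ΓΔt}).  With μ = ν = 0
the scheme is bit-identical to standard BAOAB.  The scheme is used unadjusted
(no Metropolis correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

from ._validate import ValidationError
from .gaussian_theory import GaussianTarget, PerturbationConfig

__all__ = [
    "Potential",
    "SamplerState",
    "IntegratorConfig",
    "SimulationResult",
    "rk4_flow_step",
    "ou_step",
    "baoab_perturbed_step",
    "baoab_step",
    "simulate",
    "run_replicates",
    "overdamped_limit_step",
]


@dataclass(frozen=True)
class Potential:
    """Potential V with gradient; both must accept (..., d)-shaped positions."""

    value: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    d: int

    @classmethod
    def gaussian(cls, target: GaussianTarget) -> "Potential":
        S = target.precision
        return cls(
            value=lambda q: 0.5 * np.einsum("...i,ij,...j->...", q, S, q),
            gradient=lambda q: q @ S,
            d=target.d,
        )


@dataclass
class SamplerState:
    """Position/momentum state with its reproducible RNG stream."""

    q: np.ndarray
    p: np.ndarray
    step_index: int = 0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.q.shape != self.p.shape:
            raise ValidationError("q and p must have matching shapes")


@dataclass(frozen=True)
class IntegratorConfig:
    """Step size, horizon, burn-in, seed and perturbation parameters of a run."""

    dt: float
    n_steps: int
    pert: PerturbationConfig
    burn_in_time: float = 0.0
    seed: int = 0
    divergence_bound: float = 1e8

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if self.burn_in_time < 0 or self.burn_in_time >= self.n_steps * self.dt:
            raise ValidationError("burn_in_time must lie in [0, n_steps*dt)")


@dataclass(frozen=True)
class SimulationResult:
    """Streamed time averages, final state and optional thinned trajectory."""

    averages: np.ndarray
    n_averaged: int
    final_state: SamplerState
    trajectory: np.ndarray | None = None
    times: np.ndarray | None = None


def rk4_flow_step(J1: np.ndarray, grad: Callable[[np.ndarray], np.ndarray],
                  q: np.ndarray, h: float) -> np.ndarray:
    """One classical RK4 step of the volume-preserving flow q̇ = −J₁∇V(q).

    The exact flow conserves V (since ∇V·(−J₁∇V) = 0), so the per-step energy
    drift of this approximation is O(h⁵).
    """
    if h < 0:
        raise ValidationError("h must be nonnegative")
    k1 = -(grad(q) @ J1.T)
    k2 = -(grad(q + 0.5 * h * k1) @ J1.T)
    k3 = -(grad(q + 0.5 * h * k2) @ J1.T)
    k4 = -(grad(q + h * k3) @ J1.T)
    return q + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


class _OUStep:
    """Exact solution of dp = −(Γ + νJ₂)M⁻¹ p dt + √(2Γ) dW over a fixed Δt.

    p ← E p + L ξ with E = exp(−Δt (Γ+νJ₂)M⁻¹) and L the Cholesky factor of
    M − E M Eᵀ.  Preserves N(0, M) exactly: E M Eᵀ + L Lᵀ = M because
    (Γ+νJ₂)M⁻¹·M + M·[(Γ+νJ₂)M⁻¹]ᵀ = 2Γ.
    """

    def __init__(self, pert: PerturbationConfig, dt: float):
        M = pert.M
        Minv = np.linalg.inv(M)
        A = (pert.Gamma + pert.nu * pert.J2) @ Minv
        self.E = expm(-dt * A)
        cov = M - self.E @ M @ self.E.T
        cov = 0.5 * (cov + cov.T)
        try:
            self.L = np.linalg.cholesky(cov) if dt > 0 else np.zeros_like(M)
        except np.linalg.LinAlgError as exc:
            raise ArithmeticError(
                "O-step conditional covariance is not positive definite"
            ) from exc
        self.M = M
        # analytic stationarity identity, asserted at construction
        res = np.abs(self.E @ M @ self.E.T + cov - M).max()
        if res > 1e-12 * max(np.abs(M).max(), 1.0):
            raise ArithmeticError(f"O-step stationarity identity violated: {res:.3e}")

    def __call__(self, p: np.ndarray, xi: np.ndarray) -> np.ndarray:
        return p @ self.E.T + xi @ self.L.T


def ou_step(p: np.ndarray, dt: float, pert: PerturbationConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Apply the exact O-step to momentum p, drawing the noise from ``rng``."""
    if dt < 0:
        raise ValidationError("dt must be nonnegative")
    stepper = _OUStep(pert, dt)
    xi = rng.standard_normal(np.shape(p))
    return stepper(np.asarray(p, dtype=float), xi)


class _PerturbedBAOAB:
    """Precomputed stepper for the perturbed splitting scheme."""

    def __init__(self, potential: Potential, config: IntegratorConfig):
        pert = config.pert
        if pert.d != potential.d:
            raise ValidationError("perturbation and potential dimensions differ")
        self.potential = potential
        self.dt = config.dt
        self.Minv = np.linalg.inv(pert.M)
        self.muJ1 = pert.mu * pert.J1
        self.ou = _OUStep(pert, config.dt)
        self.perturbed = np.abs(self.muJ1).max() > 0.0
        self.bound = config.divergence_bound

    def step(self, q: np.ndarray, p: np.ndarray, xi: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
        dt = self.dt
        grad = self.potential.gradient
        p = p - 0.5 * dt * grad(q)              # B
        q = q + 0.5 * dt * (p @ self.Minv.T)    # A
        if self.perturbed:
            q = rk4_flow_step(self.muJ1, grad, q, 0.5 * dt)
        p = self.ou(p, xi)                      # O
        if self.perturbed:
            q = rk4_flow_step(self.muJ1, grad, q, 0.5 * dt)
        q = q + 0.5 * dt * (p @ self.Minv.T)    # A
        p = p - 0.5 * dt * grad(q)              # B
        return q, p


def baoab_perturbed_step(state: SamplerState, potential: Potential,
                         config: IntegratorConfig) -> SamplerState:
    """Advance the state by one step of the perturbed splitting scheme."""
    stepper = _PerturbedBAOAB(potential, config)
    xi = state.rng.standard_normal(state.p.shape)
    q, p = stepper.step(state.q, state.p, xi)
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(p))):
        raise ArithmeticError(f"non-finite state at step {state.step_index + 1}")
    return SamplerState(q=q, p=p, step_index=state.step_index + 1, rng=state.rng)


def baoab_step(state: SamplerState, potential: Potential,
               config: IntegratorConfig) -> SamplerState:
    """One step of standard (unperturbed) BAOAB with matrix mass and friction."""
    unpert = replace(config, pert=PerturbationConfig(
        J1=np.zeros_like(config.pert.M), J2=np.zeros_like(config.pert.M),
        mu=0.0, nu=0.0, M=config.pert.M, Gamma=config.pert.Gamma))
    return baoab_perturbed_step(state, potential, unpert)


def _prepare_initial(potential: Potential, config: IntegratorConfig,
                     initial: SamplerState | None) -> SamplerState:
    if initial is not None:
        return initial
    d = potential.d
    return SamplerState(q=np.zeros(d), p=np.zeros(d),
                        rng=np.random.default_rng(config.seed))


def simulate(potential: Potential, config: IntegratorConfig,
             observables: Sequence[Callable[[np.ndarray], float]],
             initial: SamplerState | None = None,
             return_trajectory: bool = False, thin: int = 1) -> SimulationResult:
    """Run the perturbed scheme, streaming time averages of the observables.

    Accumulates left-Riemann averages of f(q_{n+1}) over the post-burn-in steps
    (burn-in is measured in time units and rounded down to whole steps).  Memory
    is O(d) unless a thinned trajectory is requested.  Raises on divergence
    (‖q‖∞ exceeding the configured bound), naming the offending step.
    """
    state = _prepare_initial(potential, config, initial)
    stepper = _PerturbedBAOAB(potential, config)
    n_burn = int(np.floor(config.burn_in_time / config.dt))
    sums = np.zeros(len(observables))
    count = 0
    traj, times = ([], []) if return_trajectory else (None, None)
    q, p = state.q, state.p
    rng = state.rng
    for n in range(config.n_steps):
        xi = rng.standard_normal(p.shape)
        q, p = stepper.step(q, p, xi)
        if np.abs(q).max() > stepper.bound or not np.all(np.isfinite(q)):
            raise ArithmeticError(f"trajectory diverged at step {n + 1}")
        if n >= n_burn:
            for k, f in enumerate(observables):
                sums[k] += f(q)
            count += 1
        if return_trajectory and (n % thin == 0):
            traj.append(q.copy())
            times.append((n + 1) * config.dt)
    final = SamplerState(q=q, p=p, step_index=state.step_index + config.n_steps, rng=rng)
    averages = sums / max(count, 1)
    return SimulationResult(
        averages=averages, n_averaged=count, final_state=final,
        trajectory=np.array(traj) if return_trajectory else None,
        times=np.array(times) if return_trajectory else None,
    )


def run_replicates(potential: Potential, config: IntegratorConfig,
                   observables: Sequence[Callable[[np.ndarray], float]],
                   n_replicates: int,
                   q0: np.ndarray | None = None,
                   p0: np.ndarray | None = None,
                   chunk_steps: int = 4096) -> np.ndarray:
    """Replicate ensemble of time-average estimates, vectorised across replicates.

    Replicate r uses its own generator seeded with ``config.seed + r`` and
    consumes the same noise stream as ``simulate`` with that seed (noise is
    pre-generated in chunks in stream order; batched arithmetic may differ from
    the single-trajectory path in the last ulp).  Returns an
    (n_replicates, n_observables) array of post-burn-in time averages.
    """
    d = potential.d
    q0 = np.zeros(d) if q0 is None else np.asarray(q0, dtype=float)
    p0 = np.zeros(d) if p0 is None else np.asarray(p0, dtype=float)
    stepper = _PerturbedBAOAB(potential, config)
    rngs = [np.random.default_rng(config.seed + r) for r in range(n_replicates)]
    q = np.tile(q0, (n_replicates, 1))
    p = np.tile(p0, (n_replicates, 1))
    n_burn = int(np.floor(config.burn_in_time / config.dt))
    sums = np.zeros((n_replicates, len(observables)))
    count = 0
    n = 0
    while n < config.n_steps:
        block = min(chunk_steps, config.n_steps - n)
        noise = np.stack([rng.standard_normal((block, d)) for rng in rngs], axis=1)
        for b in range(block):
            q, p = stepper.step(q, p, noise[b])
            if n >= n_burn:
                for k, f in enumerate(observables):
                    sums[:, k] += f(q)
                count += 1
            n += 1
        if np.abs(q).max() > stepper.bound or not np.all(np.isfinite(q)):
            raise ArithmeticError(f"a replicate diverged by step {n}")
    return sums / max(count, 1)


def overdamped_limit_step(q: np.ndarray, dt: float, pert: PerturbationConfig,
                          grad: Callable[[np.ndarray], np.ndarray],
                          rng: np.random.Generator) -> np.ndarray:
    """One Euler--Maruyama step of the overdamped (large-friction) limit SDE

        dq = −[(νJ₂ + Γ)⁻¹ + μJ₁] ∇V(q) dt + (νJ₂ + Γ)⁻¹ √(2Γ) dW.

    Provided for qualitative comparison with the small-mass scaling only.
    """
    A = pert.nu * pert.J2 + pert.Gamma
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError("nu*J2 + Gamma is singular") from exc
    from ._validate import sym_sqrt

    root_2G, _ = sym_sqrt(2.0 * pert.Gamma)
    mobility = Ainv + pert.mu * pert.J1
    noise_map = Ainv @ root_2G
    xi = rng.standard_normal(np.shape(q))
    return q - dt * (grad(q) @ mobility.T) + np.sqrt(dt) * (xi @ noise_map.T)
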