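"""Built-in targets: Gaussians from a precision matrix, and a discretised
double-well diffusion-bridge potential; plus seeded fixture generators.

The bridge target is the path-space measure of the diffusion
dX = −∇U(X) dt + √(2/β) dW conditioned on X(0) = X(1) = 0, with the scalar
double well U(x) = ½(x² − 1)².  Its law is absolutely continuous with respect
to a Brownian-bridge-like Gaussian reference with precision operator
−(β/2)Δ (Dirichlet boundary conditions), and the Radon--Nikodym density is
exp(−Ψ) with Ψ(x) = (β/2)∫ G(x(s), β) ds, G(x, β) = ½U′(x)² − U″(x)/β.
On an equidistant grid with spacing δ = 1/(d+1) this gives the finite-
dimensional potential

    V(x) = Ψ̃(x) + ½ x·Sx,     Ψ̃(x) = (β/2) δ Σᵢ G(xᵢ, β),
    S = (β/2) δ A_δ,           A_δ = tridiag(−1, 2, −1)/δ²,

where A_δ is the (positive definite) discrete Dirichlet Laplacian.  The
positive sign of the Gaussian part follows from taking A_δ ≈ −Δ positive
definite, which is forced by S being a precision matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._validate import ValidationError
from .gaussian_theory import GaussianTarget, QuadraticObservable
from .integrator import Potential

__all__ = [
    "build_dirichlet_laplacian",
    "BridgeTarget",
    "bridge_potential",
    "random_spd",
    "random_antisymmetric",
    "random_observable",
    "fixture_generator",
]


def build_dirichlet_laplacian(d: int) -> np.ndarray:
    """Discrete Dirichlet Laplacian tridiag(−1, 2, −1)/δ² on (0,1), δ = 1/(d+1).

    Positive definite, with eigenvalues (2/δ²)(1 − cos(kπδ)), k = 1..d.
    """
    if d < 1:
        raise ValidationError("d must be >= 1")
    delta = 1.0 / (d + 1)
    A = 2.0 * np.eye(d) - np.eye(d, k=1) - np.eye(d, k=-1)
    return A / delta**2


def _U_derivs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """U′, U″, U‴ of the double well U(x) = ½(x² − 1)²."""
    return 2.0 * x**3 - 2.0 * x, 6.0 * x**2 - 2.0, 12.0 * x


@dataclass(frozen=True)
class BridgeTarget:
    """Discretised double-well diffusion-bridge target on d interior grid points.

    ``half_bracket`` switches to the alternative reading
    G = ½(U′² − U″/β) of the path functional (the default is the continuum form
    G = ½U′² − U″/β); the two differ only by a rescaling of β in the curvature
    term and are provided for reproduction studies.
    """

    d: int
    beta: float = 1.0
    half_bracket: bool = False
    A_delta: np.ndarray = field(init=False, repr=False)
    S: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.d < 1:
            raise ValidationError("d must be >= 1")
        if self.beta <= 0:
            raise ValidationError("beta must be positive")
        A = build_dirichlet_laplacian(self.d)
        object.__setattr__(self, "A_delta", A)
        object.__setattr__(self, "S", 0.5 * self.beta * self.delta * A)

    @property
    def delta(self) -> float:
        return 1.0 / (self.d + 1)

    @property
    def gaussian_reference(self) -> GaussianTarget:
        """The Gaussian reference measure N(0, S⁻¹) used for preconditioning."""
        return GaussianTarget(self.S)

    def _curvature_factor(self) -> float:
        # coefficient of U'' in G: 1/β in the continuum form, 1/(2β) in the
        # half-bracket reading ½(U'² − U''/β)
        return 0.5 / self.beta if self.half_bracket else 1.0 / self.beta

    def value(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        up, upp, _ = _U_derivs(x)
        G = 0.5 * up**2 - self._curvature_factor() * upp
        psi = 0.5 * self.beta * self.delta * G.sum(axis=-1)
        quad = 0.5 * np.einsum("...i,ij,...j->...", x, self.S, x)
        return psi + quad

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        up, upp, uppp = _U_derivs(x)
        dpsi = 0.5 * self.beta * self.delta * (up * upp - self._curvature_factor() * uppp)
        return dpsi + x @ self.S

    def potential(self) -> Potential:
        return Potential(value=self.value, gradient=self.gradient, d=self.d)


def bridge_potential(target: BridgeTarget, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Evaluate (V(x), ∇V(x)) of the discretised bridge potential."""
    return float(target.value(x)), target.gradient(x)


# ---------------------------------------------------------------------------
# Seeded fixture generators
# ---------------------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_spd(seed, d: int) -> np.ndarray:
    """Random SPD matrix Q·diag(u)·Qᵀ with spectrum u ∈ [0.5, 2]."""
    rng = _rng(seed)
    A = rng.standard_normal((d, d))
    Q, _ = np.linalg.qr(A)
    u = rng.uniform(0.5, 2.0, size=d)
    return (Q * u) @ Q.T


def random_antisymmetric(seed, d: int) -> np.ndarray:
    """Random antisymmetric matrix (R − Rᵀ)/2, normalised to unit spectral norm."""
    rng = _rng(seed)
    R = rng.standard_normal((d, d))
    J = 0.5 * (R - R.T)
    norm = np.linalg.norm(J, 2)
    return J / norm if norm > 0 else J


def random_observable(seed, d: int) -> QuadraticObservable:
    """Random quadratic observable with ‖K‖ and ‖l‖ of order one."""
    rng = _rng(seed)
    A = rng.standard_normal((d, d)) / np.sqrt(d)
    K = 0.5 * (A + A.T)
    l = rng.standard_normal(d) / np.sqrt(d)
    return QuadraticObservable(K=K, l=l, c=float(rng.standard_normal()))


def fixture_generator(seed, d: int, kind: str):
    """Dispatch seeded fixtures: kind ∈ {"spd", "antisymmetric", "observable"}."""
    if kind == "spd":
        return random_spd(seed, d)
    if kind == "antisymmetric":
        return random_antisymmetric(seed, d)
    if kind == "observable":
        return random_observable(seed, d)
    raise ValidationError(f"unknown fixture kind {kind!r}")
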