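"""Constructive optimal antisymmetric perturbations for quadratic observables.

For a purely quadratic observable f₀(q) = q·K₀q with traceless K₀ there exists an
antisymmetric J such that the large-μ limit of the asymptotic variance vanishes.
The construction finds symmetric A and antisymmetric J with [A, J] = K₀, which
exhibits f₀ as an element of the closure of im(Jq·∇) — i.e. orthogonal to the
kernel that survives the perturbation.  Concretely:

1. conjugate K₀ by an orthogonal U so that U K₀ Uᵀ has zero diagonal,
2. pick distinct reals a₁,…,a_d and set J̄ᵢⱼ = (U K₀ Uᵀ)ᵢⱼ / (aᵢ − aⱼ),
3. pull back: J = Uᵀ J̄ U, A = Uᵀ diag(a) U.

For a general Gaussian precision S the same construction is applied to the
whitened matrix K̃ = S^{-1/2} K S^{-1/2}, giving J₁ = S^{-1/2} J̃ S^{-1/2} and
J₂ = S^{1/2} J̃ S^{1/2}, which satisfy the recommended coupling J₂ = S·J₁·S.

The output J is far from unique (U and the aᵢ are free); the binding contract is
the certificate identity [A, J̃] = K̃₀ and the resulting variance limit, which
equals the unperturbed variance of the trace part — the provable optimum over
this family of perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validate import ValidationError, check_spd, check_symmetric, sym_sqrt

__all__ = ["OptimalJResult", "zero_diagonal_similarity", "optimal_J_unit",
           "optimal_J_general"]


@dataclass(frozen=True)
class OptimalJResult:
    """Constructed perturbation pair with its commutator certificate.

    ``J1``/``J2`` are the perturbation matrices (equal in the unit case),
    ``A`` the symmetric certificate with [A, J̃] = K̃₀, ``U`` the orthogonal
    zero-diagonal similarity and ``a`` the distinct reals used.
    """

    J1: np.ndarray
    J2: np.ndarray
    A: np.ndarray
    U: np.ndarray
    a: np.ndarray


def _rotation_zeroing_diagonal(a: float, b: float, c: float) -> float:
    """Angle θ of the 2×2 rotation zeroing a diagonal entry of [[a, b], [b, c]].

    The rotated (1,1) entry is a cos²θ − 2b sinθ cosθ + c sin²θ; with t = tanθ it
    vanishes when c t² − 2b t + a = 0, solvable whenever a·c ≤ 0.
    """
    disc = b * b - a * c
    if disc < 0:
        raise ArithmeticError("2x2 block has no zero-diagonal rotation")
    r = np.sqrt(disc)
    # smaller-magnitude root via the cancellation-free (Citardauq) form
    denom = b + np.copysign(r, b) if b != 0.0 else r
    if denom == 0.0:
        if a != 0.0:
            raise ArithmeticError("degenerate 2x2 block")
        t = 0.0
    else:
        t = a / denom
    return float(np.arctan(t))


def zero_diagonal_similarity(K0: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Orthogonal U such that U K0 Uᵀ has zero diagonal, for traceless symmetric K0.

    Iterative Givens scheme: while some diagonal entry exceeds tolerance, take the
    most positive entry i and the most negative entry j (both exist by
    tracelessness) and rotate in the (i, j) plane so the smaller-magnitude entry
    of the pair becomes zero.  Each rotation touches only rows/columns i and j,
    so the count of zeroed diagonal entries strictly increases; at most 10·d²
    rotations are allowed before an error is raised.
    """
    K0 = check_symmetric(K0, "K0")
    d = K0.shape[0]
    scale = max(np.abs(K0).max(), 1.0)
    if abs(np.trace(K0)) > 1e-10 * scale * d:
        raise ValidationError("K0 must be traceless")
    A = K0.copy()
    U = np.eye(d)
    max_rot = 10 * d * d
    for _ in range(max_rot):
        diag = np.diag(A)
        if np.abs(diag).max() <= tol * scale:
            break
        i = int(np.argmax(diag))
        j = int(np.argmin(diag))
        a, b, c = A[i, i], A[i, j], A[j, j]
        if abs(a) < abs(c):
            theta = _rotation_zeroing_diagonal(a, b, c)
            ii, jj = i, j
        else:
            theta = _rotation_zeroing_diagonal(c, b, a)
            ii, jj = j, i
        G = np.eye(d)
        cth, sth = np.cos(theta), np.sin(theta)
        # rotation acting on the (ii, jj) plane; zeroes the (ii, ii) entry
        G[ii, ii] = cth
        G[ii, jj] = -sth
        G[jj, ii] = sth
        G[jj, jj] = cth
        A = G @ A @ G.T
        A = 0.5 * (A + A.T)
        A[ii, ii] = 0.0
        U = G @ U
    else:
        raise ArithmeticError("zero-diagonal similarity did not converge")
    return U


def optimal_J_unit(K: np.ndarray, a: np.ndarray | None = None) -> OptimalJResult:
    """Optimal antisymmetric J for f(q) = q·Kq under a unit-covariance Gaussian.

    Returns J with certificate [A, J] = K₀ (K₀ the traceless part of K), which
    drives the large-μ variance of the traceless part of the observable to zero.
    """
    K = check_symmetric(K, "K")
    d = K.shape[0]
    if a is None:
        a = np.arange(1.0, d + 1.0)
    else:
        a = np.asarray(a, dtype=float).reshape(-1)
        if a.shape != (d,):
            raise ValidationError(f"a must have length {d}")
        if np.min(np.abs(np.subtract.outer(a, a)[~np.eye(d, dtype=bool)])) == 0.0:
            raise ValidationError("entries of a must be pairwise distinct")
    K0 = K - (np.trace(K) / d) * np.eye(d)
    if np.abs(K0).max() <= 1e-14 * max(np.abs(K).max(), 1.0):
        Z = np.zeros((d, d))
        return OptimalJResult(J1=Z, J2=Z.copy(), A=np.diag(a), U=np.eye(d), a=a)
    U = zero_diagonal_similarity(K0)
    T = U @ K0 @ U.T
    denom = np.subtract.outer(a, a)
    np.fill_diagonal(denom, 1.0)
    Jbar = T / denom
    np.fill_diagonal(Jbar, 0.0)
    Jbar = 0.5 * (Jbar - Jbar.T)
    J = U.T @ Jbar @ U
    J = 0.5 * (J - J.T)
    A = U.T @ np.diag(a) @ U
    return OptimalJResult(J1=J, J2=J.copy(), A=0.5 * (A + A.T), U=U, a=a)


def optimal_J_general(K: np.ndarray, S: np.ndarray,
                      a: np.ndarray | None = None) -> OptimalJResult:
    """Optimal perturbation pair (J₁, J₂) for f(q) = q·Kq under N(0, S⁻¹).

    Whitens K, runs the unit-covariance construction on K̃ = S^{-1/2}KS^{-1/2}
    and pulls back: J₁ = S^{-1/2} J̃ S^{-1/2}, J₂ = S^{1/2} J̃ S^{1/2}, so that
    J₂ = S·J₁·S.  With this pair the large-μ variance limit of f equals the
    unperturbed variance of the trace part f₁(q) = q·K₁q, K₁ = (Tr(S⁻¹K)/d)·S.
    """
    S = check_spd(S, "S")
    root, inv_root = sym_sqrt(S)
    Kt = inv_root @ K @ inv_root
    unit = optimal_J_unit(Kt, a=a)
    Jt = unit.J1
    J1 = inv_root @ Jt @ inv_root
    J2 = root @ Jt @ root
    return OptimalJResult(J1=0.5 * (J1 - J1.T), J2=0.5 * (J2 - J2.T),
                          A=unit.A, U=unit.U, a=unit.a)
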