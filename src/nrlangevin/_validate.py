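"""Shared validation helpers for matrix-valued sampler parameters."""

from __future__ import annotations

import numpy as np

# Relative tolerance for symmetry / antisymmetry checks.
SYM_TOL = 1e-10
# Ergodicity margin for the spectral abscissa of the drift matrix.
ERGODIC_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


def as_square_matrix(A, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {A.shape}")
    return A


def check_symmetric(A, name: str) -> np.ndarray:
    A = as_square_matrix(A, name)
    scale = max(np.abs(A).max(), 1.0)
    if np.abs(A - A.T).max() > SYM_TOL * scale:
        raise ValidationError(f"{name} is not symmetric within tolerance")
    return 0.5 * (A + A.T)


def check_antisymmetric(A, name: str) -> np.ndarray:
    A = as_square_matrix(A, name)
    scale = max(np.abs(A).max(), 1.0)
    if np.abs(A + A.T).max() > SYM_TOL * scale:
        raise ValidationError(f"{name} is not antisymmetric within tolerance")
    return 0.5 * (A - A.T)


def check_spd(A, name: str) -> np.ndarray:
    A = check_symmetric(A, name)
    eigs = np.linalg.eigvalsh(A)
    if eigs.min() <= 0:
        raise ValidationError(
            f"{name} must be symmetric positive definite; "
            f"smallest eigenvalue {eigs.min():.3e}"
        )
    return A


def check_vector(v, d: int, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(-1)
    if v.shape != (d,):
        raise ValidationError(f"{name} must be a vector of length {d}, got {v.shape}")
    return v


def sym_sqrt(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (S^{1/2}, S^{-1/2}) via the symmetric eigendecomposition.

    S must be SPD; no eigenvalue clipping is performed.
    """
    w, V = np.linalg.eigh(S)
    if w.min() <= 0:
        raise ValidationError("matrix square root requires an SPD matrix")
    root = (V * np.sqrt(w)) @ V.T
    inv_root = (V / np.sqrt(w)) @ V.T
    return root, inv_root
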