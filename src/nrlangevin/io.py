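"""Plain-text IO: whitespace-delimited matrices, observable documents, CSV scans.

Observable documents are small structured text files::

    c 0.5
    l 1 1
    K
    2 0
    0 1

``c`` and ``l`` are optional (default 0); ``K`` starts a matrix block read to
the end of the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._validate import ValidationError
from .gaussian_theory import QuadraticObservable, VarianceCurve

__all__ = ["read_matrix", "write_matrix", "read_vector", "read_observable",
           "write_observable", "write_variance_curve", "write_sweep"]


def read_matrix(path) -> np.ndarray:
    A = np.loadtxt(path, dtype=float, ndmin=2)
    return A


def write_matrix(path, A) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(A, dtype=float)), fmt="%.17g")


def read_vector(path) -> np.ndarray:
    return np.loadtxt(path, dtype=float, ndmin=1).reshape(-1)


def read_observable(path) -> QuadraticObservable:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    c = 0.0
    l = None
    K_rows: list[list[float]] = []
    in_K = False
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        if in_K:
            K_rows.append([float(x) for x in ln.split()])
            continue
        key, *rest = ln.split()
        if key == "c":
            c = float(rest[0])
        elif key == "l":
            l = np.array([float(x) for x in rest])
        elif key == "K":
            in_K = True
        else:
            raise ValidationError(f"unknown observable key {key!r}")
    if not K_rows and l is None:
        raise ValidationError("observable document must define K and/or l")
    if K_rows:
        K = np.array(K_rows)
    else:
        K = np.zeros((l.size, l.size))
    if l is None:
        l = np.zeros(K.shape[0])
    return QuadraticObservable(K=K, l=l, c=c)


def write_observable(path, obs: QuadraticObservable) -> None:
    with open(path, "w") as fh:
        fh.write(f"c {float(obs.c)!r}\n")
        fh.write("l " + " ".join(f"{float(x)!r}" for x in obs.l) + "\n")
        fh.write("K\n")
        for row in obs.K:
            fh.write(" ".join(f"{float(x)!r}" for x in row) + "\n")


def write_variance_curve(path, curve: VarianceCurve, header_meta: dict | None = None
                         ) -> None:
    """CSV with header ``mu,sigma2,spectral_bound,limit`` and ``#`` config echo."""
    bounds = (curve.spectral_bounds if curve.spectral_bounds is not None
              else np.full_like(curve.mu_values, np.nan))
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("mu,sigma2,spectral_bound,limit\n")
        for mu, s2, sb in zip(curve.mu_values, curve.sigma2_values, bounds):
            fh.write(f"{mu:.17g},{s2:.17g},{sb:.17g},{curve.limit_value:.17g}\n")


def write_sweep(path, table: pd.DataFrame, header_meta: dict | None = None) -> None:
    """Sweep CSV ``gamma,mu,mean,std,stderr,n_replicates`` with config echo."""
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        table.to_csv(fh, index=False)
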