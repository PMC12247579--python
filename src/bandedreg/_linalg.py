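"""Cholesky helpers with progressive jitter and a factorization counter.

All symmetric positive-definite solves in the package go through
:func:`chol_factor`.  On failure a relative jitter of ``1e-10 * mean(diag)``
is added to the diagonal, escalating by factors of 10 up to ``1e-6``, after
which a :class:`~bandedreg.exceptions.NumericalError` is raised.  The
module-level counter exists so tests can assert how many posterior-system
factorizations a fit performed (one per EM iteration, independent of the
number of targets).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .exceptions import NumericalError

#: jitter ladder, relative to mean(diag)
_JITTERS = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)

#: number of successful calls to :func:`chol_factor` (monotone; tests read deltas)
n_factorizations = 0


def chol_factor(A: np.ndarray, context: str = "") -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of a symmetric PD matrix, with jitter escalation.

    Returns ``(L, jitter)`` where ``A + jitter*I ~= L @ L.T``.
    """
    global n_factorizations
    A = np.asarray(A, dtype=float)
    scale = float(np.mean(np.diag(A)))
    if not np.isfinite(scale):
        raise NumericalError(f"non-finite diagonal in {context or 'matrix'}")
    for rel in _JITTERS:
        jitter = rel * scale
        try:
            L = linalg.cholesky(
                A + jitter * np.eye(A.shape[0]) if jitter else A, lower=True
            )
        except linalg.LinAlgError:
            continue
        n_factorizations += 1
        return L, jitter
    raise NumericalError(
        f"matrix not positive definite after jitter up to {_JITTERS[-1]:g}"
        + (f" ({context})" if context else "")
    )


def chol_solve(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``(L L^T) x = B`` given the lower factor L."""
    return linalg.cho_solve((L, True), B)


def chol_inverse(L: np.ndarray) -> np.ndarray:
    """Dense inverse of ``L L^T``; symmetrized."""
    inv = linalg.cho_solve((L, True), np.eye(L.shape[0]))
    return 0.5 * (inv + inv.T)


def chol_logdet(L: np.ndarray) -> float:
    """log-determinant of ``L L^T``."""
    return 2.0 * float(np.sum(np.log(np.diag(L))))
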