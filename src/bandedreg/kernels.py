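"""Covariance kernels for smoothness priors on weight profiles."""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError

_SQRT3 = np.sqrt(3.0)


def matern_covariance(size: int, h: float) -> np.ndarray:
    """Matérn covariance of order 3/2 over integer positions ``0..size-1``.

    ``K[k, i] = (1 + sqrt(3)|k-i|/h) * exp(-sqrt(3)|k-i|/h)``

    Used as the fixed within-group prior correlation ``Omega_j`` to encourage
    once-differentiable smooth weight profiles (e.g. FIR filters across time
    lags or spectral channels).  The length scale ``h`` sets how many
    neighbouring weights co-vary; ``h -> 0`` recovers the identity
    (independent weights) and ``h -> inf`` a constant (rank-one) matrix.

    Parameters
    ----------
    size : int
        Matrix dimension (the group size D_j); >= 1.
    h : float
        Positive length scale, in units of column index.
    """
    size = int(size)
    if size < 1:
        raise DomainError(f"size must be >= 1, got {size}")
    if not (h > 0):
        raise DomainError(f"length scale h must be positive, got {h}")
    d = np.abs(np.subtract.outer(np.arange(size), np.arange(size))) / float(h)
    return (1.0 + _SQRT3 * d) * np.exp(-_SQRT3 * d)
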