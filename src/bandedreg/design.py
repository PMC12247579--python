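"""Grouped design matrices.

A grouped design is an ``M x D`` predictor matrix whose columns are
partitioned into ``J`` contiguous, named blocks ``X = [F_1, ..., F_J]``.
Each block is a *feature group* (a "band"): a stimulus feature subset in an
encoding model, or all time-lag copies of one recording channel in a
decoding model.  The partition drives the block structure of the prior
covariance, so every group carries its own shrinkage scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DimensionError, DomainError


@dataclass(frozen=True)
class GroupedDesign:
    """An ``M x D`` design matrix with a contiguous partition into named groups.

    Parameters
    ----------
    X : ndarray, shape (M, D)
        Predictor matrix.  Must be finite.
    names : tuple of str
        One name per group, in column order.
    starts, stops : ndarray of int
        Half-open column ranges ``[starts[j], stops[j])`` per group; ranges
        must be contiguous, disjoint and jointly cover all D columns.
    """

    X: np.ndarray
    names: tuple[str, ...]
    starts: np.ndarray = field(repr=False)
    stops: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=int))
        object.__setattr__(self, "stops", np.asarray(self.stops, dtype=int))
        if X.ndim != 2:
            raise DimensionError(f"X must be 2-D, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise DomainError("design matrix contains non-finite entries")
        J = len(self.names)
        if J == 0:
            raise DimensionError("at least one predictor group is required")
        if len(self.starts) != J or len(self.stops) != J:
            raise DimensionError("names/starts/stops length mismatch")
        if self.starts[0] != 0 or self.stops[-1] != X.shape[1]:
            raise DimensionError("group ranges must cover all columns")
        if np.any(self.stops <= self.starts):
            raise DimensionError("every group needs at least one column")
        if J > 1 and np.any(self.starts[1:] != self.stops[:-1]):
            raise DimensionError("group column ranges must be contiguous and ordered")
        if len(set(self.names)) != J:
            raise DimensionError("group names must be unique")

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.names)

    @property
    def sizes(self) -> np.ndarray:
        """Number of columns D_j per group."""
        return self.stops - self.starts

    def group_slice(self, key: int | str) -> slice:
        j = self.names.index(key) if isinstance(key, str) else key
        return slice(int(self.starts[j]), int(self.stops[j]))

    def block(self, key: int | str) -> np.ndarray:
        """The columns F_j of one group."""
        return self.X[:, self.group_slice(key)]

    def group_of_column(self) -> np.ndarray:
        """Group index for each of the D columns."""
        out = np.empty(self.n_predictors, dtype=int)
        for j in range(self.n_groups):
            out[self.starts[j]: self.stops[j]] = j
        return out

    def permuted(self, order: Sequence[int]) -> "GroupedDesign":
        """A new design with groups reordered (columns moved accordingly)."""
        order = list(order)
        if sorted(order) != list(range(self.n_groups)):
            raise DimensionError("order must be a permutation of group indices")
        blocks = [(self.names[j], self.block(j)) for j in order]
        return GroupedDesign.from_blocks(blocks)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_blocks(
        cls, blocks: Sequence[tuple[str, np.ndarray]]
    ) -> "GroupedDesign":
        """Concatenate named feature blocks sharing a row count into a design."""
        if len(blocks) == 0:
            raise DimensionError("empty block list")
        mats, names, sizes = [], [], []
        n_rows = None
        for name, mat in blocks:
            mat = np.atleast_2d(np.asarray(mat, dtype=float))
            if mat.ndim != 2:
                raise DimensionError(f"block {name!r} is not 2-D")
            if mat.shape[1] == 0:
                raise DimensionError(f"block {name!r} has no columns")
            if n_rows is None:
                n_rows = mat.shape[0]
            elif mat.shape[0] != n_rows:
                raise DimensionError(
                    f"block {name!r} has {mat.shape[0]} rows, expected {n_rows}"
                )
            mats.append(mat)
            names.append(str(name))
            sizes.append(mat.shape[1])
        stops = np.cumsum(sizes)
        starts = stops - np.asarray(sizes)
        return cls(np.hstack(mats), tuple(names), starts, stops)

    @classmethod
    def from_sizes(
        cls, X: np.ndarray, sizes: Sequence[int], names: Sequence[str] | None = None
    ) -> "GroupedDesign":
        """Partition an existing matrix into groups of the given column counts."""
        X = np.asarray(X, dtype=float)
        sizes = np.asarray(list(sizes), dtype=int)
        if sizes.sum() != X.shape[1]:
            raise DimensionError(
                f"group sizes sum to {sizes.sum()} but X has {X.shape[1]} columns"
            )
        if names is None:
            names = [f"F{j + 1}" for j in range(len(sizes))]
        stops = np.cumsum(sizes)
        return cls(X, tuple(str(n) for n in names), stops - sizes, stops)


def make_grouped_design(
    blocks: Sequence[tuple[str, np.ndarray]]
) -> GroupedDesign:
    """Build a :class:`GroupedDesign` from an ordered list of (name, matrix)."""
    return GroupedDesign.from_blocks(blocks)


def center_columns(
    X: np.ndarray, y: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray | None]:
    """Remove column means from predictors and targets.

    The regression model carries no intercept, so predictors and targets are
    centered and the means stored for re-use at prediction time.

    Returns ``(X_centered, y_centered, x_means, y_means)``; the y entries are
    None when ``y`` is None.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DomainError("X contains non-finite entries")
    x_means = X.mean(axis=0)
    Xc = X - x_means
    if y is None:
        return Xc, None, x_means, None
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DomainError("y contains non-finite entries")
    y_means = y.mean(axis=0)
    return Xc, y - y_means, x_means, y_means


def build_lagged_design(
    series: np.ndarray,
    lags: Sequence[int],
    channel_names: Sequence[str] | None = None,
) -> tuple[GroupedDesign, np.ndarray]:
    """Time-lagged design from a multichannel series, one group per channel.

    Column ``(c, l)`` holds ``series[t - l, c]``.  Rows where any lag falls
    outside the series are dropped (valid-sample convention); the returned
    index array gives the surviving time points ``t``, so targets can be
    aligned with ``y[kept]``.

    Parameters
    ----------
    series : ndarray, shape (M,) or (M, C)
        Multichannel time series.
    lags : sequence of int
        Sample offsets; positive lags look back in time.  ``|lag| < M``.

    Returns
    -------
    design : GroupedDesign with ``D = C * len(lags)`` columns; group j holds
        all lag copies of channel j.
    kept : ndarray of int, the retained row indices into the original series.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    M, C = series.shape
    lags = [int(l) for l in lags]
    if len(lags) == 0:
        raise DimensionError("lags must be non-empty")
    if any(abs(l) >= M for l in lags):
        raise DomainError(f"lag magnitude must be < {M}")
    lo = max(0, max(lags))
    hi = M + min(0, min(lags))
    if hi <= lo:
        raise DomainError("lag span leaves no valid samples")
    kept = np.arange(lo, hi)
    if channel_names is None:
        channel_names = [f"ch{c}" for c in range(C)]
    blocks = []
    for c in range(C):
        cols = np.column_stack([series[kept - l, c] for l in lags])
        blocks.append((str(channel_names[c]), cols))
    return GroupedDesign.from_blocks(blocks), kept
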