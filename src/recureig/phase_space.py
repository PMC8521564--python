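"""Phase-space reconstruction and fuzzy recurrence plots.

A scalar time series is lifted into an ``m``-dimensional phase space by
time-delay embedding, the phase-space vectors are soft-partitioned with
fuzzy c-means (FCM), and the pairwise recurrence structure is expressed as
a fuzzy recurrence plot (FRP): a symmetric matrix in [0, 1] whose entry
(i, k) is the max-min composed membership similarity of states i and k,
with a unit diagonal (every state trivially recurs with itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingConfig",
    "FuzzyPartition",
    "embed",
    "fcm_partition",
    "frp_from_partition",
    "build_frp",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Time-delay embedding parameters.

    Parameters
    ----------
    m : int
        Embedding dimension (number of delayed coordinates), >= 1.
    tau : int
        Time delay between successive coordinates, >= 1.
    """

    m: int = 4
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"time delay tau must be >= 1, got {self.tau}")

    def min_length(self) -> int:
        """Shortest series that admits this embedding."""
        return (self.m - 1) * self.tau + 1


@dataclass
class FuzzyPartition:
    """Result of a fuzzy c-means run.

    Attributes
    ----------
    U : ndarray, shape (M, c)
        Membership grades; each row sums to 1.
    V : ndarray, shape (c, m)
        Cluster centers.
    converged : bool
        Whether the stopping tolerance was reached before ``max_iter``.
    objective_trace : list of float
        FCM objective after each iteration; non-increasing.
    """

    U: np.ndarray
    V: np.ndarray
    converged: bool
    objective_trace: list = field(default_factory=list)

    @property
    def c(self) -> int:
        return self.U.shape[1]


def _as_series(series) -> np.ndarray:
    t = np.asarray(series, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("series must be a non-empty 1-D sequence of scalars")
    if not np.all(np.isfinite(t)):
        raise ValueError("series contains non-finite values")
    return t


def embed(series, cfg: EmbeddingConfig) -> np.ndarray:
    """Time-delay embed a scalar series into phase space.

    Returns the M x m matrix X whose row i is
    ``(t_i, t_{i+tau}, ..., t_{i+(m-1)tau})`` with ``M = N - (m-1)*tau``.
    """
    t = _as_series(series)
    n = t.size
    min_n = cfg.min_length()
    if n < min_n:
        raise ValueError(
            f"series of length {n} too short for m={cfg.m}, tau={cfg.tau}; "
            f"need N >= {min_n}"
        )
    m_rows = n - (cfg.m - 1) * cfg.tau
    cols = [t[j * cfg.tau : j * cfg.tau + m_rows] for j in range(cfg.m)]
    return np.column_stack(cols)


def _fcm_memberships(d2: np.ndarray, fuzzifier: float) -> np.ndarray:
    """Membership update from squared distances, shape (M, c).

    Points at zero distance from a center get crisp membership to the
    lowest-index such center, so exactly coincident states compose to full
    recurrence (the binary recurrence-plot limit).
    """
    M, c = d2.shape
    U = np.zeros((M, c))
    zero_rows = np.min(d2, axis=1) <= 0.0
    if np.any(zero_rows):
        idx = np.argmax(d2[zero_rows] <= 0.0, axis=1)
        U[np.flatnonzero(zero_rows), idx] = 1.0
    ok = ~zero_rows
    if np.any(ok):
        power = 1.0 / (fuzzifier - 1.0)
        inv = d2[ok] ** -power
        U[ok] = inv / inv.sum(axis=1, keepdims=True)
    return U


def fcm_partition(
    X: np.ndarray,
    c: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = 0,
) -> FuzzyPartition:
    """Partition phase-space vectors with fuzzy c-means.

    Alternating optimization of the standard FCM objective
    ``J = sum_ij u_ij^f ||x_i - v_j||^2`` with Euclidean distances.
    Initialization is a random row-stochastic membership matrix drawn from
    the given seed; iteration stops when ``max|dU| < tol`` or after
    ``max_iter`` passes.

    Parameters
    ----------
    X : ndarray, shape (M, m)
        Phase-space vectors (rows).
    c : int
        Number of clusters, 1 <= c <= M.
    fuzzifier : float
        Fuzziness exponent f > 1; 2.0 is the conventional choice.
    seed : int or None
        Seed for the membership initialization; fixed seed gives a
        bitwise-identical partition.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = X.shape[0]
    if not 1 <= c <= M:
        raise ValueError(f"cluster count c={c} must satisfy 1 <= c <= M={M}")
    if fuzzifier <= 1.0:
        raise ValueError(f"fuzzifier must be > 1, got {fuzzifier}")
    if c == 1:
        center = X.mean(axis=0, keepdims=True)
        j = float(np.sum((X - center) ** 2))
        return FuzzyPartition(np.ones((M, 1)), center, True, [j])

    rng = np.random.default_rng(seed)
    U = rng.random((M, c))
    U /= U.sum(axis=1, keepdims=True)

    degenerate = bool(np.all(np.ptp(X, axis=0) == 0.0))

    trace: list = []
    converged = False
    for _ in range(max_iter):
        W = U**fuzzifier
        denom = W.sum(axis=0)[:, None]
        # a cluster that lost all weight (can happen once crisp zero-distance
        # assignment kicks in) is re-centered at the data mean
        V = np.where(denom > 0, (W.T @ X) / np.where(denom > 0, denom, 1.0),
                     X.mean(axis=0))
        # squared Euclidean distances point->center, clipped against
        # tiny negative round-off
        d2 = np.maximum(
            np.sum(X**2, axis=1)[:, None] - 2.0 * X @ V.T + np.sum(V**2, axis=1)[None, :],
            0.0,
        )
        U_new = _fcm_memberships(d2, fuzzifier)
        trace.append(float(np.sum(U_new**fuzzifier * d2)))
        delta = float(np.max(np.abs(U_new - U)))
        U = U_new
        if delta < tol:
            converged = True
            break

    if degenerate:
        warnings.warn(
            "all phase-space vectors are identical; FCM centers coincide",
            RuntimeWarning,
            stacklevel=2,
        )
    return FuzzyPartition(U, V, converged, trace)


def frp_from_partition(U: np.ndarray) -> np.ndarray:
    """Compose memberships into a fuzzy recurrence plot.

    ``R[i, k] = max_j min(u_ij, u_kj)`` (max-min transitive composition),
    with the diagonal forced to 1 by reflexivity. Symmetric by
    construction; all entries lie in [0, 1].
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if np.any(U < 0.0) or np.any(U > 1.0):
        raise ValueError("membership grades must lie in [0, 1]")
    M = U.shape[0]
    # max over j of elementwise min; O(M^2 c) but chunked to bound memory
    R = np.empty((M, M))
    chunk = max(1, int(4e6) // max(U.size, 1))
    for start in range(0, M, chunk):
        stop = min(start + chunk, M)
        R[start:stop] = np.minimum(U[start:stop, None, :], U[None, :, :]).max(axis=2)
    np.fill_diagonal(R, 1.0)
    # exact symmetry regardless of float reduction order
    return np.maximum(R, R.T)


def build_frp(
    series,
    cfg: EmbeddingConfig,
    c: int = 3,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = 0,
) -> np.ndarray:
    """Series -> embed -> FCM -> FRP, returning the M x M fuzzy recurrence plot."""
    try:
        X = embed(series, cfg)
    except ValueError as err:
        raise ValueError(f"embedding: {err}") from err
    try:
        part = fcm_partition(X, c, fuzzifier=fuzzifier, tol=tol, max_iter=max_iter, seed=seed)
    except ValueError as err:
        raise ValueError(f"clustering: {err}") from err
    return frp_from_partition(part.U)
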