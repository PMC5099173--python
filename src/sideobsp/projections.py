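"""Projector algebra: orthogonal complements, oblique projectors and GLS.

An oblique subspace projector maps a vector onto a target subspace
``span(A_k)`` *along* a reference subspace ``span(A_rest)``: the projected
vector keeps the same orthogonal projection onto the complement of the
reference subspace as the original.  When the two subspaces are orthogonal
the oblique projector degenerates to the familiar orthogonal projector on
``span(A_k)``.  This is the algebraic core of the decomposition solver: the
contribution of one input channel is extracted along the subspace spanned by
every other channel, which is what removes cross-talk between correlated
regressors.

The solver itself never materializes the oblique projector (the regularized
normal equations only need products with the complement projector ``Q``);
the explicit constructions here exist for verification, teaching and tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .config import DEFAULT_TOLERANCES, ToleranceConfig

__all__ = [
    "BlockPartition",
    "ProjectorPair",
    "IllPosedProjectionWarning",
    "complement_projector",
    "apply_complement",
    "oblique_projector",
    "gls_estimate",
    "equivalent_ls_solution",
]


class IllPosedProjectionWarning(UserWarning):
    """Raised when target and reference subspaces overlap.

    Overlapping subspaces make the oblique projection ill-defined (the
    projector norm diverges); computation proceeds with the pseudoinverse,
    and downstream Tikhonov regularization mitigates the instability.
    """


@dataclass(frozen=True)
class BlockPartition:
    """One target block ``A_k`` and the concatenated remaining blocks."""

    A_k: np.ndarray
    A_rest: np.ndarray
    k: int

    def __post_init__(self) -> None:
        A_k = np.atleast_2d(np.asarray(self.A_k, dtype=float))
        A_rest = np.asarray(self.A_rest, dtype=float)
        if A_rest.ndim == 1:
            A_rest = A_rest.reshape(-1, 1) if A_rest.size else A_rest.reshape(A_k.shape[0], 0)
        object.__setattr__(self, "A_k", A_k)
        object.__setattr__(self, "A_rest", A_rest)
        if A_rest.size and A_rest.shape[0] != A_k.shape[0]:
            raise ValueError(
                f"A_k and A_rest must share row count; got {A_k.shape[0]} vs {A_rest.shape[0]}"
            )
        if not np.isfinite(A_k).all() or (A_rest.size and not np.isfinite(A_rest).all()):
            raise ValueError("block partition contains non-finite entries")


@dataclass(frozen=True)
class ProjectorPair:
    """Complement projector Q and oblique projector for one block.

    ``Q`` projects orthogonally onto the null space of ``A_rest.T`` (it
    annihilates the reference block); ``P_oblique`` projects onto
    ``span(A_k)`` along ``span(A_rest)``.
    """

    Q: np.ndarray
    P_oblique: np.ndarray
    rank_Q: int
    cond_report: dict


def _validate_matrix(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M.reshape(-1, 1)
    if M.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array")
    if M.shape[0] < 1:
        raise ValueError(f"{name} must have at least one row")
    if not np.isfinite(M).all():
        raise ValueError(f"{name} contains non-finite entries")
    return M


def _rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    return int(np.linalg.matrix_rank(M))


def complement_projector(A_rest: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the null space of ``A_rest.T``.

    Returns ``Q = I - A_rest (A_rest.T A_rest)^+ A_rest.T``, computed from an
    orthonormal range basis (SVD) for numerical symmetry.  An empty
    ``A_rest`` (zero columns) yields the identity.
    """
    A_rest = np.asarray(A_rest, dtype=float)
    if A_rest.ndim == 1:
        A_rest = A_rest.reshape(-1, 1)
    n = A_rest.shape[0]
    if n < 1:
        raise ValueError("A_rest must have at least one row")
    if A_rest.size == 0:
        return np.eye(n)
    if not np.isfinite(A_rest).all():
        raise ValueError("A_rest contains non-finite entries")
    U, s, _ = linalg.svd(A_rest, full_matrices=False)
    cutoff = max(A_rest.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > cutoff))
    Ur = U[:, :r]
    return np.eye(n) - Ur @ Ur.T


def apply_complement(A_rest: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Apply Q (complement projector of ``A_rest``) to ``M`` without forming Q.

    Computes ``M - A_rest @ lstsq(A_rest, M)``, i.e. the residual of the
    least-squares fit of each column of ``M`` against ``A_rest``.  Memory is
    O(N * cols) instead of O(N^2), the supported path for long records.
    """
    M = np.asarray(M, dtype=float)
    A_rest = np.asarray(A_rest, dtype=float)
    if A_rest.ndim == 1:
        A_rest = A_rest.reshape(-1, 1)
    if A_rest.size == 0:
        return M.copy()
    coef, *_ = linalg.lstsq(A_rest, M, lapack_driver="gelsd")
    return M - A_rest @ coef


def oblique_projector(
    part: BlockPartition, tol: ToleranceConfig = DEFAULT_TOLERANCES
) -> ProjectorPair:
    """Oblique projector onto ``span(A_k)`` along ``span(A_rest)``.

    ``P = A_k (A_k.T Q A_k)^+ A_k.T Q`` with ``Q`` the complement projector
    of ``A_rest``.  If the two subspaces overlap (detected through the rank
    of the stacked matrix) an :class:`IllPosedProjectionWarning` is emitted
    and the pseudoinverse proceeds regardless.
    """
    A_k, A_rest = part.A_k, part.A_rest
    Q = complement_projector(A_rest)
    _warn_if_overlapping(A_k, A_rest)
    G = A_k.T @ Q @ A_k
    G_pinv, sv_min, rank_G = _pinv_with_report(G, tol, n_rows=A_k.shape[0])
    P = A_k @ G_pinv @ A_k.T @ Q
    rank_Q = A_k.shape[0] - _rank(A_rest)
    report = {"smallest_retained_sv": sv_min, "rank_AkQAk": rank_G}
    return ProjectorPair(Q=Q, P_oblique=P, rank_Q=rank_Q, cond_report=report)


def _warn_if_overlapping(A_k: np.ndarray, A_rest: np.ndarray) -> bool:
    if A_rest.size == 0:
        return False
    stacked = np.hstack([A_k, A_rest])
    overlap = _rank(stacked) < _rank(A_k) + _rank(A_rest)
    if overlap:
        warnings.warn(
            "target and reference subspaces overlap "
            f"(rank([A_k A_rest]) = {_rank(stacked)} < "
            f"{_rank(A_k)} + {_rank(A_rest)}); the oblique projection is "
            "ill-defined and proceeds via pseudoinverse",
            IllPosedProjectionWarning,
            stacklevel=3,
        )
    return overlap


def _pinv_with_report(G: np.ndarray, tol: ToleranceConfig, n_rows: int | None = None):
    """SVD pseudoinverse with a relative cutoff of max(dim)*eps*sigma_max.

    For Gram matrices ``A'QA`` the rounding floor scales with the data row
    count of ``A``, so callers pass it as ``n_rows`` to widen the cutoff
    accordingly.
    """
    U, s, Vt = linalg.svd(G)
    if tol.pinv_rtol is None:
        dim = max(G.shape + ((n_rows,) if n_rows else ()))
        cutoff = dim * np.finfo(float).eps * (s[0] if s.size else 0.0)
    else:
        cutoff = tol.pinv_rtol * (s[0] if s.size else 0.0)
    keep = s > cutoff
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    sv_min = float(s[keep].min()) if keep.any() else 0.0
    return Vt.T @ (s_inv[:, None] * U.T), sv_min, int(keep.sum())


def gls_estimate(A: np.ndarray, y: np.ndarray, Sigma_inv: np.ndarray) -> np.ndarray:
    """Generalized least-squares estimate ``(A.T W A)^+ A.T W y``.

    With ``W = I`` this is ordinary least squares; with ``W`` equal to the
    complement projector of the other blocks, the fitted values ``A x_hat``
    realize an (idempotent, non-symmetric) oblique projection of ``y``.
    """
    A = _validate_matrix(A, "A")
    y = np.asarray(y, dtype=float).ravel()
    W = np.asarray(Sigma_inv, dtype=float)
    if y.shape[0] != A.shape[0]:
        raise ValueError(f"y has length {y.shape[0]}, expected {A.shape[0]}")
    if W.shape != (A.shape[0], A.shape[0]):
        raise ValueError(f"Sigma_inv must be {A.shape[0]} x {A.shape[0]}, got {W.shape}")
    if not np.allclose(W, W.T, atol=1e-10 * max(1.0, abs(W).max())):
        raise ValueError("Sigma_inv must be symmetric")
    G_pinv, _, _ = _pinv_with_report(A.T @ W @ A, DEFAULT_TOLERANCES, n_rows=A.shape[0])
    return G_pinv @ (A.T @ W @ y)


def equivalent_ls_solution(
    part: BlockPartition, y: np.ndarray, tol: ToleranceConfig = DEFAULT_TOLERANCES
) -> np.ndarray:
    """Per-block estimate ``(A_k.T Q A_k)^+ A_k.T Q y``.

    This is the least-squares solution of the Q-weighted regression and is
    provably identical to solving the oblique-projected problem with the
    projector formed explicitly; tests exercise that identity.  With an
    empty reference block it reduces to ordinary least squares on ``A_k``.
    """
    y = np.asarray(y, dtype=float).ravel()
    A_k, A_rest = part.A_k, part.A_rest
    if y.shape[0] != A_k.shape[0]:
        raise ValueError(f"y has length {y.shape[0]}, expected {A_k.shape[0]}")
    _warn_if_overlapping(A_k, A_rest)
    QA_k = apply_complement(A_rest, A_k)
    Qy = apply_complement(A_rest, y.reshape(-1, 1)).ravel()
    G = A_k.T @ QA_k
    G_pinv, _, _ = _pinv_with_report(G, tol, n_rows=A_k.shape[0])
    return G_pinv @ (A_k.T @ Qy)
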