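"""Oblique factor rotation by gradient projection.

Implements the Jennrich gradient-projection algorithm for oblique rotation
with the quartimin criterion (direct oblimin, gamma = 0).  Given an
unrotated loading matrix A (I x k), the algorithm searches over oblique
rotation matrices T (columns normalized) minimizing Q(Lambda) with
Lambda = A (T')^{-1}; the factor correlation matrix is Phi = T'T.
"""

from __future__ import annotations

import numpy as np

from .errors import ConvergenceError

__all__ = ["oblimin_rotate", "quartimin_criterion"]


def quartimin_criterion(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin value and gradient: Q = sum_i sum_{j != l} L_ij^2 L_il^2 / 4."""
    L2 = L**2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    gq = L * (L2 @ N)
    f = float(np.sum(L2 * (L2 @ N)) / 4.0)
    return f, gq


def oblimin_rotate(
    A: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate ``A`` obliquely to quartimin simple structure.

    Returns ``(Lambda, Phi, T)`` — the rotated pattern matrix, the factor
    correlation matrix, and the rotation matrix.  Raises
    :class:`ConvergenceError` if the projection steps stall without meeting
    the gradient tolerance.
    """
    A = np.asarray(A, dtype=float)
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.ones((1, 1)), np.ones((1, 1))
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, gq = quartimin_criterion(L)
    G = -(L.T @ gq @ Ti).T
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X**2, axis=0))
            Tt = X @ np.diag(v)
            try:
                Ti = np.linalg.inv(Tt)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            L = A @ Ti.T
            ft, gq = quartimin_criterion(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ gq @ Ti).T
    if not converged:
        # re-check: a flat criterion (e.g. perfect simple structure) is fine
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        if np.sqrt(np.sum(Gp**2)) >= 10 * tol:
            raise ConvergenceError("oblimin rotation did not converge")
    Phi = T.T @ T
    return L, Phi, T
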