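"""Riemannian geometry on symmetric positive-definite (SPD) matrices.

Spatial covariance matrices of multichannel EEG epochs are SPD and live on a
curved manifold; treating them as flat Euclidean objects discards that
structure.  Under the affine-invariant metric the manifold admits closed-form
exponential/logarithmic maps at any base point,

    Exp_P(S) = P^{1/2} expm(P^{-1/2} S P^{-1/2}) P^{1/2}
    Log_P(Q) = P^{1/2} logm(P^{-1/2} Q P^{-1/2}) P^{1/2}

a distance d(P, Q) = ||logm(P^{-1/2} Q P^{-1/2})||_F, and a Frechet (geometric)
mean computed by fixed-point iteration.  Mapping a set of covariances into the
tangent space at their Frechet mean and vectorizing yields n(n+1)/2 Euclidean
features per matrix, which ordinary classifiers can consume.

All matrix functions go through symmetric eigendecompositions with an
eigenvalue floor, which is exact for symmetric input and numerically stable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "is_spd",
    "check_spd",
    "covariance",
    "sqrtm_spd",
    "invsqrtm_spd",
    "logm_spd",
    "expm_sym",
    "exp_map",
    "log_map",
    "riemannian_distance",
    "riemannian_mean",
    "tangent_vectorize",
    "tangent_unvectorize",
    "tangent_space",
    "untangent_space",
]

_EIG_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    """Frechet-mean iteration failed to reach tolerance within max_iter."""


def _check_symmetric(A: np.ndarray, rtol: float = 1e-10, name: str = "matrix") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square 2-D, got shape {A.shape}")
    scale = max(np.abs(A).max(), 1.0)
    if np.abs(A - A.T).max() > rtol * scale:
        raise ValueError(f"{name} is not symmetric within tolerance")
    return 0.5 * (A + A.T)


def is_spd(A: np.ndarray, rtol: float = 1e-10) -> bool:
    """True if ``A`` is symmetric with strictly positive eigenvalues."""
    try:
        A = _check_symmetric(A, rtol)
    except ValueError:
        return False
    return bool(np.linalg.eigvalsh(A).min() > 0)


def check_spd(A: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate and return a symmetrized SPD matrix, raising otherwise."""
    A = _check_symmetric(A, name=name)
    if np.linalg.eigvalsh(A).min() <= 0:
        raise ValueError(f"{name} is not positive definite")
    return A


def covariance(epoch: np.ndarray, shrinkage: float = 0.0) -> np.ndarray:
    """Spatial covariance of a channels x samples epoch, optionally shrunk.

    The sample covariance C is blended with a scaled identity target,
    ``(1 - shrinkage) * C + shrinkage * mean(diag(C)) * I``, which guarantees
    positive definiteness for any ``shrinkage > 0``.

    Raises
    ------
    ValueError
        If fewer than two samples, or if ``shrinkage == 0`` and the result is
        singular (e.g. duplicated or constant channels).
    """
    X = np.asarray(epoch, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("epoch must be channels x samples with samples > 1")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / (X.shape[1] - 1)
    if shrinkage > 0.0:
        mu = np.trace(C) / C.shape[0]
        C = (1.0 - shrinkage) * C + shrinkage * mu * np.eye(C.shape[0])
    if np.linalg.eigvalsh(0.5 * (C + C.T)).min() <= 0:
        raise ValueError("covariance is singular; use shrinkage > 0")
    return 0.5 * (C + C.T)


def _eigh_fun(A: np.ndarray, fun) -> np.ndarray:
    w, V = np.linalg.eigh(A)
    return (V * fun(w)) @ V.T


def sqrtm_spd(P: np.ndarray) -> np.ndarray:
    """Symmetric square root of an SPD matrix."""
    P = check_spd(P, "P")
    return _eigh_fun(P, lambda w: np.sqrt(np.maximum(w, _EIG_FLOOR)))


def invsqrtm_spd(P: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root of an SPD matrix."""
    P = check_spd(P, "P")
    return _eigh_fun(P, lambda w: 1.0 / np.sqrt(np.maximum(w, _EIG_FLOOR)))


def logm_spd(P: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    P = check_spd(P, "P")
    return _eigh_fun(P, lambda w: np.log(np.maximum(w, _EIG_FLOOR)))


def expm_sym(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    S = _check_symmetric(S, name="S")
    return _eigh_fun(S, np.exp)


def exp_map(P: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Map a symmetric tangent vector ``S`` at base ``P`` onto the manifold."""
    P = check_spd(P, "P")
    S = _check_symmetric(S, name="S")
    if S.shape != P.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs S {S.shape}")
    Ph = sqrtm_spd(P)
    Pih = invsqrtm_spd(P)
    M = expm_sym(0.5 * ((Pih @ S @ Pih) + (Pih @ S @ Pih).T))
    out = Ph @ M @ Ph
    return 0.5 * (out + out.T)


def log_map(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Map a manifold point ``Q`` into the tangent space at base ``P``."""
    P = check_spd(P, "P")
    Q = check_spd(Q, "Q")
    if Q.shape != P.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs Q {Q.shape}")
    Ph = sqrtm_spd(P)
    Pih = invsqrtm_spd(P)
    inner = Pih @ Q @ Pih
    out = Ph @ logm_spd(0.5 * (inner + inner.T)) @ Ph
    return 0.5 * (out + out.T)


def riemannian_distance(P1: np.ndarray, P2: np.ndarray) -> float:
    """Affine-invariant geodesic distance between two SPD matrices.

    Equals ``sqrt(sum(log(lambda_i)^2))`` over the generalized eigenvalues of
    the pencil (P2, P1); invariant under congruence P -> W.T @ P @ W for any
    invertible W.
    """
    P1 = check_spd(P1, "P1")
    P2 = check_spd(P2, "P2")
    Pih = invsqrtm_spd(P1)
    inner = Pih @ P2 @ Pih
    w = np.linalg.eigvalsh(0.5 * (inner + inner.T))
    return float(np.sqrt(np.sum(np.log(np.maximum(w, _EIG_FLOOR)) ** 2)))


def riemannian_mean(
    mats,
    tol: float = 1e-8,
    max_iter: int = 50,
    return_info: bool = False,
):
    """Frechet mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration: M <- Exp_M(step * mean_i Log_M(P_i)), starting from
    the arithmetic mean, with step halving whenever the gradient norm fails to
    decrease.  Converged when the mean tangent vector's Frobenius norm falls
    below ``tol`` (relative to the Frobenius norm of M).
    """
    mats = [check_spd(P, f"mats[{i}]") for i, P in enumerate(mats)]
    if not mats:
        raise ValueError("need at least one matrix")
    if len({P.shape for P in mats}) != 1:
        raise ValueError("all matrices must share a dimension")
    if len(mats) == 1:
        M = mats[0]
        return (M, 0) if return_info else M

    M = 0.5 * (np.mean(mats, axis=0) + np.mean(mats, axis=0).T)
    step = 1.0
    prev_norm = np.inf
    for it in range(1, max_iter + 1):
        Mh = sqrtm_spd(M)
        Mih = invsqrtm_spd(M)
        # gradient in the whitened frame: mean of logm(M^-1/2 P M^-1/2)
        G = np.zeros_like(M)
        for P in mats:
            inner = Mih @ P @ Mih
            G += logm_spd(0.5 * (inner + inner.T))
        G /= len(mats)
        gnorm = np.linalg.norm(G, "fro")
        if gnorm < tol * max(np.linalg.norm(M, "fro"), 1.0):
            return (M, it) if return_info else M
        if gnorm > prev_norm:
            step = max(step / 2.0, 1e-3)
        prev_norm = gnorm
        M = Mh @ expm_sym(step * G) @ Mh
        M = 0.5 * (M + M.T)
    raise ConvergenceError(
        f"Frechet mean did not converge in {max_iter} iterations "
        f"(last gradient norm {prev_norm:.3e})"
    )


def tangent_vectorize(S: np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to length n(n+1)/2 with sqrt(2) off-diagonals.

    The weighting makes the map an isometry: the Euclidean norm of the vector
    equals the Frobenius norm of the matrix.  Inverse: `tangent_unvectorize`.
    """
    S = _check_symmetric(S, name="S")
    n = S.shape[0]
    iu = np.triu_indices(n)
    w = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return S[iu] * w


def tangent_unvectorize(v: np.ndarray) -> np.ndarray:
    """Inverse of `tangent_vectorize`."""
    v = np.asarray(v, dtype=float).ravel()
    n = int(round((np.sqrt(8 * v.size + 1) - 1) / 2))
    if n * (n + 1) // 2 != v.size:
        raise ValueError(f"length {v.size} is not a triangular number")
    iu = np.triu_indices(n)
    w = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    S = np.zeros((n, n))
    S[iu] = v / w
    return S + np.triu(S, 1).T


def tangent_space(mats, base="mean", tol: float = 1e-8, max_iter: int = 50):
    """Map SPD matrices to vectorized tangent coordinates at ``base``.

    Parameters
    ----------
    mats : sequence of SPD arrays
    base : "mean" or SPD array
        Reference point; the Frechet mean of ``mats`` when "mean".

    Returns
    -------
    vectors : (m, n(n+1)/2) array, row order preserved
    base : the resolved SPD base point
    """
    mats = list(mats)
    if not mats:
        raise ValueError("empty matrix set")
    if isinstance(base, str):
        if base != "mean":
            raise ValueError("base must be an SPD matrix or 'mean'")
        base = riemannian_mean(mats, tol=tol, max_iter=max_iter)
    else:
        base = check_spd(np.asarray(base), "base")
    # whitened log-map: vec(base^-1/2 Log_base(P) base^-1/2) — the standard
    # tangent-space coordinates, in which the metric at base is Euclidean
    Bih = invsqrtm_spd(base)
    rows = []
    for P in mats:
        inner = Bih @ check_spd(np.asarray(P)) @ Bih
        rows.append(tangent_vectorize(logm_spd(0.5 * (inner + inner.T))))
    return np.vstack(rows), base


def untangent_space(vectors: np.ndarray, base: np.ndarray):
    """Inverse of `tangent_space`: recover SPD matrices from tangent rows."""
    base = check_spd(np.asarray(base), "base")
    Bh = sqrtm_spd(base)
    out = []
    for v in np.atleast_2d(vectors):
        S = tangent_unvectorize(v)
        out.append(Bh @ expm_sym(S) @ Bh)
    return out
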