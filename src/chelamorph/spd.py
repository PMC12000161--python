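"""Affine-invariant Riemannian geometry on symmetric positive-definite matrices.

Per-sample Ω (averaged-SSCP) matrices live on the SPD manifold equipped
with the affine-invariant metric.  Distances, geodesics, point-to-geodesic
projections, Fréchet means and relative eigenvectors are the machinery
behind the transect analysis:

    d(A, B) = ‖log(A^{-1/2} B A^{-1/2})‖_F
    γ(t)    = A^{1/2} (A^{-1/2} B A^{-1/2})^t A^{1/2}

All matrix functions go through eigendecompositions of symmetrized
inputs with a relative eigenvalue floor, so the routines survive the
badly conditioned matrices that arise from near-degenerate cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "GeodesicPath",
    "NotPositiveDefiniteError",
    "spd_distance",
    "geodesic_point",
    "geodesic",
    "point_to_geodesic",
    "frechet_mean",
    "relative_eigenvectors",
    "spd_log",
    "spd_exp",
    "spd_power",
]

EIG_FLOOR = 1e-12  # relative floor applied to eigenvalues of SPD inputs
DEFAULT_M = 201  # discretization of a geodesic path


class NotPositiveDefiniteError(ValueError):
    """Raised when a matrix required to be SPD has a non-positive eigenvalue."""


def _sym(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def _eigh_spd(a: np.ndarray, name: str = "matrix") -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetrized SPD matrix with validation."""
    w, v = np.linalg.eigh(_sym(np.asarray(a, dtype=float)))
    if w[-1] <= 0 or w[0] <= -1e-10 * abs(w[-1]):
        raise NotPositiveDefiniteError(
            f"{name} is not positive-definite (smallest eigenvalue {w[0]:.3e})"
        )
    w = np.maximum(w, EIG_FLOOR * w[-1])
    return w, v


def _apply(a: np.ndarray, fn, name: str = "matrix") -> np.ndarray:
    w, v = _eigh_spd(a, name)
    return _sym((v * fn(w)) @ v.T)


def spd_power(a: np.ndarray, p: float) -> np.ndarray:
    """Matrix power A^p of an SPD matrix via eigendecomposition."""
    return _apply(a, lambda w: w**p)


def spd_log(a: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (symmetric result)."""
    return _apply(a, np.log)


def spd_exp(s: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (SPD result)."""
    w, v = np.linalg.eigh(_sym(np.asarray(s, dtype=float)))
    return _sym((v * np.exp(w)) @ v.T)


def _whiten(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Return A^{-1/2} B A^{-1/2} (symmetrized)."""
    w, v = _eigh_spd(a, "first argument")
    a_isqrt = (v * (1.0 / np.sqrt(w))) @ v.T
    return _sym(a_isqrt @ _sym(np.asarray(b, dtype=float)) @ a_isqrt)


def spd_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    Equals √(Σ log² λ_k) over the generalized eigenvalues λ of (B, A);
    invariant under joint congruence A → MAMᵀ, B → MBMᵀ.
    """
    w, _ = _eigh_spd(_whiten(a, b), "second argument (whitened)")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def geodesic_point(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Point γ(t) on the affine-invariant geodesic from A (t=0) to B (t=1).

    No extrapolation: ``t`` must lie in [0, 1].
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"geodesic parameter t={t} outside [0, 1]")
    wa, va = _eigh_spd(a, "endpoint A")
    a_sqrt = (va * np.sqrt(wa)) @ va.T
    a_isqrt = (va * (1.0 / np.sqrt(wa))) @ va.T
    mid = _sym(a_isqrt @ _sym(np.asarray(b, dtype=float)) @ a_isqrt)
    wm, vm = _eigh_spd(mid, "whitened B")
    mid_t = (vm * wm**t) @ vm.T
    return _sym(a_sqrt @ mid_t @ a_sqrt)


@dataclass(frozen=True)
class GeodesicPath:
    """A discretized geodesic between two SPD endpoints.

    ``samples[k]`` is γ(ts[k]); ``length`` is the Riemannian distance
    between the endpoints, which the parametrization traverses at
    constant speed.
    """

    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    length: float
    ts: np.ndarray
    samples: np.ndarray  # (m, d, d)

    def point(self, t: float) -> np.ndarray:
        return geodesic_point(self.endpoint_a, self.endpoint_b, t)


def geodesic(a: np.ndarray, b: np.ndarray, m: int = DEFAULT_M) -> GeodesicPath:
    """Discretize the geodesic from A to B at m evenly spaced parameters."""
    if m < 2:
        raise ValueError("need at least 2 geodesic samples")
    wa, va = _eigh_spd(a, "endpoint A")
    a_sqrt = (va * np.sqrt(wa)) @ va.T
    a_isqrt = (va * (1.0 / np.sqrt(wa))) @ va.T
    mid = _sym(a_isqrt @ _sym(np.asarray(b, dtype=float)) @ a_isqrt)
    wm, vm = _eigh_spd(mid, "whitened B")
    log_wm = np.log(wm)
    ts = np.linspace(0.0, 1.0, m)
    samples = np.empty((m, a.shape[0], a.shape[0]))
    for k, t in enumerate(ts):
        mid_t = (vm * np.exp(t * log_wm)) @ vm.T
        samples[k] = _sym(a_sqrt @ mid_t @ a_sqrt)
    return GeodesicPath(
        endpoint_a=np.asarray(a, float),
        endpoint_b=np.asarray(b, float),
        length=float(np.sqrt(np.sum(log_wm**2))),
        ts=ts,
        samples=samples,
    )


def point_to_geodesic(p: np.ndarray, path: GeodesicPath) -> tuple[float, float]:
    """Minimum distance from an SPD point to a discretized geodesic.

    Scans the path's discretization for the closest sample, then refines
    with a bounded golden-section search between that sample's
    neighbours.  Returns ``(distance, t_star)``.
    """
    d = np.array([spd_distance(p, s) for s in path.samples])
    k = int(np.argmin(d))
    lo = path.ts[max(k - 1, 0)]
    hi = path.ts[min(k + 1, len(path.ts) - 1)]
    if hi <= lo:
        return float(d[k]), float(path.ts[k])
    res = optimize.minimize_scalar(
        lambda t: spd_distance(p, path.point(float(t))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if res.fun <= d[k]:
        return float(res.fun), float(res.x)
    return float(d[k]), float(path.ts[k])


def frechet_mean(
    matrices: list[np.ndarray] | np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, dict]:
    """Weighted Fréchet (Karcher) mean under the affine-invariant metric.

    Fixed-point iteration on the tangent-space average:
    M ← M^{1/2} exp(Σ w_i log(M^{-1/2} X_i M^{-1/2})) M^{1/2},
    declared converged when the tangent-mean Frobenius norm drops below
    ``tol``.  Returns ``(mean, info)`` where ``info`` carries the
    convergence flag, iteration count and final residual norm.
    """
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if len(mats) == 0:
        raise ValueError("need at least one matrix")
    if weights is None:
        weights = np.full(len(mats), 1.0 / len(mats))
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    mean = _sym(sum(w * m for w, m in zip(weights, mats)))  # arithmetic init
    residual = np.inf
    for it in range(1, max_iter + 1):
        wm, vm = _eigh_spd(mean, "current mean")
        m_sqrt = (vm * np.sqrt(wm)) @ vm.T
        m_isqrt = (vm * (1.0 / np.sqrt(wm))) @ vm.T
        tangent = np.zeros_like(mean)
        for w, x in zip(weights, mats):
            tangent += w * spd_log(_sym(m_isqrt @ x @ m_isqrt))
        residual = float(np.linalg.norm(tangent))
        mean = _sym(m_sqrt @ spd_exp(tangent) @ m_sqrt)
        if residual < tol:
            return mean, {"converged": True, "iterations": it, "residual": residual}
    return mean, {"converged": False, "iterations": max_iter, "residual": residual}


def relative_eigenvectors(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Relative eigenanalysis of B with respect to A.

    Eigenpairs of A^{-1/2} B A^{-1/2} sorted by descending eigenvalue,
    with the eigenvectors mapped back through A^{1/2} so each column is a
    direction in the original coordinate system (one loading per
    measurement position).  Returns ``(eigenvalues, vectors, degenerate)``
    where ``degenerate`` is True when all eigenvalues are 1 within
    tolerance (B = A; the basis is then arbitrary).  The eigenvalues of
    (A, B) are the reciprocals of those of (B, A).
    """
    wa, va = _eigh_spd(a, "reference A")
    a_sqrt = (va * np.sqrt(wa)) @ va.T
    mid = _whiten(a, b)
    w, v = np.linalg.eigh(_sym(mid))
    order = np.argsort(w)[::-1]
    w = w[order]
    vecs = a_sqrt @ v[:, order]
    # fix sign: largest-magnitude loading of each vector positive
    for j in range(vecs.shape[1]):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    degenerate = bool(np.allclose(w, 1.0, atol=1e-10))
    return w, vecs, degenerate
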