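"""Minimum-volume enclosing ellipsoid (Khachiyan's algorithm) and simple
sampleable regions used by the ellipse-refined ABC estimator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["EllipseRegion", "BoxRegion", "mvee", "fit_region"]


def _unit_ball_log_volume(k: int) -> float:
    return 0.5 * k * np.log(np.pi) - gammaln(0.5 * k + 1.0)


@dataclass(frozen=True)
class EllipseRegion:
    """Ellipsoid {x : (x-center)^T shape (x-center) <= 1}."""

    center: np.ndarray
    shape: np.ndarray  # (K, K) positive definite

    @property
    def volume(self) -> float:
        k = self.center.size
        sign, logdet = np.linalg.slogdet(self.shape)
        return float(np.exp(_unit_ball_log_volume(k) - 0.5 * logdet))

    def contains(self, x: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
        d = np.atleast_2d(x) - self.center
        q = np.einsum("ni,ij,nj->n", d, self.shape, d)
        return q <= 1.0 + rtol

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform draws inside the ellipsoid."""
        k = self.center.size
        g = rng.normal(size=(n, k))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        radii = rng.random(n) ** (1.0 / k)
        # map unit ball -> ellipsoid via shape^{-1/2}
        evals, evecs = np.linalg.eigh(self.shape)
        evals = np.maximum(evals, 1e-300)
        L = evecs @ np.diag(evals ** -0.5) @ evecs.T
        return self.center + (radii[:, None] * g) @ L.T


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box fallback for degenerate point sets."""

    lower: np.ndarray
    upper: np.ndarray

    @property
    def volume(self) -> float:
        return float(np.prod(self.upper - self.lower))

    def contains(self, x: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
        x = np.atleast_2d(x)
        pad = rtol * (self.upper - self.lower + 1.0)
        return ((x >= self.lower - pad) & (x <= self.upper + pad)).all(axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.lower.size))


def mvee(points: np.ndarray, tol: float = 1e-5, max_iter: int = 200) -> EllipseRegion:
    """Minimum-volume ellipsoid enclosing ``points`` (n, K).

    Khachiyan's iterative algorithm; raises LinAlgError for degenerate
    (rank-deficient) point sets.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    n, k = P.shape
    if n < k + 1:
        raise np.linalg.LinAlgError("need at least K+1 points for a full-rank ellipsoid")
    Q = np.column_stack([P, np.ones(n)]).T  # (k+1, n)
    u = np.full(n, 1.0 / n)
    inv_x = np.linalg.inv((Q * u) @ Q.T)
    for it in range(max_iter):
        if it % 64 == 63:  # refresh against rank-1-update drift
            inv_x = np.linalg.inv((Q * u) @ Q.T)
        M = np.einsum("jn,jn->n", Q, inv_x @ Q)
        j = int(np.argmax(M))
        step = (M[j] - k - 1.0) / ((k + 1.0) * (M[j] - 1.0))
        if step <= tol:
            break
        u *= 1.0 - step
        u[j] += step
        # Sherman-Morrison update of inv((1-step) X + step q q^T)
        q = Q[:, j]
        inv_a = inv_x / (1.0 - step)
        w = inv_a @ q
        inv_x = inv_a - np.outer(w, w) * (step / (1.0 + step * (q @ w)))
    center = u @ P
    cov = (P.T * u) @ P - np.outer(center, center)
    shape = np.linalg.inv(cov) / k
    # exact enclosure regardless of how far the iteration converged:
    # rescale so the farthest defining point sits on the boundary
    d = P - center
    q_max = float(np.einsum("ni,ij,nj->n", d, shape, d).max())
    region = EllipseRegion(center, shape / (q_max * (1.0 + tol)))
    return region


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    """Reduce to convex-hull vertices (the MVEE only depends on them)."""
    n, k = points.shape
    if n <= 3 * (k + 1) or n <= 50:
        return points
    if k == 1:
        return points[[int(points[:, 0].argmin()), int(points[:, 0].argmax())]]
    try:
        from scipy.spatial import ConvexHull

        return points[ConvexHull(points).vertices]
    except Exception:
        return points


def fit_region(points: np.ndarray, tol: float = 1e-5) -> EllipseRegion | BoxRegion:
    """MVEE with a bounding-box fallback for degenerate point sets."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    try:
        region = mvee(_hull_vertices(points), tol=tol)
        if not region.contains(points).all() or not np.isfinite(region.volume):
            raise np.linalg.LinAlgError("ellipse fit failed to enclose points")
        return region
    except np.linalg.LinAlgError:
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        span = hi - lo
        pad = 1e-9 * (span + 1.0)
        return BoxRegion(lo - pad, hi + pad)
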