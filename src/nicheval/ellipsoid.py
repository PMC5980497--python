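"""Minimum-volume enclosing ellipsoids (MVE).

The observed niche of a species in environmental space is represented here as
the smallest ellipsoid enclosing the occurrence points (optionally a robust
h-fraction subset of them).  The enclosing ellipsoid is computed with
Khachiyan's first-order barycentric-coordinate ascent, which solves the dual
D-optimal design problem; the algorithm is simple, deterministic, and
accurate to a prescribed relative volume tolerance in low dimension
(here typically d = 2 or 3 retained principal components).

An ellipsoid is the set {x : (x - center)^T A (x - center) <= 1} with A
symmetric positive definite; its volume is V_d * det(A)^(-1/2) where V_d is
the volume of the d-dimensional unit ball.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln


class DegeneratePointsError(ValueError):
    """Point set is affinely dependent: no full-dimensional ellipsoid exists.

    Raised when the points span fewer than d dimensions; reduce the
    dimensionality (e.g. retain fewer principal components) and refit.
    """


def unit_ball_volume(d: int) -> float:
    """Volume of the d-dimensional unit ball: pi^(d/2) / Gamma(d/2 + 1)."""
    return float(np.exp(d / 2 * np.log(np.pi) - gammaln(d / 2 + 1)))


@dataclass
class Ellipsoid:
    """An ellipsoid {x : (x - center)^T shape (x - center) <= 1}."""

    center: np.ndarray
    shape: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).ravel()
        self.shape = np.asarray(self.shape, dtype=float)
        d = self.center.size
        if self.shape.shape != (d, d):
            raise ValueError("shape matrix dimensions do not match center")
        if not np.allclose(self.shape, self.shape.T, atol=1e-9):
            raise ValueError("shape matrix must be symmetric (tol 1e-9)")
        self.shape = (self.shape + self.shape.T) / 2
        eigvals = np.linalg.eigvalsh(self.shape)
        if np.any(eigvals <= 0):
            raise ValueError("shape matrix must be positive definite")

    @property
    def dim(self) -> int:
        return self.center.size

    @property
    def volume(self) -> float:
        sign, logdet = np.linalg.slogdet(self.shape)
        if sign <= 0:
            raise ValueError("shape matrix must be positive definite")
        return unit_ball_volume(self.dim) * float(np.exp(-0.5 * logdet))

    def mahalanobis_sq(self, x: np.ndarray) -> np.ndarray | float:
        """Quadratic form (x - c)^T A (x - c); vectorized over rows of x."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x)
        if pts.shape[1] != self.dim:
            raise ValueError(
                f"point dimension {pts.shape[1]} does not match ellipsoid dim {self.dim}"
            )
        diff = pts - self.center
        m = np.einsum("ij,jk,ik->i", diff, self.shape, diff)
        return float(m[0]) if single else m

    def contains(self, x: np.ndarray, tol: float = 1e-9) -> np.ndarray | bool:
        m = self.mahalanobis_sq(x)
        return m <= 1 + tol

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points uniformly from the ellipsoid interior.

        Uniform points in the unit ball are mapped through the affine
        transform x = center + L^{-T} u where shape = L L^T (Cholesky).
        """
        d = self.dim
        u = rng.standard_normal((n, d))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = rng.random(n) ** (1.0 / d)
        ball = u * r[:, None]
        L = np.linalg.cholesky(self.shape)
        return self.center + np.linalg.solve(L.T, ball.T).T

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "shape": self.shape.tolist(),
            "volume": self.volume,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipsoid":
        return cls(np.array(d["center"]), np.array(d["shape"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Ellipsoid":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _khachiyan(points: np.ndarray, tolerance: float, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Khachiyan barycentric ascent for the minimum enclosing ellipsoid.

    Returns (center, shape).  The returned ellipsoid is rescaled so that
    every input point satisfies the membership inequality; the rescaling
    keeps the volume within a (1 + d * tolerance) factor of the optimum.
    """
    n, d = points.shape
    Q = np.column_stack([points, np.ones(n)])  # lifted points, n x (d+1)
    u = np.full(n, 1.0 / n)
    # Wolfe-Atwood ascent with away steps: at each iteration either increase
    # the weight of the worst-covered point (plus step) or decrease the
    # weight of an over-weighted interior point (away step).  The away steps
    # give linear convergence, unlike the O(1/k) plain Khachiyan ascent.
    for _ in range(max_iter):
        X = Q.T @ (Q * u[:, None])  # (d+1) x (d+1)
        M = np.einsum("ij,ij->i", Q @ np.linalg.inv(X), Q)
        j_plus = int(np.argmax(M))
        eps_plus = M[j_plus] / (d + 1.0) - 1.0
        active = u > 0
        M_active = np.where(active, M, np.inf)
        j_minus = int(np.argmin(M_active))
        eps_minus = 1.0 - M[j_minus] / (d + 1.0)
        if max(eps_plus, eps_minus) <= tolerance:
            break
        if eps_plus >= eps_minus:
            j, maximum = j_plus, M[j_plus]
            step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        else:
            j, minimum = j_minus, M[j_minus]
            step = (minimum - d - 1.0) / ((d + 1.0) * (minimum - 1.0))
            step = max(step, -u[j] / (1.0 - u[j]))  # keep weights feasible
        u *= 1.0 - step
        u[j] += step
        u = np.maximum(u, 0.0)
        u /= u.sum()
    center = points.T @ u
    cov = points.T @ (points * u[:, None]) - np.outer(center, center)
    shape = np.linalg.inv(cov) / d
    shape = (shape + shape.T) / 2
    # guarantee containment: scale so the farthest point sits on the boundary
    diff = points - center
    max_m = float(np.max(np.einsum("ij,jk,ik->i", diff, shape, diff)))
    if max_m > 1.0:
        shape = shape / max_m
    return center, shape


def fit_mve(
    points: np.ndarray,
    coverage: float = 1.0,
    tolerance: float = 1e-7,
    max_iter: int = 10_000,
) -> Ellipsoid:
    """Fit a minimum-volume ellipsoid to a point cloud.

    Parameters
    ----------
    points
        (n, d) array; requires at least d + 1 affinely independent points.
    coverage
        Fraction of points the ellipsoid must enclose.  1.0 (default) gives
        the true minimum ENCLOSING ellipsoid.  Values below 1 give a robust
        variant: points with the largest Mahalanobis distance under the full
        fit are peeled off one at a time (greedy) until ceil(coverage * n)
        remain, then the enclosing ellipsoid of the survivors is returned.
    tolerance
        Relative duality-gap tolerance of the Khachiyan iteration; the fitted
        volume is within (1 + d * tolerance) of the minimum.

    Raises
    ------
    DegeneratePointsError
        If the points are affinely dependent (span < d dimensions).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = points.shape
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    n_keep = max(int(np.ceil(coverage * n)), d + 1)
    if n < d + 1:
        raise DegeneratePointsError(
            f"need at least {d + 1} points in dimension {d}, got {n}"
        )
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(points).max())) < d:
        raise DegeneratePointsError(
            f"points are affinely dependent in dimension {d}; "
            "reduce the dimensionality and refit"
        )
    keep = points
    while len(keep) > n_keep:
        # covariance-based peeling: drop the point most outlying w.r.t. the
        # mean/covariance of the survivors, refusing to break affine
        # independence.  A greedy approximation of the exact h-subset MVE.
        mean = keep.mean(axis=0)
        cov = np.cov(keep.T, ddof=0) + 1e-12 * np.eye(d)
        diff = keep - mean
        m = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
        dropped = False
        for j in np.argsort(m)[::-1]:
            candidate = np.delete(keep, j, axis=0)
            c = candidate - candidate.mean(axis=0)
            if np.linalg.matrix_rank(c, tol=1e-10) == d:
                keep = candidate
                dropped = True
                break
        if not dropped:
            break
    center, shape = _khachiyan(keep, tolerance, max_iter)
    return Ellipsoid(center, shape)


__all__ = [
    "Ellipsoid",
    "fit_mve",
    "unit_ball_volume",
    "DegeneratePointsError",
]
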