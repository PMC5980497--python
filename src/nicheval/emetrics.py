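"""Environmental-space model evaluation.

Geographic evaluation alone cannot tell whether a model predicts suitability
under environments the species was never observed in.  The two indices here
work in the retained principal-component space and take the minimum-volume
ellipsoid (MVE) around all available occurrences as the *observed niche*:

* **Index I — interpolation/extrapolation frequencies.**  The unique
  environmental combinations predicted suitable are partitioned into those
  inside the observed-niche ellipsoid (interpolation: conditions within the
  observed range) and outside it (extrapolation: conditions beyond anything
  observed).  Overbroad models score high on both; overfit models low on
  both.

* **Index II — niche similarity and degree of extrapolation.**  Model fit is
  the Jaccard similarity between the modeled niche and the observed niche;
  the degree of extrapolation is the Euclidean distance (in component units)
  from the observed-niche centroid to the most distant suitable prediction
  outside the MVE.  Two models with equal extrapolation *frequency* can
  extrapolate to mildly vs. wildly un-observed conditions; the distance
  separates them.

Duplicate environments are ignored throughout: all counting is over unique
environmental combinations (deduplicated after rounding to 6 decimals in
component units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ellipsoid import DegeneratePointsError, Ellipsoid, fit_mve
from .espace import EnvSpace
from .geodata import BinaryMap, check_aligned

#: Decimal places (in component units) used to deduplicate environments.
DEDUP_DECIMALS = 6


def _dedup(points: np.ndarray) -> np.ndarray:
    if points.size == 0:
        return points.reshape(0, points.shape[-1] if points.ndim == 2 else 0)
    return np.unique(np.round(points, DEDUP_DECIMALS), axis=0)


def unique_env_points(
    bin_map: BinaryMap,
    space: EnvSpace,
    region_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Unique component-space vectors of the cells predicted suitable.

    Returns a (k, d) array; empty when nothing is suitable.  ``region_mask``
    optionally restricts the cells considered.
    """
    check_aligned(bin_map.geometry, space.geometry)
    suitable = bin_map.suitable.ravel()
    if region_mask is not None:
        suitable = suitable & np.asarray(region_mask, dtype=bool).ravel()
    sel = suitable[space.cell_ids]
    return _dedup(space.scores[sel])


def espace_index_I(
    bin_map: BinaryMap,
    space: EnvSpace,
    observed: Ellipsoid,
    region_mask: np.ndarray | None = None,
) -> tuple[int, int]:
    """Interpolation and extrapolation frequencies (E-space index I).

    Partitions the unique suitable environments by membership in the
    observed-niche ellipsoid: (n_interpolation, n_extrapolation).
    """
    pts = unique_env_points(bin_map, space, region_mask)
    if pts.shape[0] == 0:
        return (0, 0)
    if pts.shape[1] != observed.dim:
        raise ValueError("ellipsoid dimension does not match component space")
    inside = observed.contains(pts)
    n_in = int(np.sum(inside))
    return (n_in, pts.shape[0] - n_in)


def jaccard_similarity(
    modeled: Ellipsoid | np.ndarray,
    observed: Ellipsoid,
    mode: str = "ellipsoid_volume",
    background: np.ndarray | None = None,
    mc_samples: int = 100_000,
    seed: int = 0,
) -> float:
    """Jaccard similarity J = |A intersect B| / |A union B| between niches.

    ``ellipsoid_volume`` mode treats both niches as ellipsoids (``modeled``
    must be an :class:`Ellipsoid`, typically the MVE of the model's suitable
    unique environments) and estimates the intersection volume by uniform
    Monte-Carlo sampling inside the smaller ellipsoid; J is then
    V_int / (V1 + V2 - V_int).

    ``discrete_cells`` mode counts unique background environmental
    combinations: ``modeled`` is the (k, d) suitable point set, ``background``
    the (m, d) unique background combinations, and the observed niche is the
    subset of the background inside ``observed``.  This mode is exact (no
    sampling) and is the natural choice when the prediction does not fill an
    ellipsoidal region.
    """
    if mode == "ellipsoid_volume":
        if not isinstance(modeled, Ellipsoid):
            raise TypeError("ellipsoid_volume mode requires an Ellipsoid")
        if modeled.dim != observed.dim:
            raise ValueError("ellipsoid dimensions differ")
        v1, v2 = modeled.volume, observed.volume
        if v1 + v2 <= 0:
            raise ValueError("zero-volume union")
        small, other = (modeled, observed) if v1 <= v2 else (observed, modeled)
        rng = np.random.default_rng(seed)
        pts = small.sample(mc_samples, rng)
        frac_in = float(np.mean(other.contains(pts)))
        v_int = small.volume * frac_in
        return v_int / (v1 + v2 - v_int)
    if mode == "discrete_cells":
        pts = np.atleast_2d(np.asarray(modeled, dtype=float))
        if background is None:
            raise ValueError("discrete_cells mode requires the background combinations")
        background = _dedup(np.asarray(background, dtype=float))
        if background.shape[0] == 0:
            raise ValueError("empty background")
        inside = np.asarray(observed.contains(background))
        m_keys = {tuple(p) for p in np.round(pts, DEDUP_DECIMALS)} if pts.size else set()
        s_keys = {tuple(p) for p in background[inside]}
        union = m_keys | s_keys
        if not union:
            raise ValueError("zero-volume union")
        return len(m_keys & s_keys) / len(union)
    raise ValueError(f"unknown Jaccard mode {mode!r}")


def extrapolation_distance(
    bin_map: BinaryMap,
    space: EnvSpace,
    observed: Ellipsoid,
    region_mask: np.ndarray | None = None,
) -> float:
    """Degree of extrapolation (E-space index II distance component).

    The Euclidean distance, in raw component units, from the observed-niche
    centroid to the farthest unique suitable environment *outside* the
    ellipsoid; 0 when no suitable environment lies outside.
    """
    pts = unique_env_points(bin_map, space, region_mask)
    if pts.shape[0] == 0:
        return 0.0
    outside = ~np.asarray(observed.contains(pts))
    if not np.any(outside):
        return 0.0
    dists = np.linalg.norm(pts[outside] - observed.center, axis=1)
    return float(np.max(dists))


@dataclass
class ESpaceReport:
    """Bundle of E-space indices I and II for one binary prediction."""

    n_interpolation: int
    n_extrapolation: int
    n_unique_suitable: int
    jaccard: float
    jaccard_mode: str
    extrapolation_distance: float
    mc_samples: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_interpolation": self.n_interpolation,
            "n_extrapolation": self.n_extrapolation,
            "n_unique_suitable": self.n_unique_suitable,
            "jaccard": self.jaccard,
            "jaccard_mode": self.jaccard_mode,
            "extrapolation_distance": self.extrapolation_distance,
            "mc_samples": self.mc_samples,
            "seed": self.seed,
        }


def espace_report(
    bin_map: BinaryMap,
    space: EnvSpace,
    observed: Ellipsoid,
    jaccard_mode: str = "ellipsoid_volume",
    mc_samples: int = 100_000,
    seed: int = 0,
    region_mask: np.ndarray | None = None,
) -> ESpaceReport:
    """E-space indices I and II for one binary prediction.

    In ``ellipsoid_volume`` mode the modeled niche is the MVE fit to the
    model's suitable unique environments; when that MVE cannot be fit (fewer
    than d + 1 points, or a degenerate cloud) the report falls back to
    ``discrete_cells`` mode, recorded in ``jaccard_mode``.
    """
    pts = unique_env_points(bin_map, space, region_mask)
    n_in, n_out = espace_index_I(bin_map, space, observed, region_mask)
    dist = extrapolation_distance(bin_map, space, observed, region_mask)
    bg = _dedup(space.scores)

    mode = jaccard_mode
    if mode == "ellipsoid_volume":
        try:
            modeled = fit_mve(pts) if pts.shape[0] >= space.d + 1 else None
            if modeled is None:
                raise DegeneratePointsError("too few suitable environments")
            j = jaccard_similarity(
                modeled, observed, mode="ellipsoid_volume",
                mc_samples=mc_samples, seed=seed,
            )
        except DegeneratePointsError:
            mode = "discrete_cells"
    if mode == "discrete_cells":
        j = jaccard_similarity(
            pts, observed, mode="discrete_cells", background=bg,
            mc_samples=mc_samples, seed=seed,
        )
    return ESpaceReport(
        n_interpolation=n_in,
        n_extrapolation=n_out,
        n_unique_suitable=int(pts.shape[0]),
        jaccard=float(j),
        jaccard_mode=mode,
        extrapolation_distance=dist,
        mc_samples=mc_samples,
        seed=seed,
    )


def observed_niche(
    occ_scores: np.ndarray,
    coverage: float = 1.0,
    tolerance: float = 1e-7,
) -> Ellipsoid:
    """Fit the observed-niche MVE to occurrence component scores.

    By convention the observed niche uses ALL available occurrences
    (calibration and evaluation populations), so the evaluation asks whether
    a model predicts beyond anything ever observed.
    """
    return fit_mve(np.asarray(occ_scores, dtype=float), coverage=coverage, tolerance=tolerance)


__all__ = [
    "unique_env_points",
    "espace_index_I",
    "jaccard_similarity",
    "extrapolation_distance",
    "ESpaceReport",
    "espace_report",
    "observed_niche",
    "DEDUP_DECIMALS",
]
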