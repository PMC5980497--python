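"""Geographic-space model evaluation for presence-only data.

Implements the evaluation toolkit applied to continuous and binary
suitability maps when only presences are available:

* **Omission-error thresholding** — binarize a continuous prediction at the
  value that omits at most a chosen fraction of calibration occurrences
  (tolerance 0 gives the minimum training presence: 0% calibration
  omission).
* **Omission rate** — fraction of independent evaluation occurrences on
  cells predicted unsuitable (the Type I error of a presence-only map).
* **Proportional suitable area** — fraction of the (masked) region predicted
  suitable, the commission-side quantity presences alone can constrain.
* **Cumulative binomial probability (CBP)** — one-tailed P(X >= k) for k of
  n evaluation presences falling on suitable cells when a random map of the
  same suitable proportion would hit each with that probability.
* **Partial ROC** — the ROC restricted to the low-omission band
  (sensitivity > 1 - E), summarized as the ratio of the partial AUC to the
  same band's area under the 1:1 null line; 1 is random, the ratio is
  bounded by [0, 2].  Replicated by bootstrap over evaluation occurrences.
* **Ensemble sum** — per-cell count of binary maps voting suitable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geodata import (
    BinaryMap,
    CellAssignment,
    OccurrenceSet,
    Raster,
    assign_cells,
    check_aligned,
)


class DegeneratePredictionError(ValueError):
    """The prediction is constant, so no threshold sweep is possible."""


def _usable_values(pred: Raster, occ: OccurrenceSet, unique_cells: bool = False):
    """Prediction values at usable occurrence cells (optionally one per cell)."""
    assignment = assign_cells(occ, pred.geometry, pred.nodata_mask)
    cells = (
        assignment.unique_usable_cells() if unique_cells else assignment.usable_cells
    )
    values = np.array([pred.values[c] for c in cells], dtype=float)
    return values, assignment


def threshold_by_omission(
    pred: Raster,
    calib: OccurrenceSet,
    omission_tolerance: float = 0.0,
) -> BinaryMap:
    """Binarize a prediction at an omission-error tolerance on calibration data.

    With sorted calibration predictions v_1 <= ... <= v_n, the threshold is
    v_{floor(tolerance * n) + 1} (1-based), i.e. the smallest calibration
    value after discarding the lowest ``floor(tolerance * n)`` of them.
    Tolerance 0 therefore uses the minimum training presence.  A cell is
    suitable iff its value >= threshold (closed comparison), which makes the
    observed calibration omission at tolerance 0 exactly zero.
    """
    if not 0 <= omission_tolerance < 1:
        raise ValueError("omission_tolerance must lie in [0, 1)")
    values, _ = _usable_values(pred, calib)
    if values.size == 0:
        raise ValueError("no usable calibration occurrence falls on the prediction")
    v = np.sort(values)
    k = int(np.floor(omission_tolerance * v.size))  # number of points removed
    threshold = float(v[k])
    suitable = np.where(np.isfinite(pred.values), pred.values >= threshold, False)
    return BinaryMap(
        geometry=pred.geometry,
        suitable=suitable,
        nodata_mask=pred.nodata_mask,
        threshold_value=threshold,
        omission_tolerance=omission_tolerance,
    )


@dataclass
class OmissionResult:
    omission_rate: float
    n_test: int
    n_omitted: int
    assignment: CellAssignment


def omission_rate(bin_map: BinaryMap, test: OccurrenceSet) -> OmissionResult:
    """Fraction of usable evaluation occurrences on unsuitable cells."""
    assignment = assign_cells(test, bin_map.geometry, bin_map.nodata_mask)
    cells = assignment.usable_cells
    if not cells:
        raise ValueError("no usable test occurrence falls on the binary map")
    omitted = sum(1 for c in cells if not bin_map.suitable[c])
    return OmissionResult(
        omission_rate=omitted / len(cells),
        n_test=len(cells),
        n_omitted=omitted,
        assignment=assignment,
    )


def proportion_suitable(
    bin_map: BinaryMap,
    region_mask: np.ndarray | None = None,
    latitude_weighted: bool = False,
) -> float:
    """Proportion of the region's valid cells predicted suitable.

    ``region_mask`` restricts counting to a boolean sub-region (e.g. the
    evaluation area).  By default cells are counted with equal weight; with
    ``latitude_weighted`` each cell is weighted by the cosine of its center
    latitude (an approximation of true cell area, off by default because the
    study extents this toolkit targets are small).
    """
    valid = ~bin_map.nodata_mask
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != bin_map.geometry.shape:
            raise ValueError("region mask shape does not match geometry")
        valid = valid & region_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("region contains no valid cells")
    if latitude_weighted:
        g = bin_map.geometry
        lats = np.array([g.cell_center(r, 0)[1] for r in range(g.n_rows)])
        w = np.cos(np.deg2rad(lats))[:, None] * np.ones(g.shape)
        return float(w[valid & bin_map.suitable].sum() / w[valid].sum())
    return float((valid & bin_map.suitable).sum() / n_valid)


def cumulative_binomial(n_success: int, n_trials: int, p_success: float) -> float:
    """One-tailed cumulative binomial probability P(X >= n_success).

    X ~ Binomial(n_trials, p_success); computed through the regularized
    incomplete beta function (scipy survival function), which is numerically
    stable in the tails.  This is the significance test for "k of n
    evaluation presences fell on suitable cells" against a random map whose
    suitable proportion is ``p_success``.
    """
    if not 0 <= n_success <= n_trials:
        raise ValueError("need 0 <= n_success <= n_trials")
    if not 0 <= p_success <= 1:
        raise ValueError("p_success must lie in [0, 1]")
    if n_success == 0:
        return 1.0
    return float(stats.binom.sf(n_success - 1, n_trials, p_success))


@dataclass
class GMetricsReport:
    """Omission rate, suitable area and CBP for one binary map."""

    omission_rate: float
    n_test: int
    n_omitted: int
    proportion_suitable: float
    cbp_p: float
    threshold_value: float
    omission_tolerance: float

    def to_dict(self) -> dict:
        return {
            "omission_rate": self.omission_rate,
            "n_test": self.n_test,
            "n_omitted": self.n_omitted,
            "proportion_suitable": self.proportion_suitable,
            "cbp_p": self.cbp_p,
            "threshold_value": self.threshold_value,
            "omission_tolerance": self.omission_tolerance,
        }


def gmetrics_report(
    bin_map: BinaryMap,
    test: OccurrenceSet,
    region_mask: np.ndarray | None = None,
) -> GMetricsReport:
    """Bundle omission rate, proportional area and CBP for one binary map."""
    om = omission_rate(bin_map, test)
    area = proportion_suitable(bin_map, region_mask)
    cbp = cumulative_binomial(om.n_test - om.n_omitted, om.n_test, area)
    return GMetricsReport(
        omission_rate=om.omission_rate,
        n_test=om.n_test,
        n_omitted=om.n_omitted,
        proportion_suitable=area,
        cbp_p=cbp,
        threshold_value=bin_map.threshold_value,
        omission_tolerance=bin_map.omission_tolerance,
    )


# ---------------------------------------------------------------------------
# Partial ROC
# ---------------------------------------------------------------------------

#: Above this many distinct prediction values the threshold sweep switches to
#: equal-quantile classes, bounding cost on large continuous rasters.
MAX_THRESHOLD_CLASSES = 1000


@dataclass
class PartialROCResult:
    """Bootstrap-replicated partial ROC AUC ratios.

    ``p_value`` is the fraction of replicate ratios <= 1 (the probability
    that the model performs no better than random within the band).
    """

    E: float
    n_replicates: int
    resample_fraction: float
    ratios: np.ndarray
    seed: int
    n_test: int

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))

    @property
    def p_value(self) -> float:
        return float(np.mean(self.ratios <= 1.0))

    def to_dict(self) -> dict:
        return {
            "E": self.E,
            "n_replicates": self.n_replicates,
            "resample_fraction": self.resample_fraction,
            "mean_ratio": self.mean_ratio,
            "p_value": self.p_value,
            "seed": self.seed,
            "n_test": self.n_test,
            "ratios": self.ratios.tolist(),
        }


def _partial_auc_ratio(x: np.ndarray, y: np.ndarray, E: float) -> float:
    """Partial-AUC ratio over the sensitivity band (1 - E, 1].

    ``x`` is the fractional predicted area and ``y`` the sensitivity at each
    threshold, both non-decreasing with x[-1] = y[-1] = 1.  The curve is cut
    at y = 1 - E (with a linearly interpolated crossing point), the model
    partial AUC is the trapezoid integral of y over the remaining x range,
    and the null partial AUC is the integral of the 1:1 line over the same
    range.  Their ratio is in [0, 2] because y <= 1.
    """
    band = 1.0 - E
    keep = y >= band
    if not np.any(keep):
        return 0.0
    i0 = int(np.argmax(keep))  # first index inside the band
    xs = x[keep]
    ys = y[keep]
    if i0 > 0 and ys[0] > band:
        # interpolate the exact band crossing between (i0-1) and i0
        x_prev, y_prev = x[i0 - 1], y[i0 - 1]
        if ys[0] > y_prev:
            t = (band - y_prev) / (ys[0] - y_prev)
            x_cross = x_prev + t * (xs[0] - x_prev)
            xs = np.concatenate([[x_cross], xs])
            ys = np.concatenate([[band], ys])
    if xs.size < 2 or xs[-1] <= xs[0]:
        return 0.0
    auc_model = float(np.trapezoid(ys, xs))
    auc_null = float(np.trapezoid(xs, xs))
    if auc_null == 0.0:
        return 0.0
    return auc_model / auc_null


def partial_roc(
    pred: Raster,
    test: OccurrenceSet,
    E: float = 0.05,
    n_replicates: int = 100,
    resample_fraction: float = 0.5,
    seed: int = 0,
) -> PartialROCResult:
    """Partial ROC evaluation of a continuous prediction.

    Per bootstrap replicate, ``ceil(resample_fraction * n_test)`` evaluation
    cells are drawn with replacement; the ROC-like curve (fractional
    predicted area vs. sensitivity) is swept over prediction-value classes
    and the partial AUC ratio over the sensitivity band (1 - E, 1] is
    recorded.  Evaluation occurrences are reduced to unique usable cells
    before resampling.

    Raises
    ------
    DegeneratePredictionError
        If the prediction is constant over valid cells.
    ValueError
        If E is outside (0, 0.5] or fewer than 2 usable test cells exist.
    """
    if not 0 < E <= 0.5:
        raise ValueError("E must lie in (0, 0.5]")
    if not 0 < resample_fraction <= 1:
        raise ValueError("resample_fraction must lie in (0, 1]")
    background = pred.finite_values
    if background.size == 0 or np.ptp(background) == 0:
        raise DegeneratePredictionError("prediction is constant over valid cells")
    test_values, _ = _usable_values(pred, test, unique_cells=True)
    n_test = test_values.size
    if n_test < 2:
        raise ValueError("need at least 2 usable evaluation cells")

    distinct = np.unique(background)
    if distinct.size > MAX_THRESHOLD_CLASSES:
        qs = np.linspace(0, 1, MAX_THRESHOLD_CLASSES)
        thresholds = np.unique(np.quantile(distinct, qs))
    else:
        thresholds = distinct
    thresholds = thresholds[::-1]  # descending: area grows along the sweep

    sorted_bg = np.sort(background)
    n_bg = sorted_bg.size
    # fractional predicted area at each threshold (value >= t)
    x = 1.0 - np.searchsorted(sorted_bg, thresholds, side="left") / n_bg

    rng = np.random.default_rng(seed)
    n_draw = int(np.ceil(resample_fraction * n_test))
    ratios = np.empty(n_replicates)
    for r in range(n_replicates):
        sample = rng.choice(test_values, size=n_draw, replace=True)
        s = np.sort(sample)
        y = 1.0 - np.searchsorted(s, thresholds, side="left") / n_draw
        ratios[r] = _partial_auc_ratio(x, y, E)
    return PartialROCResult(
        E=E,
        n_replicates=n_replicates,
        resample_fraction=resample_fraction,
        ratios=ratios,
        seed=seed,
        n_test=n_test,
    )


def ensemble_sum(maps: list[BinaryMap]) -> Raster:
    """Per-cell count of binary maps voting suitable.

    All maps must share a grid; a cell is nodata in the ensemble when it is
    nodata in any input.
    """
    if len(maps) < 2:
        raise ValueError("an ensemble needs at least 2 binary maps")
    check_aligned(*[m.geometry for m in maps])
    counts = np.zeros(maps[0].geometry.shape, dtype=float)
    nodata = np.zeros(maps[0].geometry.shape, dtype=bool)
    for m in maps:
        counts += m.suitable
        nodata |= m.nodata_mask
    counts[nodata] = np.nan
    return Raster(maps[0].geometry, counts)


__all__ = [
    "threshold_by_omission",
    "omission_rate",
    "OmissionResult",
    "proportion_suitable",
    "cumulative_binomial",
    "GMetricsReport",
    "gmetrics_report",
    "PartialROCResult",
    "partial_roc",
    "ensemble_sum",
    "DegeneratePredictionError",
]
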