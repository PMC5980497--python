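"""Information-criterion evaluation of niche models.

AIC = 2K - 2 ln(L) scores a model's fit to the calibration occurrences
penalized by its parameter count K; AICc adds the small-sample correction
2K(K+1)/(n - K - 1).  For niche models whose internals are not re-run here,
K is an input, with two helper counting rules:

* a quadratic generalized linear model without interaction terms contributes
  one linear and one quadratic term per predictor (intercept excluded), so
  K = 2p;
* a classification model (regression tree or genetic algorithm) contributes
  K = N * (p + p(p+1)/2 + c), where N is the average number of nodes per
  tree (or individuals per population), p the predictor dimensionality, and
  c the per-split penalty.

The likelihood of a continuous suitability raster given occurrence records
follows the standard raster-likelihood recipe: normalize the raster to a
probability distribution over valid cells and sum the log of the normalized
value at each occurrence record (records sharing a cell each contribute).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodata import OccurrenceSet, Raster, assign_cells


def aic(K: int, lnL: float) -> float:
    """Akaike information criterion, 2K - 2 ln(L)."""
    if K < 0:
        raise ValueError("K must be non-negative")
    return 2.0 * K - 2.0 * lnL


def aicc(K: int, lnL: float, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2K(K+1)/(n - K - 1).

    Requires n > K + 1; as n grows the correction vanishes and AICc
    converges to AIC.
    """
    if n <= K + 1:
        raise ValueError(f"AICc undefined: need n > K + 1 (n={n}, K={K})")
    return aic(K, lnL) + 2.0 * K * (K + 1) / (n - K - 1)


def glm_quadratic_K(p: int) -> int:
    """Parameter count of a quadratic, no-interaction GLM on p predictors.

    One linear plus one squared term per predictor; the intercept is not
    counted.  With the three leading principal components as predictors this
    gives K = 6.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    return 2 * p


def classification_K(N: float, p: int, c: int) -> int:
    """Parameter count of a classification model: N * (p + p(p+1)/2 + c).

    N is the average number of nodes per regression tree (or individuals per
    population in a genetic algorithm) and may be non-integer; the product is
    rounded to the nearest integer.  c is the penalty per data-based split
    (3 when each split partitions records into true/false/unknown).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if p < 1:
        raise ValueError("p must be at least 1")
    if c < 0:
        raise ValueError("c must be non-negative")
    return int(round(N * (p + p * (p + 1) / 2 + c)))


def raster_log_likelihood(pred: Raster, occ: OccurrenceSet) -> float:
    """Log-likelihood of occurrences under a normalized suitability raster.

    The raster is rescaled to sum to 1 over its valid cells (so any positive
    rescaling of the input leaves the result unchanged) and the
    log-probabilities at occurrence cells are summed over records.

    Raises
    ------
    ValueError
        If any usable occurrence sits on a cell with zero suitability, or no
        occurrence is usable, or the raster is not non-negative with a
        positive total.
    """
    vals = pred.values
    finite = np.isfinite(vals)
    if np.any(vals[finite] < 0):
        raise ValueError("suitability values must be non-negative")
    total = float(vals[finite].sum())
    if not total > 0:
        raise ValueError("suitability raster has no positive values")
    assignment = assign_cells(occ, pred.geometry, pred.nodata_mask)
    cells = assignment.usable_cells
    if not cells:
        raise ValueError("no usable occurrence falls on the raster")
    at_occ = np.array([vals[c] for c in cells], dtype=float)
    zero = np.flatnonzero(at_occ == 0.0)
    if zero.size:
        raise ValueError(
            f"occurrence(s) on zero-suitability cells at record positions {zero.tolist()}"
        )
    return float(np.sum(np.log(at_occ / total)))


@dataclass
class AICResult:
    """AIC (and optionally AICc) with the inputs echoed for provenance."""

    K: int
    lnL: float
    aic: float
    n: int | None = None
    aicc: float | None = None

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "lnL": self.lnL,
            "aic": self.aic,
            "n": self.n,
            "aicc": self.aicc,
        }


def aic_report(K: int, lnL: float, n: int | None = None) -> AICResult:
    """AIC, plus AICc when an occurrence count n is supplied."""
    res = AICResult(K=K, lnL=lnL, aic=aic(K, lnL))
    if n is not None:
        res.n = n
        res.aicc = aicc(K, lnL, n)
    return res


__all__ = [
    "aic",
    "aicc",
    "glm_quadratic_K",
    "classification_K",
    "raster_log_likelihood",
    "AICResult",
    "aic_report",
]
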