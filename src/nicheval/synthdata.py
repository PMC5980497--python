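"""Seeded synthetic virtual-species scenarios.

Real evaluations of niche models need climate rasters, occurrence records
and fitted model outputs.  This module generates all three from a seed, so
every metric in the package is exercisable end to end with no downloads:

* a stack of smooth, mutually correlated environmental layers (standing in
  for bioclimatic variables) built from a shared latent field plus
  independent smooth fields;
* a *true niche*: a Gaussian (bell-shaped) suitability response around an
  ellipsoid in layer space — physiological tolerance curves are unimodal,
  not bimodal, which is exactly the behaviour overfit models violate;
* three occurrence populations in disjoint latitudinal bands — a northern
  and a southern calibration population separated by an occupied but
  unsampled middle, plus a small held-out central evaluation population.
  This is the dispersal-limited ("Wallace's Dream") configuration: the
  species' range edges are set by barriers, not by unsuitable environments,
  so calibration data under-sample the niche and the central population
  probes model interpolation;
* four contrasting pseudo-models standing in for fitted algorithms:
  ``matched`` (the truth itself), ``broad`` (a monotone flattening of the
  truth, suitable nearly everywhere at any fixed cut), ``overfit`` (the
  truth masked to a small neighbourhood of the calibration cells) and
  ``random`` (i.i.d. uniform noise).

Every artifact is a pure function of (seed, configuration).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .ellipsoid import Ellipsoid
from .espace import EnvStack
from .geodata import (
    CELL_2P5_ARCMIN,
    GridGeometry,
    OccurrenceRecord,
    OccurrenceSet,
    Raster,
    write_ascii_grid,
    write_occurrences,
)

#: Default grid: 60 x 60 cells of 2.5 arcminutes (a 2.5 x 2.5 degree window
#: in the latitudes of the southern temperate forests).
DEFAULT_GEOMETRY = GridGeometry(
    n_rows=60, n_cols=60, cell_size=CELL_2P5_ARCMIN, origin_lon=-74.0, origin_lat=-41.0
)

#: Post-thinning population sizes: north / central / south.
DEFAULT_COUNTS = (42, 7, 61)

#: Row bands (fractions of n_rows): north at the top, south at the bottom,
#: a small central band in between, with unsampled gaps separating them.
BANDS = {"north": (0.00, 0.30), "central": (0.40, 0.60), "south": (0.70, 1.00)}

#: Minimum true suitability of any sampled occurrence cell.
SUITABILITY_FLOOR = 0.5

#: Fixed absolute binarization cut used for pseudo-model comparisons on the
#: [0, 1] truth scale (quantile-type thresholds are rank-invariant and would
#: collapse the "broad" flattening onto "matched").
FIXED_BINARY_THRESHOLD = 0.5


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Spatially smoothed Gaussian noise, standardized to unit variance."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_env_stack(
    seed: int,
    geometry: GridGeometry = DEFAULT_GEOMETRY,
    n_layers: int = 8,
    layer_correlation: float = 0.6,
    smoothing_sigma: float | None = None,
) -> EnvStack:
    """Generate correlated smooth environmental layers.

    Each layer is an affine transform of
    sqrt(rho) * latent + sqrt(1 - rho) * own, where ``latent`` is a shared
    smooth field (strong latitudinal gradient plus smoothed noise) and
    ``own`` an independent smooth field with a random weak gradient
    direction.  ``layer_correlation`` = rho in [0, 1]: at 1 all layers are
    affinely identical; at 0 the mean absolute pairwise correlation is small.
    """
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    if not 0 <= layer_correlation <= 1:
        raise ValueError("layer_correlation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nr, nc = geometry.shape
    if smoothing_sigma is None:
        smoothing_sigma = max(nr, nc) / 15.0

    rows = np.linspace(-1, 1, nr)[:, None] * np.ones((1, nc))
    cols = np.ones((nr, 1)) * np.linspace(-1, 1, nc)[None, :]
    lat_grad = (rows - rows.mean()) / rows.std()
    lon_grad = (cols - cols.mean()) / cols.std()

    latent = 0.8 * lat_grad + 0.6 * _smooth_field(rng, (nr, nc), smoothing_sigma)
    latent = (latent - latent.mean()) / latent.std()

    w_shared = np.sqrt(layer_correlation)
    w_own = np.sqrt(1.0 - layer_correlation)
    layers: dict[str, np.ndarray] = {}
    for i in range(n_layers):
        c1, c2 = 0.15 * rng.standard_normal(2)
        own = c1 * lon_grad + c2 * lat_grad + _smooth_field(rng, (nr, nc), smoothing_sigma)
        own = (own - own.mean()) / own.std()
        f = w_shared * latent + w_own * own
        scale = rng.uniform(0.5, 3.0)
        offset = rng.uniform(-10.0, 10.0)
        layers[f"env{i + 1:02d}"] = offset + scale * f
    return EnvStack(geometry=geometry, layers=layers)


class InfeasibleScenarioError(ValueError):
    """A band does not contain enough sufficiently suitable cells."""


def _band_rows(geometry: GridGeometry, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    r0 = int(np.floor(lo * geometry.n_rows))
    r1 = int(np.ceil(hi * geometry.n_rows))
    return np.arange(r0, r1)


@dataclass
class SyntheticScenario:
    """A complete seeded virtual-species test scenario."""

    seed: int
    stack: EnvStack
    true_niche: Ellipsoid  # in raw layer ("generating-variable") space
    truth: Raster  # true suitability in [0, 1]
    populations: dict[str, OccurrenceSet]
    pseudo_models: dict[str, Raster] = field(default_factory=dict)

    @property
    def geometry(self) -> GridGeometry:
        return self.stack.geometry

    def calibration(self) -> OccurrenceSet:
        """Northern + southern populations (the model-calibration split)."""
        return OccurrenceSet(
            self.populations["north"].records + self.populations["south"].records
        )

    def evaluation(self) -> OccurrenceSet:
        """The held-out central population."""
        return self.populations["central"]

    def all_occurrences(self) -> OccurrenceSet:
        return OccurrenceSet(
            [r for pop in ("north", "central", "south") for r in self.populations[pop].records]
        )

    def save(self, out_dir: str | Path) -> None:
        """Write layers, rasters, occurrences and a manifest to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, raster in self.stack.rasters().items():
            write_ascii_grid(raster, out / f"{name}.asc")
        write_ascii_grid(self.truth, out / "truth.asc")
        for name, raster in self.pseudo_models.items():
            write_ascii_grid(raster, out / f"model_{name}.asc")
        write_occurrences(self.all_occurrences(), out / "occurrences.csv")
        manifest = {
            "seed": self.seed,
            "n_layers": self.stack.n_layers,
            "layers": [f"{n}.asc" for n in self.stack.layer_names],
            "truth": "truth.asc",
            "pseudo_models": {n: f"model_{n}.asc" for n in self.pseudo_models},
            "occurrences": "occurrences.csv",
            "populations": {k: len(v) for k, v in self.populations.items()},
            "true_niche": self.true_niche.to_dict(),
            "fixed_binary_threshold": FIXED_BINARY_THRESHOLD,
        }
        (out / "scenario.json").write_text(json.dumps(manifest, indent=1))


def generate_truth_and_occurrences(
    stack: EnvStack,
    seed: int,
    niche_breadth: float = 1.0,
    counts: tuple[int, int, int] = DEFAULT_COUNTS,
    suitability_floor: float = SUITABILITY_FLOOR,
) -> SyntheticScenario:
    """Derive the true niche and sample the three occurrence populations.

    The niche is an ellipsoid in layer space centred on the mean environment
    of the three occupied bands with axis lengths proportional to the local
    environmental spread times ``niche_breadth``; true suitability is the
    bell-shaped response exp(-mahalanobis_sq / 2).  Within each band,
    occurrence cells are drawn without replacement with probability
    proportional to suitability, restricted to cells whose suitability
    reaches ``suitability_floor``; occurrences sit at cell centres, so the
    set is already thinned (one record per cell).
    """
    if any(c <= 0 for c in counts):
        raise ValueError("population counts must be positive")
    rng = np.random.default_rng(seed)
    geometry = stack.geometry
    data, cell_ids = stack.to_matrix()
    nr, nc = geometry.shape

    band_rows = {name: _band_rows(geometry, b) for name, b in BANDS.items()}
    rows_of_cells = cell_ids // nc
    in_band = {
        name: np.isin(rows_of_cells, rows) for name, rows in band_rows.items()
    }
    occupied = in_band["north"] | in_band["central"] | in_band["south"]

    mu = data[occupied].mean(axis=0)
    sigma = data[occupied].std(axis=0, ddof=0)
    sigma = np.maximum(sigma, 1e-9)
    d = data.shape[1]
    # shape = diag(1 / (d * (breadth * sigma)^2)): mahalanobis_sq averages the
    # squared per-layer deviations, so breadth is in units of local spread
    axes = niche_breadth * sigma * np.sqrt(d)
    true_niche = Ellipsoid(mu, np.diag(1.0 / axes**2))

    m2 = true_niche.mahalanobis_sq(data)
    suit = np.exp(-np.asarray(m2) / 2.0)
    truth_vals = np.full(nr * nc, np.nan)
    truth_vals[cell_ids] = suit
    truth = Raster(geometry, truth_vals.reshape(nr, nc))

    populations: dict[str, OccurrenceSet] = {}
    for name, count in zip(("north", "central", "south"), counts, strict=True):
        eligible = np.flatnonzero(in_band[name] & (suit >= suitability_floor))
        if eligible.size < count:
            raise InfeasibleScenarioError(
                f"band {name!r} has {eligible.size} cells at suitability >= "
                f"{suitability_floor}, need {count}"
            )
        p = suit[eligible] / suit[eligible].sum()
        chosen = rng.choice(eligible, size=count, replace=False, p=p)
        records = []
        for idx in chosen:
            flat = int(cell_ids[idx])
            lon, lat = geometry.cell_center(flat // nc, flat % nc)
            records.append(OccurrenceRecord(lon, lat, name))
        populations[name] = OccurrenceSet(records)

    return SyntheticScenario(
        seed=seed,
        stack=stack,
        true_niche=true_niche,
        truth=truth,
        populations=populations,
    )


def generate_pseudo_models(
    scenario: SyntheticScenario,
    seed: int | None = None,
    overfit_radius: int = 3,
) -> dict[str, Raster]:
    """Four contrasting stand-ins for fitted niche-model outputs.

    ``matched``: the true suitability itself.  ``broad``: truth ** 0.1, a
    monotone flattening that predicts nearly everything suitable at any
    fixed cut.  ``overfit``: truth zeroed beyond ``overfit_radius`` cells
    (Chebyshev) of any calibration occurrence cell.  ``random``: i.i.d.
    uniform(0, 1) noise.  The models are attached to the scenario and
    returned.
    """
    if seed is None:
        seed = scenario.seed + 1
    rng = np.random.default_rng(seed)
    geometry = scenario.geometry
    truth = scenario.truth.values
    finite = np.isfinite(truth)

    broad = np.where(finite, np.power(np.clip(truth, 0, None), 0.1), np.nan)

    calib = scenario.calibration()
    near = np.zeros(geometry.shape, dtype=bool)
    for rec in calib:
        cell = geometry.cell_of(rec.longitude, rec.latitude)
        if cell is None:
            continue
        r, c = cell
        r0, r1 = max(0, r - overfit_radius), min(geometry.n_rows, r + overfit_radius + 1)
        c0, c1 = max(0, c - overfit_radius), min(geometry.n_cols, c + overfit_radius + 1)
        near[r0:r1, c0:c1] = True
    overfit = np.where(finite, np.where(near, truth, 0.0), np.nan)

    random_vals = np.where(finite, rng.random(geometry.shape), np.nan)

    models = {
        "matched": Raster(geometry, truth.copy()),
        "broad": Raster(geometry, broad),
        "overfit": Raster(geometry, overfit),
        "random": Raster(geometry, random_vals),
    }
    scenario.pseudo_models = models
    return models


def generate_scenario(
    seed: int,
    geometry: GridGeometry = DEFAULT_GEOMETRY,
    n_layers: int = 8,
    layer_correlation: float = 0.6,
    niche_breadth: float = 1.0,
    counts: tuple[int, int, int] = DEFAULT_COUNTS,
) -> SyntheticScenario:
    """One-call scenario: stack, truth, populations and pseudo-models.

    Sub-seeds for the stack, the occurrence sampling and the pseudo-models
    are derived from the master seed, so the whole scenario is a pure
    function of its arguments.
    """
    stack = generate_env_stack(
        seed, geometry=geometry, n_layers=n_layers, layer_correlation=layer_correlation
    )
    scenario = generate_truth_and_occurrences(
        stack, seed=seed + 10_000, niche_breadth=niche_breadth, counts=counts
    )
    scenario.seed = seed
    generate_pseudo_models(scenario, seed=seed + 20_000)
    return scenario


__all__ = [
    "SyntheticScenario",
    "InfeasibleScenarioError",
    "generate_env_stack",
    "generate_truth_and_occurrences",
    "generate_pseudo_models",
    "generate_scenario",
    "DEFAULT_GEOMETRY",
    "DEFAULT_COUNTS",
    "FIXED_BINARY_THRESHOLD",
    "SUITABILITY_FLOOR",
]
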