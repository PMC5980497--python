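"""Full evaluation pipeline: calibration inputs -> G-space + E-space + IC reports.

`run_full_evaluation` ties the modules together in the standard workflow:
build the principal-component background from the environmental stack, thin
the occurrences to the analysis grid, fit the observed-niche ellipsoid to
all occurrences, then score every candidate prediction raster with the
geographic metrics (omission rate, proportional suitable area, cumulative
binomial probability at each omission tolerance, partial ROC on the
continuous output), the environmental-space indices, and optionally AIC —
finally summing the thresholded maps into an agreement ensemble.

The report is a plain JSON-serializable dict.  Every number in it is
reproducible from the configuration and master seed alone; input files are
referenced by content hash so a silently swapped raster is detectable, and
flagged occurrences (off-grid, on nodata) are surfaced because dropped
points change every metric.  A stage failing for one model is reported for
that model without aborting the others.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .ellipsoid import Ellipsoid
from .emetrics import espace_report, observed_niche
from .espace import EnvStack, build_pca
from .geodata import (
    OccurrenceSet,
    Raster,
    assign_cells,
    read_occurrences,
    read_raster,
    thin_to_grid,
)
from .gmetrics import ensemble_sum, gmetrics_report, partial_roc, threshold_by_omission
from .icmetrics import aic_report, raster_log_likelihood

logger = logging.getLogger(__name__)

DEFAULTS = {
    "retention": 0.90,
    "omission_tolerances": [0.0, 0.05],
    "thin": True,
    "proc": {"E": 0.05, "n_replicates": 100, "resample_fraction": 0.5},
    "jaccard_mode": "ellipsoid_volume",
    "mc_samples": 100_000,
    "seed": 42,
}


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return h[:16]


def _load_stack(layer_paths: list[str]) -> EnvStack:
    rasters = {Path(p).stem: read_raster(p) for p in layer_paths}
    first = next(iter(rasters.values()))
    return EnvStack(
        geometry=first.geometry, layers={k: r.values for k, r in rasters.items()}
    )


def _occurrence_scores(occ: OccurrenceSet, space, nodata_mask) -> np.ndarray:
    assignment = assign_cells(occ, space.geometry, nodata_mask)
    return space.scores_for_cells(assignment.unique_usable_cells())


def run_full_evaluation(config: dict) -> dict:
    """Run the complete evaluation workflow described by ``config``.

    Config keys (defaults in ``DEFAULTS``):

    ``env_layers``
        List of environmental raster paths (ESRI ASCII grids).
    ``predictions``
        Mapping of model name -> continuous suitability raster path.
    ``occurrences`` / (``calibration`` + ``evaluation``)
        Either a single CSV whose ``population`` column separates
        ``north``/``south`` (calibration) from ``central`` (evaluation), or
        two explicit CSVs.  ``evaluation`` may be absent: evaluation-side
        metrics are then reported as skipped.
    ``aic``
        Optional mapping of model name -> {"K": int} (parameter count for
        models whose internals are not re-run here).
    ``retention``, ``omission_tolerances``, ``thin``, ``proc``,
    ``jaccard_mode``, ``mc_samples``, ``seed``
        Tuning knobs; all randomness derives from the single master seed.
    """
    cfg = {**DEFAULTS, **config}
    cfg["proc"] = {**DEFAULTS["proc"], **config.get("proc", {})}
    seed = int(cfg["seed"])

    hashes = {}
    for p in cfg.get("env_layers", []):
        hashes[str(p)] = _file_hash(p)
    for key in ("occurrences", "calibration", "evaluation"):
        if cfg.get(key):
            hashes[str(cfg[key])] = _file_hash(cfg[key])

    stack = _load_stack(cfg["env_layers"])
    space = build_pca(stack, retention=cfg["retention"])
    nodata = stack.nodata_mask

    warnings: list[str] = []
    if cfg.get("occurrences"):
        occ, rejected = read_occurrences(cfg["occurrences"])
        if rejected:
            warnings.append(f"occurrence rows rejected: {rejected}")
        calib = occ.subset(("north", "south"))
        evalset: OccurrenceSet | None = occ.subset("central")
        if len(evalset) == 0:
            evalset = None
    else:
        calib, rejected = read_occurrences(cfg["calibration"])
        if rejected:
            warnings.append(f"calibration rows rejected: {rejected}")
        evalset = None
        if cfg.get("evaluation"):
            evalset, rejected = read_occurrences(cfg["evaluation"])
            if rejected:
                warnings.append(f"evaluation rows rejected: {rejected}")

    if cfg["thin"]:
        calib = thin_to_grid(calib, stack.geometry.cell_size)
        if evalset is not None:
            evalset = thin_to_grid(evalset, stack.geometry.cell_size)

    everything = OccurrenceSet(
        calib.records + (evalset.records if evalset is not None else [])
    )
    for name, assignment in (
        ("calibration", assign_cells(calib, stack.geometry, nodata)),
        ("all", assign_cells(everything, stack.geometry, nodata)),
    ):
        if assignment.off_grid or assignment.on_nodata:
            warnings.append(
                f"{name} occurrences flagged: {len(assignment.off_grid)} off-grid, "
                f"{len(assignment.on_nodata)} on nodata"
            )

    observed = observed_niche(_occurrence_scores(everything, space, nodata))

    report: dict = {
        "nicheval_version": __version__,
        "numpy_version": np.__version__,
        "config": {k: v for k, v in cfg.items() if k != "predictions"},
        "predictions": {str(k): str(v) for k, v in cfg.get("predictions", {}).items()},
        "input_hashes": hashes,
        "seed": seed,
        "pca": {
            "d": space.d,
            "explained": space.explained.tolist(),
            "cumulative_explained": space.cumulative_explained,
        },
        "observed_niche": observed.to_dict(),
        "warnings": warnings,
        "models": {},
    }

    binary_at_zero = []
    for model_seed_offset, (name, path) in enumerate(cfg.get("predictions", {}).items()):
        entry: dict = {"path": str(path), "status": "ok"}
        try:
            hashes[str(path)] = _file_hash(path)
            pred = read_raster(path)
            entry["thresholds"] = {}
            for tol in cfg["omission_tolerances"]:
                bin_map = threshold_by_omission(pred, calib, tol)
                tol_entry: dict = {"threshold_value": bin_map.threshold_value}
                if evalset is not None:
                    g = gmetrics_report(bin_map, evalset)
                    tol_entry["gmetrics"] = g.to_dict()
                else:
                    tol_entry["gmetrics"] = {"status": "skipped (no evaluation occurrences)"}
                e = espace_report(
                    bin_map,
                    space,
                    observed,
                    jaccard_mode=cfg["jaccard_mode"],
                    mc_samples=cfg["mc_samples"],
                    seed=seed,
                )
                tol_entry["espace"] = e.to_dict()
                entry["thresholds"][f"{tol:g}"] = tol_entry
                if tol == 0.0:
                    binary_at_zero.append(bin_map)
            if evalset is not None:
                pr = partial_roc(
                    pred,
                    evalset,
                    E=cfg["proc"]["E"],
                    n_replicates=cfg["proc"]["n_replicates"],
                    resample_fraction=cfg["proc"]["resample_fraction"],
                    seed=seed + model_seed_offset,
                )
                entry["partial_roc"] = pr.to_dict()
            else:
                entry["partial_roc"] = {"status": "skipped (no evaluation occurrences)"}
            aic_cfg = cfg.get("aic", {}).get(name)
            if aic_cfg is not None:
                lnL = raster_log_likelihood(pred, calib)
                entry["aic"] = aic_report(
                    int(aic_cfg["K"]), lnL, n=aic_cfg.get("n")
                ).to_dict()
        except Exception as exc:  # per-model isolation: others keep running
            logger.exception("model %s failed", name)
            entry["status"] = "error"
            entry["error"] = f"{type(exc).__name__}: {exc}"
        report["models"][name] = entry

    if len(binary_at_zero) >= 2:
        ens = ensemble_sum(binary_at_zero)
        vals = ens.finite_values
        report["ensemble"] = {
            "n_models": len(binary_at_zero),
            "max_agreement": float(vals.max()) if vals.size else 0.0,
            "mean_agreement": float(vals.mean()) if vals.size else 0.0,
        }
        report["_ensemble_raster"] = ens  # stripped before JSON writing
    return report


def strip_non_serializable(report: dict) -> dict:
    return {k: v for k, v in report.items() if not k.startswith("_")}


__all__ = ["run_full_evaluation", "strip_non_serializable", "DEFAULTS"]
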