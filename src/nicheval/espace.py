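"""Environmental space: raster stacks and their principal-component ordination.

Climatic predictor layers are strongly collinear, so niche analyses are run
in the space of the leading principal components of the standardized layers
rather than in raw variable space.  The ordination is fit on the
*background* — every non-nodata cell of the study area — and occurrences are
projected into the resulting component space, where niche ellipsoids are fit
(:mod:`nicheval.ellipsoid`).

Scaling: the PCA operates on the correlation matrix (each layer centred and
scaled to unit variance over background cells) because bioclimatic layers
carry incommensurate units.  The number of retained components is the
smallest leading set whose cumulative explained variance reaches the
retention threshold (default 0.90).  Loading signs follow a fixed
convention — the largest-magnitude entry of each loading column is made
positive — so results are reproducible across linear-algebra backends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .geodata import GridGeometry, Raster, check_aligned


class DegenerateVarianceError(ValueError):
    """A layer has (near-)zero variance and cannot be standardized."""


@dataclass
class EnvStack:
    """An aligned multi-layer environmental raster stack.

    The common nodata mask is the union of the per-layer masks: a cell with
    any missing layer is excluded from the background.
    """

    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("an environmental stack needs at least 2 layers")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.geometry.shape:
                raise ValueError(f"layer {name!r} shape does not match geometry")
            self.layers[name] = arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def nodata_mask(self) -> np.ndarray:
        mask = np.zeros(self.geometry.shape, dtype=bool)
        for arr in self.layers.values():
            mask |= ~np.isfinite(arr)
        return mask

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Background data matrix (n_cells x n_layers) and flat cell ids.

        Cell ids are flat row-major indices into the grid, restricted to
        cells valid in every layer.
        """
        mask = ~self.nodata_mask
        ids = np.flatnonzero(mask.ravel())
        data = np.column_stack([arr.ravel()[ids] for arr in self.layers.values()])
        return data, ids

    def rasters(self) -> dict[str, Raster]:
        return {name: Raster(self.geometry, arr) for name, arr in self.layers.items()}


@dataclass
class EnvSpace:
    """Background cells projected onto retained principal components."""

    geometry: GridGeometry
    cell_ids: np.ndarray  # flat indices of background cells
    scores: np.ndarray  # (n_cells, d)
    loadings: np.ndarray  # (n_layers, d)
    means: np.ndarray  # per-layer standardization means
    scales: np.ndarray  # per-layer standardization std devs
    explained: np.ndarray  # all component variance fractions (length n_layers)
    layer_names: list[str]

    @property
    def d(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_explained(self) -> float:
        return float(np.sum(self.explained[: self.d]))

    def project(self, raw_values: np.ndarray) -> np.ndarray:
        """Project raw layer vectors into the retained component space.

        Applies the background standardization then the loading matrix:
        ((raw - means) / scales) @ loadings.  Accepts a single layer vector
        or an (n, n_layers) matrix.
        """
        raw = np.asarray(raw_values, dtype=float)
        single = raw.ndim == 1
        mat = np.atleast_2d(raw)
        if mat.shape[1] != len(self.layer_names):
            raise ValueError(
                f"expected {len(self.layer_names)} layer values, got {mat.shape[1]}"
            )
        out = ((mat - self.means) / self.scales) @ self.loadings
        return out[0] if single else out

    def scores_for_cells(self, cells: list[tuple[int, int]]) -> np.ndarray:
        """Component scores of specific (row, col) cells.

        Raises KeyError if a requested cell is not part of the background.
        """
        index = {int(cid): i for i, cid in enumerate(self.cell_ids)}
        rows = []
        for r, c in cells:
            flat = r * self.geometry.n_cols + c
            if flat not in index:
                raise KeyError(f"cell {(r, c)} is not a background cell")
            rows.append(index[flat])
        return self.scores[rows]

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path, scores_path: str | Path | None = None) -> None:
        """Write a JSON sidecar (loadings, means, scales, explained) and a
        scores CSV keyed by flat cell id."""
        path = Path(path)
        meta = {
            "geometry": {
                "n_rows": self.geometry.n_rows,
                "n_cols": self.geometry.n_cols,
                "cell_size": self.geometry.cell_size,
                "origin_lon": self.geometry.origin_lon,
                "origin_lat": self.geometry.origin_lat,
            },
            "layer_names": self.layer_names,
            "loadings": self.loadings.tolist(),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "explained": self.explained.tolist(),
        }
        path.write_text(json.dumps(meta, indent=1))
        if scores_path is None:
            scores_path = path.with_suffix(".scores.csv")
        df = pd.DataFrame(self.scores, columns=[f"pc{i + 1}" for i in range(self.d)])
        df.insert(0, "cell_id", self.cell_ids)
        df.to_csv(scores_path, index=False)

    @classmethod
    def load(cls, path: str | Path, scores_path: str | Path | None = None) -> "EnvSpace":
        path = Path(path)
        meta = json.loads(path.read_text())
        if scores_path is None:
            scores_path = path.with_suffix(".scores.csv")
        df = pd.read_csv(scores_path)
        g = meta["geometry"]
        return cls(
            geometry=GridGeometry(
                g["n_rows"], g["n_cols"], g["cell_size"], g["origin_lon"], g["origin_lat"]
            ),
            cell_ids=df["cell_id"].to_numpy(),
            scores=df.drop(columns="cell_id").to_numpy(),
            loadings=np.array(meta["loadings"]),
            means=np.array(meta["means"]),
            scales=np.array(meta["scales"]),
            explained=np.array(meta["explained"]),
            layer_names=list(meta["layer_names"]),
        )


def build_pca(stack: EnvStack, retention: float = 0.90) -> EnvSpace:
    """Principal-component ordination of the background environments.

    Layers are standardized to zero mean and unit variance over the
    background cells, then decomposed; the smallest leading set of components
    whose cumulative explained-variance fraction reaches ``retention`` is
    kept (always at least one).

    Raises
    ------
    DegenerateVarianceError
        If any layer is constant over the background.
    """
    if not 0 <= retention <= 1:
        raise ValueError("retention must lie in [0, 1]")
    data, cell_ids = stack.to_matrix()
    n_cells, n_layers = data.shape
    if n_cells < 2:
        raise ValueError("need at least 2 background cells")
    means = data.mean(axis=0)
    scales = data.std(axis=0, ddof=0)
    tiny = scales <= 1e-12 * np.maximum(1.0, np.abs(means))
    if np.any(tiny):
        bad = [stack.layer_names[i] for i in np.flatnonzero(tiny)]
        raise DegenerateVarianceError(f"layer(s) with zero variance: {bad}")
    z = (data - means) / scales

    pca = PCA(n_components=min(n_layers, n_cells), svd_solver="full")
    pca.fit(z)
    explained = pca.explained_variance_ratio_
    # pad so `explained` always has one entry per possible component
    if explained.size < n_layers:
        explained = np.concatenate([explained, np.zeros(n_layers - explained.size)])
    cumulative = np.cumsum(explained)
    d = int(np.searchsorted(cumulative, retention - 1e-12) + 1)
    d = max(1, min(d, pca.components_.shape[0]))

    loadings = pca.components_[:d].T  # (n_layers, d)
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(d):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    scores = z @ loadings
    return EnvSpace(
        geometry=stack.geometry,
        cell_ids=cell_ids,
        scores=scores,
        loadings=loadings,
        means=means,
        scales=scales,
        explained=explained,
        layer_names=stack.layer_names,
    )


__all__ = [
    "EnvStack",
    "EnvSpace",
    "build_pca",
    "DegenerateVarianceError",
]
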