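"""Model/Results interface for SOM-based spectral stratification.

`SOMStratifier` wraps the full unsupervised arm: Frobenius row
normalisation, SOM training, observation mapping, distance-score (U-matrix)
computation and threshold cluster extraction.  The stage is blinded by
construction — the model only ever sees the intensity matrix; class labels
are rejoined afterwards through :meth:`SOMResults.composition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clusters as _clusters
from . import som as _som
from .spectra import SpectrumSet

__all__ = ["SOMStratifier", "SOMResults"]


class SOMStratifier:
    """Unsupervised SOM stratification model for a set of spectra.

    Parameters
    ----------
    data : SpectrumSet or (n_obs, n_points) matrix
        Preprocessed spectra.  Rows are Frobenius-normalised internally.
    config : SOMConfig
        Lattice and schedule settings; defaults to the standard operating
        point (14 x 10 lattice, sigma0 = 3, alpha0 = 0.75, t_max = 1e6).
    """

    def __init__(self, data, config: _som.SOMConfig | None = None):
        X = data.intensities if isinstance(data, SpectrumSet) else np.asarray(data, float)
        self.data = _som.normalize_rows(X)
        self.config = config or _som.SOMConfig()

    def fit(self, n_steps: int | None = None) -> "SOMResults":
        grid = _som.init_grid(self.config, self.data.shape[1])
        grid = _som.train(grid, self.data, self.config, n_steps=n_steps)
        hits = _som.map_observations(grid, self.data)
        dmap = _clusters.distance_map(grid)
        return SOMResults(model=self, grid=grid, hits=hits, dmap=dmap)


@dataclass
class SOMResults:
    """Trained map: grid weights, observation hits, distance scores."""

    model: SOMStratifier
    grid: _som.SOMGrid
    hits: dict[tuple[int, int], list[int]]
    dmap: _clusters.DistanceMap
    _extracted: tuple[list, pd.DataFrame] | None = field(default=None, repr=False)

    def hit_counts(self) -> np.ndarray:
        counts = np.zeros((self.dmap.y_dim, self.dmap.x_dim), int)
        for (x, y), obs in self.hits.items():
            counts[y, x] = len(obs)
        return counts

    def quantization_error(self) -> float:
        return _som.quantization_error(self.grid, self.model.data)

    def select_threshold(self, min_size: int = 6, step: float = 0.01) -> float:
        """Automatic cleft reading of the trained map's distance scores."""
        return _clusters.select_threshold(self.dmap, self.hits,
                                          min_size=min_size, step=step)

    def extract_clusters(self, threshold: float | str = 0.72,
                         min_size: int = 1):
        """Threshold clustering with boundary rules; returns (clusters, audit).

        ``threshold`` may be the string ``"auto"`` to read the threshold off
        the map (see :meth:`select_threshold`).
        """
        if threshold == "auto":
            threshold = self.select_threshold(min_size=max(min_size, 6))
        self._extracted = _clusters.extract_clusters(
            self.dmap, self.hits, float(threshold), min_size=min_size)
        return self._extracted

    def composition(self, labels: np.ndarray,
                    threshold: float | str = 0.72) -> pd.DataFrame:
        """Rejoin class labels and account cluster composition."""
        if self._extracted is None:
            self.extract_clusters(threshold)
        return _clusters.composition_table(self._extracted[0], labels)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "SOM stratification",
            "=" * 56,
            f"lattice {cfg.x_dim} x {cfg.y_dim} = {cfg.x_dim * cfg.y_dim} nodes, "
            f"sigma0={cfg.sigma0}, alpha0={cfg.alpha0}, t_max={cfg.t_max}, "
            f"seed={cfg.seed}",
            f"observations mapped: {sum(len(v) for v in self.hits.values())}",
            f"quantization error: {self.quantization_error():.5f}",
        ]
        if self._extracted is not None:
            cls, audit = self._extracted
            lines.append(f"clusters: {len(cls)}")
            for c in cls:
                lines.append(f"  {c.cluster_id}: {c.n_obs} observations over "
                             f"{len(c.member_nodes)} interior + "
                             f"{len(c.edge_nodes)} edge nodes")
            excl = audit[audit.status.str.startswith("excluded")]
            lines.append(f"excluded nodes: {len(excl)}")
        return "\n".join(lines)

    def plot_map(self, ax=None, annotate_hits: bool = True):
        """Distance-score heat map with per-node observation counts."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        im = ax.imshow(self.dmap.scores, origin="lower", cmap="bone",
                       vmin=0.0, vmax=1.0)
        if annotate_hits:
            counts = self.hit_counts()
            for y in range(self.dmap.y_dim):
                for x in range(self.dmap.x_dim):
                    if counts[y, x]:
                        ax.text(x, y, str(counts[y, x]), ha="center",
                                va="center", fontsize=7, color="tab:red")
        ax.set_xlabel("node column")
        ax.set_ylabel("node row")
        ax.figure.colorbar(im, ax=ax, label="distance score")
        return ax
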