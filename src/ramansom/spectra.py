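"""Spectrum containers and the two-file CSV layout.

A :class:`Spectrum` is a wavenumber axis (cm^-1, strictly increasing) plus an
intensity vector; a :class:`SpectrumSet` is a stack of spectra sharing one
axis, the universal currency of the pipeline.  On disk a set is stored in the
two-file layout used throughout: ``axis.csv`` holding the wavenumber axis (one
column) and ``intensities.csv`` holding the observations x wavenumber matrix,
optionally accompanied by a labels table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectrumSet"]


def _check_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("axis must be a 1-D vector with at least two points")
    if not np.all(np.isfinite(axis)):
        raise ValueError("axis contains non-finite values")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    return axis


@dataclass
class Spectrum:
    """One spectrum: wavenumber axis + intensity vector + free-form metadata."""

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.shape:
            raise ValueError("axis and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    @property
    def n_points(self) -> int:
        return self.axis.size

    def copy_with(self, intensity: np.ndarray | None = None,
                  axis: np.ndarray | None = None) -> "Spectrum":
        return Spectrum(
            axis=self.axis.copy() if axis is None else np.asarray(axis, float),
            intensity=self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            meta=dict(self.meta),
        )


@dataclass
class SpectrumSet:
    """Observations x wavenumber intensity matrix on a shared axis.

    ``labels`` is an optional per-observation class label vector (e.g.
    ``"normal"`` / ``"cancer"``); ``meta`` an optional per-observation table
    carried alongside (ground truth, ids).  Analyses that must run blinded
    (the SOM stage) receive only :attr:`intensities`.
    """

    axis: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D (n_obs x n_points) matrix")
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError("intensity rows must match the axis length")
        if self.intensities.shape[0] < 1:
            raise ValueError("a SpectrumSet needs at least one observation")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_obs:
                raise ValueError("labels must have one entry per observation")

    @property
    def n_obs(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    def __len__(self) -> int:
        return self.n_obs

    def spectrum(self, i: int) -> Spectrum:
        meta = {"observation": i}
        if self.labels is not None:
            meta["label"] = self.labels[i]
        return Spectrum(self.axis.copy(), self.intensities[i].copy(), meta)

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.axis.copy(), self.intensities.mean(axis=0),
                        {"n_obs": self.n_obs})

    def copy_with(self, intensities: np.ndarray | None = None,
                  axis: np.ndarray | None = None) -> "SpectrumSet":
        return SpectrumSet(
            axis=self.axis.copy() if axis is None else np.asarray(axis, float),
            intensities=self.intensities.copy() if intensities is None else np.asarray(intensities, float),
            labels=None if self.labels is None else self.labels.copy(),
            meta=None if self.meta is None else self.meta.copy(),
        )

    # ---------------------------------------------------------------- I/O
    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        """Write the two-file layout (plus labels, if any) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "axis": outdir / "axis.csv",
            "intensities": outdir / "intensities.csv",
        }
        pd.DataFrame({"wavenumber_cm1": self.axis}).to_csv(paths["axis"], index=False)
        pd.DataFrame(self.intensities).to_csv(paths["intensities"], index=False, header=False)
        if self.meta is not None:
            paths["truth"] = outdir / "truth.csv"
            self.meta.to_csv(paths["truth"], index=False)
        elif self.labels is not None:
            paths["truth"] = outdir / "truth.csv"
            pd.DataFrame({"observation_id": np.arange(self.n_obs),
                          "class": self.labels}).to_csv(paths["truth"], index=False)
        return paths

    @classmethod
    def from_csv(cls, axis_path: str | Path, intensities_path: str | Path,
                 truth_path: str | Path | None = None) -> "SpectrumSet":
        axis = pd.read_csv(axis_path).iloc[:, 0].to_numpy(float)
        intensities = pd.read_csv(intensities_path, header=None).to_numpy(float)
        labels = None
        meta = None
        if truth_path is not None:
            meta = pd.read_csv(truth_path)
            if "class" in meta.columns:
                labels = meta["class"].to_numpy()
        return cls(axis=axis, intensities=intensities, labels=labels, meta=meta)
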