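"""Gaussian multi-peak fitting, band-difference biomarkers and peak ratios.

Average spectra are fitted per local window (a linear baseline plus a sum of
Gaussians, height-parameterised) with constrained nonlinear least squares;
windows default to +/-25 cm^-1 around each requested band centre and are
merged when they overlap.  Fitted heights carry standard errors from the
covariance of the fit.  Band differences between two fitted models use
quadrature-combined SEs, with a difference flagged significant when its
magnitude exceeds that combined SE; a peak-intensity ratio carries the
linear sum of the component relative SEs, the convention used for this kind
of biomarker table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "PeakModel", "BandDifference", "PIRResult", "build_windows", "fit_bands",
    "band_differences", "peak_intensity_ratio",
]

#: half-width of the default local fit window around each requested centre
DEFAULT_WINDOW_HALFWIDTH = 25.0
#: how far a fitted centre may wander from the requested position
CENTRE_TOLERANCE = 8.0
SIGMA_BOUNDS = (3.0, 40.0)


@dataclass
class BandFit:
    """One fitted Gaussian band (height parameterisation) with SEs."""

    centre_requested: float
    centre: float
    centre_se: float
    height: float
    height_se: float
    sigma: float
    sigma_se: float
    window: tuple[float, float]
    area: float = 0.0
    area_se: float = float("nan")


@dataclass
class PeakModel:
    """Results object of :func:`fit_bands`: bands sorted by centre.

    ``failures`` lists windows whose fit did not converge (other windows are
    unaffected); ``baselines`` holds the per-window linear baseline
    (slope, intercept).
    """

    bands: list[BandFit]
    baselines: dict[tuple[float, float], tuple[float, float]] = field(default_factory=dict)
    failures: list[tuple[float, float]] = field(default_factory=list)
    intensity_measure: str = "height"

    def band(self, centre: float) -> BandFit:
        for b in self.bands:
            if b.centre_requested == centre:
                return b
        raise KeyError(f"no fitted band requested at {centre} cm^-1")

    def intensity(self, centre: float) -> tuple[float, float]:
        """(value, SE) of the configured intensity measure for one band."""
        b = self.band(centre)
        if self.intensity_measure == "area":
            return b.area, b.area_se
        return b.height, b.height_se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "centre_requested": b.centre_requested, "centre": b.centre,
            "centre_se": b.centre_se, "height": b.height,
            "height_se": b.height_se, "sigma": b.sigma, "sigma_se": b.sigma_se,
            "window_lo": b.window[0], "window_hi": b.window[1],
        } for b in self.bands])

    def summary(self) -> str:
        lines = ["Gaussian band fit", "=" * 64,
                 f"{'centre':>8} {'height':>10} {'+/-':>8} {'sigma':>8} {'+/-':>8}"]
        for b in self.bands:
            lines.append(f"{b.centre:8.1f} {b.height:10.4g} {b.height_se:8.2g} "
                         f"{b.sigma:8.2f} {b.sigma_se:8.2g}")
        if self.failures:
            lines.append(f"failed windows: {self.failures}")
        return "\n".join(lines)


@dataclass
class BandDifference:
    """height(condition) - height(reference) at one band, with propagated SE."""

    centre: float
    delta: float
    se: float
    direction: str          # "up" | "down" | "none"
    significant: bool


@dataclass
class PIRResult:
    """Ratio of two fitted band heights with linearly-propagated uncertainty."""

    numerator_centre: float
    denominator_centre: float
    ratio: float
    se: float


def build_windows(band_centres, halfwidth: float = DEFAULT_WINDOW_HALFWIDTH
                  ) -> list[tuple[tuple[float, float], list[float]]]:
    """Local fit windows +/-halfwidth around each centre, merged on overlap.

    Returns (window interval, centres inside it) pairs, sorted.
    """
    centres = sorted(float(c) for c in band_centres)
    if not centres:
        raise ValueError("need at least one band centre")
    windows: list[tuple[list[float], list[float]]] = []
    for c in centres:
        lo, hi = c - halfwidth, c + halfwidth
        if windows and lo <= windows[-1][0][1]:
            windows[-1][0][1] = max(windows[-1][0][1], hi)
            windows[-1][1].append(c)
        else:
            windows.append([[lo, hi], [c]])
    return [((w[0], w[1]), cs) for w, cs in windows]


def _gaussian(x, height, center, sigma):
    return height * np.exp(-((x - center) ** 2) / (2.0 * sigma ** 2))


def _fit_window(axis: np.ndarray, intensity: np.ndarray,
                window: tuple[float, float], centres: list[float]):
    mask = (axis >= window[0]) & (axis <= window[1])
    x, y = axis[mask], intensity[mask]
    if x.size < 5:
        raise ValueError(f"window {window} holds fewer than 5 points")

    params = lmfit.Parameters()
    slope = (y[-1] - y[0]) / (x[-1] - x[0])  # through the window end points
    params.add("bl_slope", value=slope)
    params.add("bl_intercept", value=y[0] - slope * x[0])
    span = max(y.max() - min(y.min(), 0.0), 1e-12)
    for i, c in enumerate(centres):
        j = int(np.argmin(np.abs(x - c)))
        guess = max(y[j] - (params["bl_intercept"].value
                            + params["bl_slope"].value * c), 0.05 * span)
        params.add(f"g{i}_height", value=guess, min=0.0)
        params.add(f"g{i}_center", value=c, min=c - CENTRE_TOLERANCE,
                   max=c + CENTRE_TOLERANCE)
        params.add(f"g{i}_sigma", value=10.0, min=SIGMA_BOUNDS[0],
                   max=SIGMA_BOUNDS[1])
    n = len(centres)

    def residual(p):
        v = p.valuesdict()
        model = v["bl_slope"] * x + v["bl_intercept"]
        for i in range(n):
            model = model + _gaussian(x, v[f"g{i}_height"],
                                      v[f"g{i}_center"], v[f"g{i}_sigma"])
        return model - y

    return lmfit.minimize(residual, params)


def fit_bands(avg: Spectrum, band_centres, windows=None,
              halfwidth: float = DEFAULT_WINDOW_HALFWIDTH,
              intensity_measure: str = "height") -> PeakModel:
    """Fit linear baseline + Gaussians per local window of an average spectrum.

    ``windows`` may supply explicit (interval, centres) pairs; by default
    they are built with :func:`build_windows`.  A window whose fit raises or
    does not converge is recorded in ``failures`` without affecting others.
    """
    if intensity_measure not in ("height", "area"):
        raise ValueError("intensity_measure must be 'height' or 'area'")
    plan = windows if windows is not None else build_windows(band_centres, halfwidth)
    bands: list[BandFit] = []
    baselines: dict = {}
    failures: list = []
    for window, centres in plan:
        window = (float(window[0]), float(window[1]))
        try:
            result = _fit_window(avg.axis, avg.intensity, window, centres)
            if not result.success:
                raise RuntimeError(result.message)
        except Exception:
            failures.append(window)
            continue
        p = result.params
        baselines[window] = (p["bl_slope"].value, p["bl_intercept"].value)

        def se(name: str) -> float:
            err = p[name].stderr
            return float(err) if err is not None else float("nan")

        for i, c in enumerate(centres):
            h = p[f"g{i}_height"].value
            s = p[f"g{i}_sigma"].value
            h_se, s_se = se(f"g{i}_height"), se(f"g{i}_sigma")
            area = h * s * np.sqrt(2.0 * np.pi)
            # first-order propagation for the alternative area measure
            if np.isfinite(h_se) and np.isfinite(s_se) and h > 0 and s > 0:
                area_se = area * np.hypot(h_se / h, s_se / s)
            else:
                area_se = float("nan")
            bands.append(BandFit(
                centre_requested=c, centre=p[f"g{i}_center"].value,
                centre_se=se(f"g{i}_center"), height=h, height_se=h_se,
                sigma=s, sigma_se=s_se, window=window, area=area,
                area_se=area_se))
    bands.sort(key=lambda b: b.centre_requested)
    return PeakModel(bands=bands, baselines=baselines, failures=failures,
                     intensity_measure=intensity_measure)


def band_differences(m_cond: PeakModel, m_ref: PeakModel) -> list[BandDifference]:
    """Per-band intensity difference condition - reference.

    SEs combine in quadrature; a difference is significant when its
    magnitude exceeds the combined SE.  Antisymmetric in its arguments.
    """
    cond_centres = [b.centre_requested for b in m_cond.bands]
    ref_centres = [b.centre_requested for b in m_ref.bands]
    if cond_centres != ref_centres:
        raise ValueError("models were not fitted over the same band list")
    out = []
    for c in cond_centres:
        v1, se1 = m_cond.intensity(c)
        v0, se0 = m_ref.intensity(c)
        delta = v1 - v0
        se = float(np.hypot(se1, se0))
        direction = "up" if delta > 0 else ("down" if delta < 0 else "none")
        out.append(BandDifference(centre=c, delta=delta, se=se,
                                  direction=direction,
                                  significant=bool(abs(delta) > se)))
    return out


def peak_intensity_ratio(m: PeakModel, num_centre: float,
                         den_centre: float) -> PIRResult:
    """Ratio of two fitted heights; SE = ratio * (rel SE num + rel SE den)."""
    h_num, se_num = m.intensity(num_centre)
    h_den, se_den = m.intensity(den_centre)
    if h_den <= 0:
        raise ZeroDivisionError("denominator band height must be positive")
    ratio = h_num / h_den
    se = ratio * (se_num / h_num + se_den / h_den) if h_num > 0 else se_num / h_den
    return PIRResult(numerator_centre=float(num_centre),
                     denominator_centre=float(den_centre),
                     ratio=float(ratio), se=float(se))
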