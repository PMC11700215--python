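"""Synthetic single-cell Raman spectrum generator.

Emulates the statistical structure the downstream analysis assumes: two cell
populations (a normal line and a cancer line) measured in the high-wavenumber
C-H stretching window, 1056 points on 2700-3100 cm^-1, with nine Gaussian
bands at the canonical lipid/protein band centres.  The cancer class mixes
three latent sub-profiles: a protein-rich state (CH3 bands up, CH2 fatty-acid
band down), a lipid-rich state (CH2 / unsaturated =CH bands up, CH3 and
cholesterol/cholesterol-ester bands down) and a diffuse remainder sitting at
the class mean with a larger cell-to-cell variability, which is what keeps it
unclustered on the map.  Each cell draws per-band amplitudes from a log-normal
jitter (positivity-preserving), sits on a cubic polynomial background and gets
i.i.d. additive Gaussian noise.

Default effect directions follow the known disease-state band shifts (total
fatty-acid CH2 at 2852 and unsaturated =CH at 3015 up in cancer; CH3 protein
markers at 2933/2966 up in the protein-rich state); magnitudes are a one-time
calibration so each discriminative band shifts by roughly 2-4x the per-band
within-profile SD (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "BAND_CENTRES",
    "BandSpec",
    "PopulationProfile",
    "SynthConfig",
    "make_default_profiles",
    "generate_spectrum",
    "generate_dataset",
    "save_dataset",
]

#: The nine high-wavenumber band centres (cm^-1) used throughout the pipeline.
BAND_CENTRES: tuple[float, ...] = (2727.0, 2852.0, 2872.0, 2894.0, 2933.0,
                                   2941.0, 2966.0, 3015.0, 3064.0)

# Mean band heights of the normal profile (arbitrary intensity units) and the
# Gaussian widths (sigma, cm^-1).  Widths at 2933/2941 are deliberately
# distinct (narrow + broad) as the two bands are only 8 cm^-1 apart.
_BASE_AMP = {2727.0: 0.5, 2852.0: 4.0, 2872.0: 3.5, 2894.0: 3.0, 2933.0: 6.0,
             2941.0: 5.0, 2966.0: 3.0, 3015.0: 1.0, 3064.0: 1.5}
_SIGMA = {2727.0: 14.0, 2852.0: 12.0, 2872.0: 11.0, 2894.0: 13.0, 2933.0: 10.0,
          2941.0: 20.0, 2966.0: 12.0, 3015.0: 13.0, 3064.0: 15.0}

# Amplitude and width multipliers of the two latent cancer sub-profiles
# relative to the normal baseline.  The protein-rich state raises the
# 2933/2966 CH3 markers and the aromatic protein band at 3064 (its
# signature), lowers the 2852 CH2 band, and sharpens its protein bands; the
# lipid-rich state raises 2852/2894 and the unsaturated =CH 3015 marker (its
# signature, with a narrowed ordered-lipid 2852) and lowers the CH3 bands.
# A shared "cancer" component (2727 up; 2941 down) gives the class a common
# axis against normal, and the two sub-state deviation axes are kept close
# to orthogonal in shape space so the map separates all three states; the
# weighted class mean reproduces the full-population disease-state sign
# pattern at all nine centres.
_B_MULT = {2727.0: 1.70, 2852.0: 0.65, 2872.0: 1.20, 2894.0: 0.90, 2933.0: 1.22,
           2941.0: 0.62, 2966.0: 1.40, 3015.0: 1.50, 3064.0: 2.40}
_C_MULT = {2727.0: 1.70, 2852.0: 1.25, 2872.0: 0.75, 2894.0: 1.30, 2933.0: 0.85,
           2941.0: 0.62, 2966.0: 0.80, 3015.0: 2.50, 3064.0: 0.60}
_B_WIDTH_MULT = {2933.0: 0.70, 3015.0: 0.90, 3064.0: 1.45}
_C_WIDTH_MULT = {2852.0: 0.75, 3015.0: 0.80, 2894.0: 1.25}
#: protein-rich cells mix a per-cell fraction lambda ~ U(0, _B_TAIL) toward
#: the population centre, a continuum tail connecting the state inward
_B_TAIL = 0.3
#: diffuse remainder: collective wavenumber drift (cm^-1) and width scaling
_DIFFUSE_SHIFT_SD = 10.0
_DIFFUSE_WIDTH_CV = 0.25

# Cell-to-cell amplitude coefficient of variation: tight for the three
# coherent states, looser for the diffuse unclustered remainder (whose main
# heterogeneity is the collective drift above).
_CV_CORE = 0.05
_CV_DIFFUSE = 0.15

# Sub-profile mixing inside the cancer class, mirroring the study's margins
# (18 protein-rich + 73 lipid-rich of 130, remainder diffuse).
_W_B = 18.0 / 130.0
_W_C = 73.0 / 130.0

# Cubic background in the scaled coordinate x = (nu - 2900) / 200, low-order
# coefficients first.  Shared across profiles; the preprocessing stage is
# responsible for removing it.
_BASELINE = (1.5, 0.3, -0.2, 0.1)
_BASELINE_CENTRE = 2900.0
_BASELINE_SCALE = 200.0


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: centre/width in cm^-1, mean height, cell-to-cell CV.

    ``centre_sd`` and ``width_cv`` add per-cell positional and width jitter
    (molecular-scale heterogeneity); both default to zero so coherent states
    vary in amplitude only.
    """

    centre: float
    width: float
    amplitude: float
    amplitude_cv: float = 0.0
    centre_sd: float = 0.0
    width_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0 or self.amplitude_cv < 0:
            raise ValueError("amplitude and amplitude_cv must be non-negative")
        if self.centre_sd < 0 or self.width_cv < 0:
            raise ValueError("centre_sd and width_cv must be non-negative")


@dataclass
class PopulationProfile:
    """A latent cell state: its band set, background and within-class weight.

    Optional heterogeneity structure beyond per-band amplitude jitter:
    ``collective_shift_sd`` / ``collective_width_cv`` draw one wavenumber
    offset and one width factor per cell applied to every band (instrument
    drift / conformational heterogeneity); ``tail_bands`` with
    ``tail_max`` > 0 mix each cell a random fraction lambda ~ U(0, tail_max)
    toward another band set, producing a continuum tail of intermediate
    cells.
    """

    name: str
    class_label: str
    bands: list[BandSpec]
    baseline_coeffs: tuple[float, ...] = (0.0,)
    mixing_weight: float = 1.0
    collective_shift_sd: float = 0.0
    collective_width_cv: float = 0.0
    tail_bands: list[BandSpec] | None = None
    tail_max: float = 0.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("profile needs at least one band")
        if len(self.baseline_coeffs) > 4:
            raise ValueError("baseline polynomial degree must be <= 3")
        if not (0.0 <= self.mixing_weight <= 1.0):
            raise ValueError("mixing_weight must lie in [0, 1]")
        if self.collective_shift_sd < 0 or self.collective_width_cv < 0:
            raise ValueError("collective jitter scales must be >= 0")
        if not (0.0 <= self.tail_max <= 1.0):
            raise ValueError("tail_max must lie in [0, 1]")
        if self.tail_max > 0 and (self.tail_bands is None
                                  or len(self.tail_bands) != len(self.bands)):
            raise ValueError("tail_bands must match the band list")

    def amplitude(self, centre: float) -> float:
        """Mean height of the band at ``centre`` (exact match on centre)."""
        for b in self.bands:
            if b.centre == centre:
                return b.amplitude
        raise KeyError(f"no band at {centre} cm^-1 in profile {self.name!r}")

    def band_sum(self, axis: np.ndarray,
                 amplitudes: np.ndarray | None = None) -> np.ndarray:
        """Analytic sum of the profile's Gaussian bands on ``axis``."""
        axis = np.asarray(axis, float)
        amps = ([b.amplitude for b in self.bands]
                if amplitudes is None else amplitudes)
        out = np.zeros_like(axis)
        for b, a in zip(self.bands, amps):
            out += a * np.exp(-((axis - b.centre) ** 2) / (2.0 * b.width ** 2))
        return out

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        x = (np.asarray(axis, float) - _BASELINE_CENTRE) / _BASELINE_SCALE
        return np.polynomial.polynomial.polyval(x, list(self.baseline_coeffs))


@dataclass
class SynthConfig:
    """Dataset-level settings: class sizes, axis grid, noise scale, seed."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"normal": 154, "cancer": 130})
    axis_start: float = 2700.0
    axis_stop: float = 3100.0
    n_points: int = 1056
    noise_sd: float = 0.05
    seed: int = 0
    stratified: bool = True  # exact sub-profile counts; False -> multinomial
    shuffle: bool = True     # randomised acquisition order (blinded layout)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.axis_stop <= self.axis_start:
            raise ValueError("axis_stop must exceed axis_start")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_start, self.axis_stop, self.n_points)

    def to_dict(self) -> dict:
        return {
            "n_per_class": dict(self.n_per_class),
            "axis_start": self.axis_start,
            "axis_stop": self.axis_stop,
            "n_points": self.n_points,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "stratified": self.stratified,
        }


def _profile(name: str, class_label: str, mult: dict[float, float] | None,
             cv: float, weight: float, centre_sd: float = 0.0,
             width_cv: float = 0.0,
             wmult: dict[float, float] | None = None) -> PopulationProfile:
    bands = []
    for c in BAND_CENTRES:
        amp = _BASE_AMP[c] * (1.0 if mult is None else mult[c])
        width = _SIGMA[c] * (1.0 if wmult is None else wmult.get(c, 1.0))
        bands.append(BandSpec(centre=c, width=width, amplitude=amp,
                              amplitude_cv=cv, centre_sd=centre_sd,
                              width_cv=width_cv))
    return PopulationProfile(name=name, class_label=class_label, bands=bands,
                             baseline_coeffs=_BASELINE, mixing_weight=weight)


def make_default_profiles(effect_scale: float = 1.0,
                          diffuse_cv: float = _CV_DIFFUSE,
                          core_cv: float = _CV_CORE
                          ) -> list[PopulationProfile]:
    """The three-state default population: normal_A, cancer_B, cancer_C.

    cancer_B is the protein-rich sub-state (2933 and 2966 raised, 2852
    lowered relative to normal_A, with its own aromatic 3064 signature and
    a continuum tail toward the population centre); cancer_C the lipid-rich
    one (2852, 2894 and 3015 raised, 2933 and 2966 lowered).  A fourth
    diffuse profile, ``cancer_unclustered``, carries the cancer class-mean
    band set with a large per-cell collective wavenumber drift and width
    scaling — these atypical cells scatter to the map boundary rather than
    forming a coherent mode, and take the remaining mixing weight so the
    class margins mirror the study (18 + 73 clustered of 130).

    ``effect_scale`` scales every band-amplitude deviation from the normal
    baseline (1.0 = the calibrated default).
    """
    def scaled(mult: dict[float, float]) -> dict[float, float]:
        return {k: 1.0 + effect_scale * (v - 1.0) for k, v in mult.items()}

    b_mult, c_mult = scaled(_B_MULT), scaled(_C_MULT)
    normal = _profile("normal_A", "normal", None, core_cv, 1.0)
    b = _profile("cancer_B", "cancer", b_mult, core_cv, _W_B,
                 wmult=_B_WIDTH_MULT)
    c = _profile("cancer_C", "cancer", c_mult, core_cv, _W_C,
                 wmult=_C_WIDTH_MULT)
    # protein-rich cells carry a continuum tail toward the overall
    # population centre (intermediate cells anchoring the state inside the
    # main spectral manifold)
    centre_mult = {k: 0.5 * (1.0 + c_mult[k]) for k in c_mult}
    centre_wmult = {k: 0.5 * (1.0 + _C_WIDTH_MULT.get(k, 1.0))
                    for k in c_mult}
    b.tail_bands = _profile("_centre", "cancer", centre_mult, 0.0, 1.0,
                            wmult=centre_wmult).bands
    b.tail_max = _B_TAIL
    # diffuse remainder: cancer class-mean amplitudes/widths with a large
    # per-cell collective wavenumber drift and width scaling — atypical
    # cells that scatter to the map boundary instead of forming a mode
    wb, wc = _W_B / (_W_B + _W_C), _W_C / (_W_B + _W_C)
    mean_mult = {k: wb * b_mult[k] + wc * c_mult[k] for k in b_mult}
    mean_wmult = {k: wb * _B_WIDTH_MULT.get(k, 1.0)
                  + wc * _C_WIDTH_MULT.get(k, 1.0) for k in b_mult}
    diffuse = _profile("cancer_unclustered", "cancer", mean_mult, diffuse_cv,
                       1.0 - _W_B - _W_C, wmult=mean_wmult)
    diffuse.collective_shift_sd = _DIFFUSE_SHIFT_SD
    diffuse.collective_width_cv = _DIFFUSE_WIDTH_CV
    return [normal, b, c, diffuse]


def generate_spectrum(profile: PopulationProfile, config: SynthConfig,
                      rng: np.random.Generator) -> Spectrum:
    """Draw one cell's spectrum: jittered band sum + background + noise.

    Per-cell band heights come from a log-normal with mean equal to the
    profile amplitude and the stated CV (a CV of zero reproduces the
    amplitude exactly); noise is i.i.d. Gaussian with ``config.noise_sd``.
    """
    axis = config.axis()

    def lognorm(mean: float, cv: float) -> float:
        if cv == 0.0 or mean == 0.0:
            return mean
        s2 = np.log1p(cv ** 2)
        return rng.lognormal(mean=np.log(mean) - 0.5 * s2, sigma=np.sqrt(s2))

    lam = rng.uniform(0.0, profile.tail_max) if profile.tail_max > 0 else 0.0
    shift = (rng.normal(0.0, profile.collective_shift_sd)
             if profile.collective_shift_sd > 0 else 0.0)
    wfac = lognorm(1.0, profile.collective_width_cv)

    intensity = profile.baseline(axis)
    for i, b in enumerate(profile.bands):
        a0, c0, w0 = b.amplitude, b.centre, b.width
        if lam > 0:
            t = profile.tail_bands[i]
            a0 = (1.0 - lam) * a0 + lam * t.amplitude
            c0 = (1.0 - lam) * c0 + lam * t.centre
            w0 = (1.0 - lam) * w0 + lam * t.width
        amp = lognorm(a0, b.amplitude_cv)
        centre = c0 + shift
        if b.centre_sd > 0:
            centre = rng.normal(centre, b.centre_sd)
        width = lognorm(w0, b.width_cv) * wfac
        intensity = intensity + amp * np.exp(
            -((axis - centre) ** 2) / (2.0 * width ** 2))
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, axis.size)
    return Spectrum(axis, intensity, {"profile": profile.name,
                                      "class": profile.class_label})


def _assign_subprofiles(profiles: list[PopulationProfile], n: int,
                        stratified: bool,
                        rng: np.random.Generator) -> np.ndarray:
    """Indices into ``profiles`` for ``n`` cells of one class."""
    weights = np.array([p.mixing_weight for p in profiles], float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixing weights within a class must sum to 1")
    if stratified:
        # largest-remainder apportionment -> exact deterministic counts
        raw = weights * n
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        for i in np.argsort(-rem)[: n - counts.sum()]:
            counts[i] += 1
        idx = np.repeat(np.arange(len(profiles)), counts)
    else:
        idx = rng.choice(len(profiles), size=n, p=weights)
    return idx


def generate_dataset(config: SynthConfig | None = None,
                     profiles: list[PopulationProfile] | None = None,
                     ) -> tuple[SpectrumSet, pd.DataFrame]:
    """Generate a labelled dataset plus its ground-truth table.

    Returns the :class:`SpectrumSet` (labels attached for later un-blinding;
    the SOM stage must only be handed the intensity matrix) and a truth table
    with one row per observation: ``observation_id``, ``class``,
    ``sub_profile``.
    """
    config = config or SynthConfig()
    profiles = profiles if profiles is not None else make_default_profiles()
    rng = np.random.default_rng(config.seed)
    axis = config.axis()

    by_class: dict[str, list[PopulationProfile]] = {}
    for p in profiles:
        by_class.setdefault(p.class_label, []).append(p)

    rows, classes, subs = [], [], []
    for class_label, n in config.n_per_class.items():
        if n == 0:
            continue
        if class_label not in by_class:
            raise ValueError(f"no profile for class {class_label!r}")
        members = by_class[class_label]
        idx = _assign_subprofiles(members, n, config.stratified, rng)
        for i in idx:
            prof = members[i]
            rows.append(generate_spectrum(prof, config, rng).intensity)
            classes.append(class_label)
            subs.append(prof.name)
    if not rows:
        raise ValueError("empty dataset: all class counts are zero")

    rows = np.asarray(rows)
    classes = np.asarray(classes)
    subs = np.asarray(subs)
    if config.shuffle and len(rows) > 1:
        order = rng.permutation(len(rows))
        rows, classes, subs = rows[order], classes[order], subs[order]

    truth = pd.DataFrame({
        "observation_id": np.arange(len(rows)),
        "class": classes,
        "sub_profile": subs,
    })
    sset = SpectrumSet(axis=axis, intensities=rows, labels=classes,
                       meta=truth)
    return sset, truth


def save_dataset(sset: SpectrumSet, truth: pd.DataFrame, config: SynthConfig,
                 outdir: str | Path) -> dict[str, Path]:
    """Write axis.csv / intensities.csv / truth.csv plus the config YAML."""
    outdir = Path(outdir)
    paths = sset.to_csv(outdir)
    paths["truth"] = outdir / "truth.csv"
    truth.to_csv(paths["truth"], index=False)
    paths["config"] = outdir / "synth_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths
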