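"""Raw measurements to phenotype traits: photon catches and pattern metrics.

Colour and luminance are quantified as receptor photon catches

    Q_i = integral of R(lambda) * I(lambda) * S_i(lambda) d(lambda)

for an avian visual system with UV, SW, MW and LW single cones and double
cones (the luminance channel): R is the egg's reflectance, I the illuminant
irradiance and S_i the receptor's spectral sensitivity.  Catches are
optionally normalized so that a perfect white reflector (R = 1) scores 1.

Pattern is quantified by granularity analysis: the masked egg image is
decomposed into octave spatial-frequency bands by Fourier bandpass
filtering, and the energy-per-band profile summarizes marking size and
contrast.  Five scalar pattern metrics are derived from it: predominant
marking size, contribution of the main marking to overall pattern, pattern
contrast, proportion of the egg surface covered by markings, and dispersion
of markings along the egg's long axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

RECEPTORS = ("uv", "sw", "mw", "lw", "double")

# Idealized Gaussian receptor templates (peak nm, bandwidth nm).  These are
# synthetic curves standing in for measured cone sensitivities; the analyses
# only require a plausible avian tetrachromatic system, not a particular
# species' eye.
_RECEPTOR_PEAKS = {
    "uv": (370.0, 25.0),
    "sw": (445.0, 30.0),
    "mw": (508.0, 35.0),
    "lw": (565.0, 40.0),
    "double": (560.0, 80.0),
}


@dataclass
class ReflectanceSpectrum:
    wavelengths: np.ndarray  # strictly increasing, nm
    reflectance: np.ndarray  # in [0, 1]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelength and reflectance grids differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.reflectance < -1e-9) or np.any(self.reflectance > 1 + 1e-9):
            raise ValueError("reflectance must lie in [0, 1]")


@dataclass
class VisualSystem:
    """Illuminant irradiance plus one sensitivity curve per receptor class."""

    wavelengths: np.ndarray
    illuminant: np.ndarray
    sensitivities: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.illuminant = np.asarray(self.illuminant, dtype=float)
        if np.any(self.illuminant < 0):
            raise ValueError("illuminant must be non-negative")
        for name, s in self.sensitivities.items():
            s = np.asarray(s, dtype=float)
            if s.shape != self.wavelengths.shape:
                raise ValueError(f"sensitivity {name!r} not on the system grid")
            if np.any(s < 0):
                raise ValueError(f"sensitivity {name!r} has negative values")
            self.sensitivities[name] = s

    @classmethod
    def idealized(cls, wl_min: float = 300.0, wl_max: float = 700.0,
                  step: float = 1.0) -> "VisualSystem":
        """Synthetic tetrachromatic system: Gaussian cones, flat illuminant."""
        wl = np.arange(wl_min, wl_max + step / 2, step)
        sens = {
            name: np.exp(-0.5 * ((wl - peak) / width) ** 2)
            for name, (peak, width) in _RECEPTOR_PEAKS.items()
        }
        return cls(wl, np.ones_like(wl), sens)


def photon_catch(
    spectrum: ReflectanceSpectrum,
    vis: VisualSystem,
    receptor: str,
    normalize: bool = True,
) -> float:
    """Receptor photon catch of a reflectance spectrum.

    The reflectance is linearly interpolated onto the part of the visual
    system's wavelength grid that the spectrum covers, and the product
    R * I * S_i is integrated by the trapezoid rule.  With ``normalize`` the
    catch is divided by the catch of a perfect white (R = 1), so the result
    is a dimensionless index in [0, 1] for physical reflectances.
    """
    if receptor not in vis.sensitivities:
        raise KeyError(f"unknown receptor {receptor!r}")
    lo = max(vis.wavelengths[0], spectrum.wavelengths[0])
    hi = min(vis.wavelengths[-1], spectrum.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectrum and visual system wavelength ranges are disjoint")
    keep = (vis.wavelengths >= lo) & (vis.wavelengths <= hi)
    wl = vis.wavelengths[keep]
    refl = np.interp(wl, spectrum.wavelengths, spectrum.reflectance)
    weight = vis.illuminant[keep] * vis.sensitivities[receptor][keep]
    q = np.trapezoid(refl * weight, wl)
    if normalize:
        white = np.trapezoid(weight, wl)
        if white <= 0:
            raise ValueError(f"receptor {receptor!r} has zero response in range")
        q /= white
    return float(q)


@dataclass
class EggImage:
    pixels: np.ndarray  # 2-D grayscale
    mask: np.ndarray    # boolean egg region, same shape

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.shape != self.mask.shape:
            raise ValueError("pixels must be 2-D and match the mask shape")
        if not self.mask.any():
            raise ValueError("egg mask is empty")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")


@dataclass
class GranularitySpectrum:
    scales: np.ndarray    # descending band sizes, px
    energies: np.ndarray  # mean squared bandpassed value inside the mask

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.scales.shape != self.energies.shape:
            raise ValueError("scales and energies differ in length")
        if np.any(self.energies < -1e-12):
            raise ValueError("energies must be non-negative")

    @property
    def total_energy(self) -> float:
        return float(self.energies.sum())


def _octave_scales(img_shape: tuple[int, int], n_bands: int | None) -> np.ndarray:
    largest = min(img_shape) / 2
    scales = []
    s = largest
    while s >= 2.0 and (n_bands is None or len(scales) < n_bands):
        scales.append(s)
        s /= 2
    return np.array(scales)


def granularity_spectrum(img: EggImage, n_bands: int | None = None) -> GranularitySpectrum:
    """Octave-band Fourier energy spectrum of the masked egg image.

    Pixels outside the mask are replaced by the masked mean and the mean is
    subtracted, so the transform carries no DC component.  Bands are
    half-open annuli of Euclidean spatial frequency: the coarsest band
    covers structure sizes down to half the smaller image dimension, each
    subsequent band halves the size, and the finest band absorbs everything
    up to the Nyquist frequency so the bands tile the frequency plane.
    Band energy is the mean squared bandpassed value inside the mask.
    """
    if int(img.mask.sum()) < 64:
        raise ValueError("mask area must be at least 64 px")
    scales = _octave_scales(img.pixels.shape, n_bands)
    if len(scales) < 2:
        raise ValueError("image too small: fewer than 2 feasible octave bands")
    mean_val = img.pixels[img.mask].mean()
    work = np.where(img.mask, img.pixels, mean_val) - mean_val
    F = np.fft.fft2(work)
    fy = np.fft.fftfreq(work.shape[0])[:, None]
    fx = np.fft.fftfreq(work.shape[1])[None, :]
    freq = np.hypot(fy, fx)
    # cutoff frequencies: DC < f <= 1/s_0 is band 0, 1/s_0 < f <= 1/s_1 band 1, ...
    energies = []
    prev = 0.0
    for i, s in enumerate(scales):
        hi = np.inf if i == len(scales) - 1 else 1.0 / s
        band = (freq > prev) & (freq <= hi) if np.isfinite(hi) else (freq > prev)
        filtered = np.fft.ifft2(F * band).real
        energies.append(float(np.mean(filtered[img.mask] ** 2)))
        prev = hi
    return GranularitySpectrum(scales, np.array(energies))


def pattern_metrics(img: EggImage, gran: GranularitySpectrum | None = None,
                    n_zones: int = 5) -> dict[str, float]:
    """The five scalar pattern traits.

    marking_size
        Scale (px) of the granularity band with maximal energy, i.e. the
        predominant marking size; NaN for a patternless image.
    main_contribution
        Energy at the dominant scale as a fraction of total energy.
    contrast
        Square root of total band energy — the RMS amplitude of the
        pattern relative to the egg's mean.
    coverage
        Fraction of mask pixels darker than an adaptive (Otsu) threshold.
    dispersion
        Coefficient of variation of coverage across ``n_zones`` equal-length
        zones along the egg's long axis; large values mean markings are
        concentrated at one end.
    """
    if gran is None:
        gran = granularity_spectrum(img)
    total = gran.total_energy
    if total <= 1e-18:
        marking_size, main_contribution, contrast = float("nan"), 0.0, 0.0
    else:
        k = int(np.argmax(gran.energies))
        marking_size = float(gran.scales[k])
        main_contribution = float(gran.energies[k] / total)
        contrast = float(np.sqrt(total))

    vals = img.pixels[img.mask]
    if np.ptp(vals) < 1e-12:
        coverage = 0.0
        dark = np.zeros_like(img.mask)
    else:
        thr = threshold_otsu(vals)
        dark = img.mask & (img.pixels < thr)
        coverage = float(dark.sum() / img.mask.sum())

    # longitudinal zones follow the longer image axis of the mask bounding box
    axis = 0 if img.pixels.shape[0] >= img.pixels.shape[1] else 1
    idx = np.where(img.mask.any(axis=1 - axis))[0]
    edges = np.linspace(idx[0], idx[-1] + 1, n_zones + 1)
    zone_cov = []
    for a, b in zip(edges[:-1], edges[1:]):
        sl = (slice(int(a), int(b)), slice(None)) if axis == 0 else (slice(None), slice(int(a), int(b)))
        zmask = img.mask[sl]
        if zmask.sum() == 0:
            continue
        zone_cov.append(dark[sl].sum() / zmask.sum())
    zone_cov = np.array(zone_cov)
    mean_cov = zone_cov.mean() if len(zone_cov) else 0.0
    dispersion = float(zone_cov.std(ddof=0) / mean_cov) if mean_cov > 0 else 0.0

    return {
        "marking_size": marking_size,
        "main_contribution": main_contribution,
        "contrast": contrast,
        "coverage": coverage,
        "dispersion": dispersion,
    }
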