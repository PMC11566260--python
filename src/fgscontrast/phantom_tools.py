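"""Instrument-characterization computations on imaging phantoms.

Three characterizations are covered:

* **Tube FWHM** — a thin dye-filled tube imaged at depth yields a bright
  ridge; the full width at half maximum of the mean perpendicular intensity
  profile measures blur/scattering, and comparing FWHM across emission-filter
  configurations drives the filter choice (a small FWHM penalty can buy a
  large noise reduction).
* **Liquid-phantom sensitivity** — a dilution series of wells; the lowest
  detectable concentration is the smallest well whose SNR clears the 3-sigma
  (> 9.5 dB) rule with every more-concentrated well also detectable.
* **Spectral-response correction** — the recorded spectrum of a calibrated
  halogen lamp is divided into a black-body fit of the lamp's emission,
  yielding a per-wavelength correction curve (proportional to the inverse
  detector response) that is applied multiplicatively to raw spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants, optimize

from .core import ModalityImage
from .line_analysis import LineSpec, extract_subimage
from .slice_metrics import RoiStats, is_detectable, snr_db

__all__ = [
    "Spectrum",
    "FwhmResult",
    "BlackbodyFit",
    "FilterTradeoff",
    "mean_perpendicular_profile",
    "fwhm",
    "filter_tradeoff",
    "sensitivity_series",
    "blackbody",
    "fit_blackbody",
    "spectral_correction",
    "apply_correction",
]


@dataclass
class Spectrum:
    """A sampled spectrum: wavelengths in nm (strictly increasing), values >= 0."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if len(self.wavelengths) < 3:
            raise ValueError("a spectrum needs at least 3 samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass(frozen=True)
class FwhmResult:
    """Full width at half maximum of a single-peaked profile."""

    fwhm: float
    peak_position: float
    peak_value: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


@dataclass(frozen=True)
class BlackbodyFit:
    """Least-squares Planck fit of a lamp spectrum."""

    temperature: float
    scale: float
    fitted: Spectrum
    rms_residual: float


@dataclass(frozen=True)
class FilterTradeoff:
    """Percent FWHM change between two filter configurations, per depth."""

    per_condition_pct: np.ndarray
    mean_pct: float


def mean_perpendicular_profile(
    image: ModalityImage,
    axis_line: LineSpec,
) -> np.ndarray:
    """Average perpendicular cross-section of a tube ridge, peak-normalized.

    ``axis_line`` runs along the ridge; its ``width`` sets how far the
    perpendicular cross-section extends (it must span the full tube response).
    Cross-sections at every position along the ridge are averaged and the
    result is divided by its own maximum, so the returned profile peaks at 1.
    """
    sub = extract_subimage(image, axis_line)  # (width, length)
    profile = sub.mean(axis=1)
    peak = profile.max()
    if peak <= 0:
        raise ValueError("profile has no positive signal; cannot normalize")
    return profile / peak


def fwhm(profile: np.ndarray, spacing: float = 1.0) -> FwhmResult:
    """Full width at half maximum of a single-peaked 1-D profile.

    The two half-maximum crossings are located by linear interpolation
    between the bracketing samples. The above-half-max region must be a
    single connected run (a multimodal profile is an error, not a guess), and
    the profile must fall below half max on both sides of the peak.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or len(profile) < 3:
        raise ValueError("profile must be a 1-D array with at least 3 samples")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    i_peak = int(np.argmax(profile))
    peak = profile[i_peak]
    half = peak / 2.0
    above = np.flatnonzero(profile > half)
    if above[-1] - above[0] + 1 != len(above):
        raise ValueError("profile has multiple above-half-max regions (multimodal)")
    first, last = above[0], above[-1]
    if first == 0:
        raise ValueError("profile never falls below half maximum on the left side")
    if last == len(profile) - 1:
        raise ValueError("profile never falls below half maximum on the right side")
    # linear interpolation between the bracketing samples on each side
    left = first - 1 + (half - profile[first - 1]) / (profile[first] - profile[first - 1])
    right = last + (profile[last] - half) / (profile[last] - profile[last + 1])
    return FwhmResult(
        fwhm=float((right - left) * spacing),
        peak_position=float(i_peak * spacing),
        peak_value=float(peak),
    )


def filter_tradeoff(
    reference: list[FwhmResult] | np.ndarray,
    alternative: list[FwhmResult] | np.ndarray,
) -> FilterTradeoff:
    """Percent FWHM change of ``alternative`` relative to ``reference``.

    The two lists must hold matched depth conditions in the same order.
    Positive percentages mean the alternative configuration is blurrier.
    """

    def widths(seq) -> np.ndarray:
        return np.array([r.fwhm if isinstance(r, FwhmResult) else float(r) for r in seq])

    ref = widths(reference)
    alt = widths(alternative)
    if ref.shape != alt.shape or ref.size == 0:
        raise ValueError("configurations must hold matched, non-empty condition lists")
    pct = 100.0 * (alt - ref) / ref
    return FilterTradeoff(per_condition_pct=pct, mean_pct=float(pct.mean()))


def sensitivity_series(
    well_stats: list[tuple[float, RoiStats]],
    control: RoiStats,
) -> float | None:
    """Lowest detectable concentration of a dilution series.

    ``well_stats`` is an ascending-concentration list of (concentration,
    RoiStats); ``control`` is the zero-concentration well. The result is the
    smallest concentration whose SNR clears the detectability rule with every
    larger concentration also detectable (a monotone cut, so a single noisy
    outlier cannot fake a detection limit). Returns ``None`` when no well is
    detectable.
    """
    if len(well_stats) == 0:
        raise ValueError("well series is empty")
    concs = [c for c, _ in well_stats]
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be non-negative")
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be strictly increasing")
    detectable = [is_detectable(snr_db(s, control)) for _, s in well_stats]
    limit = None
    for conc, det in zip(reversed(concs), reversed(detectable)):
        if not det:
            break
        limit = conc
    return limit


def blackbody(wavelengths: np.ndarray, temperature: float, scale: float = 1.0) -> Spectrum:
    """Planck spectral radiance (wavelength form) on a nm grid.

    Values are in W sr^-1 m^-2 nm^-1 times ``scale``; any common scale factor
    is permitted since only the spectral shape matters for calibration.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    wavelengths = np.asarray(wavelengths, dtype=float)
    lam = wavelengths * 1e-9
    h, c, k = constants.h, constants.c, constants.k
    with np.errstate(over="ignore"):  # exp overflow at tiny lambda*T -> 0 radiance
        radiance = 2.0 * h * c**2 / lam**5 / np.expm1(h * c / (lam * k * temperature))
    return Spectrum(wavelengths=wavelengths, values=scale * radiance * 1e-9)


def fit_blackbody(measured: Spectrum) -> BlackbodyFit:
    """Least-squares (temperature, scale) Planck fit of a lamp spectrum.

    Initializes the temperature from Wien's displacement law at the measured
    peak and refines both parameters with nonlinear least squares. Raises if
    the optimizer fails or the residual shows the spectrum has no Planck
    shape (relative RMS residual above 5%).
    """
    if len(measured) < 10:
        raise ValueError("at least 10 samples spanning the peak or its flank are required")
    wl = measured.wavelengths
    y = measured.values
    if np.any(y < 0):
        raise ValueError("spectrum values must be non-negative")

    wien_b = 2.897771955e6  # nm K
    t0 = float(np.clip(wien_b / wl[np.argmax(y)], 500.0, 20000.0))
    s0 = float(y.max() / blackbody(wl, t0).values.max())

    def model(lam_nm, temperature, scale):
        return blackbody(lam_nm, temperature, scale).values

    try:
        popt, _ = optimize.curve_fit(
            model,
            wl,
            y,
            p0=[t0, s0],
            bounds=([100.0, 0.0], [1e5, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"black-body fit did not converge: {exc}") from exc
    temperature, scale = float(popt[0]), float(popt[1])
    fitted = blackbody(wl, temperature, scale)
    rms = float(np.sqrt(np.mean((fitted.values - y) ** 2)))
    rel_rms = rms / float(np.mean(y)) if np.mean(y) > 0 else np.inf
    if rel_rms > 0.05:
        raise ValueError(
            "black-body fit rejected: relative RMS residual "
            f"{rel_rms:.3f} exceeds 5% (T={temperature:.0f} K, scale={scale:.3g}); "
            "the spectrum does not have a Planck shape"
        )
    return BlackbodyFit(temperature=temperature, scale=scale, fitted=fitted, rms_residual=rms)


def spectral_correction(measured_lamp: Spectrum, fitted: BlackbodyFit | Spectrum) -> Spectrum:
    """Per-wavelength correction: black-body fit divided by the recorded lamp.

    Applying the correction to the recorded lamp spectrum reproduces the
    fitted black-body curve exactly; applied to any raw spectrum it undoes
    the instrument's spectral response up to a constant.
    """
    fitted_spectrum = fitted.fitted if isinstance(fitted, BlackbodyFit) else fitted
    if not np.array_equal(measured_lamp.wavelengths, fitted_spectrum.wavelengths):
        raise ValueError("wavelength grids of lamp and fit must match")
    if np.any(measured_lamp.values <= 0):
        raise ValueError("recorded lamp spectrum must be strictly positive")
    return Spectrum(
        wavelengths=measured_lamp.wavelengths,
        values=fitted_spectrum.values / measured_lamp.values,
    )


def apply_correction(raw: Spectrum, correction: Spectrum) -> Spectrum:
    """Multiply a raw spectrum pointwise by the correction curve."""
    if not np.array_equal(raw.wavelengths, correction.wavelengths):
        raise ValueError("wavelength grids of spectrum and correction must match")
    return Spectrum(wavelengths=raw.wavelengths, values=raw.values * correction.values)
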