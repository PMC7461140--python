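"""Mid-infrared spectral preprocessing.

Implements the processing chain applied to ATR-FTIR absorbance spectra of
powdered leaf tissue before any statistical modelling: anchor-window baseline
subtraction, area normalization over the 1800-900 cm^-1 region, trapezoidal
band-area integration, tiling of the spectrum into fixed-width windows for
screening, and Gaussian-sum deconvolution of overlapping bands by nonlinear
least squares.

Spectra are stored as (wavenumber, absorbance) pairs on a uniform grid,
conventionally ordered from high to low wavenumber as spectrometers emit
them; every operation here is orientation-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Spectrum",
    "BandWindow",
    "GaussianPeak",
    "DeconvolutionResult",
    "SpectrumRangeError",
    "NormalizationError",
    "baseline_correct",
    "normalize_area",
    "integrate_band",
    "fragment_spectrum",
    "deconvolve",
    "gaussian_sum",
    "read_spectrum",
    "write_spectrum",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian profile
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

NORMALIZATION_WINDOW = (900.0, 1800.0)
DECONVOLUTION_WINDOW = (600.0, 1200.0)


class SpectrumRangeError(ValueError):
    """A requested window lies (partly) outside the spectrum's range."""


class NormalizationError(ValueError):
    """The normalization window integral is not positive."""


@dataclass(frozen=True)
class BandWindow:
    """Closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float
    partial: bool = False  # marks a truncated tile from fragment_spectrum

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class GaussianPeak:
    """Gaussian band: center (cm^-1), height (AU), full width at half maximum (cm^-1)."""

    center: float
    height: float
    fwhm: float

    def __post_init__(self):
        if self.height < 0:
            raise ValueError("peak height must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("peak fwhm must be > 0")

    @property
    def sigma(self) -> float:
        return self.fwhm / _FWHM_PER_SIGMA

    @property
    def area(self) -> float:
        """Analytic area under the Gaussian, height*fwhm*sqrt(pi/(4 ln 2))."""
        return self.height * self.fwhm * np.sqrt(np.pi / (4.0 * np.log(2.0)))


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum on a uniform wavenumber grid with processing provenance."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    steps_applied: tuple[str, ...] = ()

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.ndim != 1 or wn.shape != ab.shape or wn.size < 2:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-d, length >= 2")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotonic")
        step = np.abs(d)
        if np.max(step) - np.min(step) > 1e-6 * np.max(step):
            raise ValueError("wavenumber grid spacing must be uniform")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance must be finite")

    @property
    def lo(self) -> float:
        return float(min(self.wavenumbers[0], self.wavenumbers[-1]))

    @property
    def hi(self) -> float:
        return float(max(self.wavenumbers[0], self.wavenumbers[-1]))

    @property
    def step(self) -> float:
        return float(abs(self.wavenumbers[1] - self.wavenumbers[0]))

    def with_step(self, absorbance: np.ndarray, tag: str) -> "Spectrum":
        """Return a copy with new absorbance values and an appended step tag."""
        return Spectrum(self.wavenumbers, absorbance, self.steps_applied + (tag,))

    def _ascending(self) -> tuple[np.ndarray, np.ndarray]:
        if self.wavenumbers[0] > self.wavenumbers[-1]:
            return self.wavenumbers[::-1], self.absorbance[::-1]
        return self.wavenumbers, self.absorbance


@dataclass(frozen=True)
class DeconvolutionResult:
    """Outcome of a Gaussian-sum least-squares fit over a window."""

    peaks: tuple[GaussianPeak, ...]
    fitted: Spectrum
    rss: float
    converged: bool


def _check_window(spectrum: Spectrum, window: BandWindow) -> None:
    if window.lo < spectrum.lo - 1e-9 or window.hi > spectrum.hi + 1e-9:
        raise SpectrumRangeError(
            f"window [{window.lo}, {window.hi}] outside spectrum range "
            f"[{spectrum.lo}, {spectrum.hi}]"
        )


def baseline_correct(spectrum: Spectrum, anchor_windows: list[BandWindow]) -> Spectrum:
    """Subtract a piecewise-linear baseline anchored at window means.

    Each anchor window contributes one baseline knot at (window midpoint,
    mean absorbance over the window); the baseline interpolates linearly
    between knots and extends the end segments linearly beyond them.  With a
    single anchor this reduces to constant-offset subtraction; with two it is
    the classical two-point linear baseline.
    """
    if not anchor_windows:
        raise ValueError("at least one anchor window is required")
    for w in anchor_windows:
        _check_window(spectrum, w)
    wn_a, ab_a = spectrum._ascending()
    knots_x, knots_y = [], []
    for w in sorted(anchor_windows, key=lambda w: w.lo):
        mask = (wn_a >= w.lo) & (wn_a <= w.hi)
        if not mask.any():
            raise SpectrumRangeError(f"anchor window [{w.lo}, {w.hi}] contains no grid point")
        knots_x.append(0.5 * (w.lo + w.hi))
        knots_y.append(float(ab_a[mask].mean()))
    baseline = np.interp(spectrum.wavenumbers, knots_x, knots_y)
    if len(knots_x) >= 2:
        # extend the outermost segments linearly beyond the anchor knots
        wn = spectrum.wavenumbers
        lo_slope = (knots_y[1] - knots_y[0]) / (knots_x[1] - knots_x[0])
        hi_slope = (knots_y[-1] - knots_y[-2]) / (knots_x[-1] - knots_x[-2])
        below = wn < knots_x[0]
        above = wn > knots_x[-1]
        baseline[below] = knots_y[0] + lo_slope * (wn[below] - knots_x[0])
        baseline[above] = knots_y[-1] + hi_slope * (wn[above] - knots_x[-1])
    return spectrum.with_step(spectrum.absorbance - baseline, "baseline_correct")


def normalize_area(spectrum: Spectrum, window: BandWindow | None = None) -> Spectrum:
    """Scale the whole spectrum so its integral over `window` equals 1.

    Defaults to the 1800-900 cm^-1 normalization region.  The scaling is
    global: every absorbance value is divided by the same window integral,
    so ratios of band areas are preserved.
    """
    if window is None:
        window = BandWindow(*NORMALIZATION_WINDOW)
    area = integrate_band(spectrum, window)
    if area <= 0:
        raise NormalizationError(f"window integral {area} is not positive")
    return spectrum.with_step(
        spectrum.absorbance / area, f"normalize_area[{window.lo:g},{window.hi:g}]"
    )


def integrate_band(spectrum: Spectrum, window: BandWindow) -> float:
    """Trapezoidal integral of absorbance over [lo, hi].

    Window edges falling between grid points are included by linear
    interpolation.  The result is orientation-agnostic (the absolute value
    of the signed trapezoid), so descending-stored spectra integrate
    identically to ascending ones.
    """
    _check_window(spectrum, window)
    wn, ab = spectrum._ascending()
    inside = (wn > window.lo) & (wn < window.hi)
    xs = np.concatenate(([window.lo], wn[inside], [window.hi]))
    ys = np.concatenate(
        ([np.interp(window.lo, wn, ab)], ab[inside], [np.interp(window.hi, wn, ab)])
    )
    return float(abs(np.trapezoid(ys, xs)))


def fragment_spectrum(spectrum: Spectrum, width: float = 10.0) -> list[BandWindow]:
    """Tile the spectrum range into contiguous windows of `width` cm^-1.

    Tiling starts at the high-wavenumber end; a final narrower remainder at
    the low end is kept and flagged ``partial``.  The returned windows are
    ordered high to low, are pairwise disjoint, and cover the range exactly.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    span = spectrum.hi - spectrum.lo
    if width >= span:
        warnings.warn("window width >= spectrum span; returning a single window")
        return [BandWindow(spectrum.lo, spectrum.hi, partial=width > span)]
    windows = []
    hi = spectrum.hi
    while hi - spectrum.lo > 1e-9:
        lo = max(hi - width, spectrum.lo)
        windows.append(BandWindow(lo, hi, partial=(hi - lo) < width - 1e-9))
        hi = lo
    return windows


def gaussian_sum(wn: np.ndarray, peaks) -> np.ndarray:
    """Evaluate a sum of Gaussian bands on a wavenumber grid."""
    wn = np.asarray(wn, dtype=float)
    out = np.zeros_like(wn)
    for p in peaks:
        out += p.height * np.exp(-0.5 * ((wn - p.center) / p.sigma) ** 2)
    return out


def deconvolve(
    spectrum: Spectrum,
    initial_peaks,
    window: BandWindow | None = None,
    max_nfev: int = 10_000,
    rtol: float = 1e-10,
) -> DeconvolutionResult:
    """Resolve overlapping bands as a sum of Gaussians by least squares.

    Parameters are (center, height, fwhm) per peak; nonnegativity of height
    and width is enforced by fitting their absolute values.  The optimizer
    starts from `initial_peaks`, so the residual sum of squares never exceeds
    that of the initial guess.  Non-convergence within the evaluation budget
    is reported through ``converged=False`` rather than raised.
    """
    if window is None:
        window = BandWindow(*DECONVOLUTION_WINDOW)
    initial_peaks = list(initial_peaks)
    if not initial_peaks:
        raise ValueError("at least one initial peak is required")
    _check_window(spectrum, window)
    wn_a, ab_a = spectrum._ascending()
    mask = (wn_a >= window.lo) & (wn_a <= window.hi)
    x, y = wn_a[mask], ab_a[mask]

    def unpack(theta):
        return [
            GaussianPeak(c, abs(h), max(abs(f), 1e-12))
            for c, h, f in theta.reshape(-1, 3)
        ]

    def resid(theta):
        return gaussian_sum(x, unpack(theta)) - y

    theta0 = np.array([[p.center, p.height, p.fwhm] for p in initial_peaks]).ravel()
    sol = least_squares(resid, theta0, max_nfev=max_nfev, xtol=rtol, ftol=rtol, gtol=rtol)
    peaks = sorted(unpack(sol.x), key=lambda p: -p.center)
    fitted = Spectrum(
        x, gaussian_sum(x, peaks), spectrum.steps_applied + ("deconvolve",)
    )
    rss = float(np.sum(resid(sol.x) ** 2))
    rss0 = float(np.sum(resid(theta0) ** 2))
    if rss > rss0:  # optimizer can never accept a worse point, but be explicit
        peaks = sorted(unpack(theta0), key=lambda p: -p.center)
        rss = rss0
        fitted = Spectrum(x, gaussian_sum(x, peaks), spectrum.steps_applied + ("deconvolve",))
    return DeconvolutionResult(
        peaks=tuple(peaks), fitted=fitted, rss=rss, converged=bool(sol.success)
    )


def read_spectrum(path) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV; header row optional."""
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = not np.issubdtype(np.asarray(first.iloc[0, 0]).dtype, np.number) and not str(
        first.iloc[0, 0]
    ).replace(".", "", 1).lstrip("-").isdigit()
    frame = pd.read_csv(path, header=0 if has_header else None)
    wn = frame.iloc[:, 0].astype(float).to_numpy()
    ab = frame.iloc[:, 1].astype(float).to_numpy()
    return Spectrum(wn, ab, ("read",))


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as a two-column CSV with header."""
    pd.DataFrame(
        {"wavenumber": spectrum.wavenumbers, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False, float_format="%.17g")
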