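"""Synthetic spectra and mediation datasets with known ground truth.

Two generators make every pipeline stage testable without measured data:

* :func:`simulate_spectra` builds ATR-FTIR-like absorbance spectra as sums
  of Gaussian bands at the twelve band centers resolved in the 1200-600
  cm^-1 fingerprint region of barley leaf tissue (1153, 1104, 1069, 1036,
  991, 960, 896, 825, 719, 710, 701, 670 cm^-1), on the instrument grid
  (4000-400 cm^-1 at 4 cm^-1 steps), plus linear baseline drift and white
  Gaussian noise.  Selected peak heights can be tied to a latent per-sample
  factor so that band areas carry a planted signal.

* :func:`simulate_mediation` draws (moderated) mediation datasets in the
  regenerant table schema: x uniform over the observed combined-absorbance
  range, m = i_M + (a + a3 w) x + noise, y = i_Y + c' x + (b + b2 w) m +
  noise, with culture time w sampled from {21, 28, 35} days.

Both are fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import GaussianPeak, Spectrum, gaussian_sum
from .table import Dataset, RegenerantRecord

__all__ = [
    "RESOLVED_CENTERS",
    "SpectrumTemplate",
    "MediationTruth",
    "default_template",
    "simulate_spectra",
    "simulate_mediation",
]

#: Band centers (cm^-1) resolved by Gaussian deconvolution of the
#: 1200-600 cm^-1 region of barley leaf spectra.
RESOLVED_CENTERS = (1153, 1104, 1069, 1036, 991, 960, 896, 825, 719, 710, 701, 670)

# heights/widths chosen to mimic the fingerprint region's shape: two dominant
# polysaccharide bands (1069, 1036), small shoulder peaks (991, 960), and a
# narrow low-frequency triplet (719/710/701)
_DEFAULT_HEIGHTS = (0.30, 0.45, 1.00, 0.90, 0.18, 0.12, 0.20, 0.15, 0.25, 0.30, 0.25, 0.22)
_DEFAULT_FWHMS = (28.0, 26.0, 30.0, 28.0, 16.0, 14.0, 22.0, 14.0, 8.0, 8.0, 8.0, 14.0)


@dataclass(frozen=True)
class SpectrumTemplate:
    """Recipe for synthetic spectra: bands, baseline drift, noise, grid."""

    peaks: tuple[GaussianPeak, ...]
    baseline_slope: float = 0.0  # AU per cm^-1
    baseline_offset: float = 0.0  # AU
    noise_sd: float = 0.0  # AU
    grid: tuple[float, float, float] = (4000.0, 400.0, 4.0)  # start, stop, step

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be > 0")

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round(abs(start - stop) / step)) + 1
        return np.linspace(start, stop, n)


def default_template(noise_sd: float = 0.0, baseline_slope: float = 0.0) -> SpectrumTemplate:
    """Template with the twelve resolved fingerprint bands at realistic shapes."""
    peaks = tuple(
        GaussianPeak(c, h, f)
        for c, h, f in zip(RESOLVED_CENTERS, _DEFAULT_HEIGHTS, _DEFAULT_FWHMS)
    )
    return SpectrumTemplate(peaks=peaks, noise_sd=noise_sd, baseline_slope=baseline_slope)


def simulate_spectra(
    template: SpectrumTemplate,
    n: int,
    effect_map: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[list[Spectrum], np.ndarray]:
    """Draw `n` spectra from a template; return them with the latent factors.

    ``effect_map`` maps peak indices (into ``template.peaks``) to slopes: the
    height of peak ``i`` for sample ``j`` is ``height_i + slope * z_j`` with
    ``z_j ~ N(0, 1)`` the sample's latent factor (clipped at zero height).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    effect_map = effect_map or {}
    rng = np.random.default_rng(seed)
    wn = template.wavenumbers()
    latent = rng.standard_normal(n)
    baseline = template.baseline_offset + template.baseline_slope * wn
    spectra = []
    for j in range(n):
        peaks = [
            GaussianPeak(
                p.center,
                max(p.height + effect_map.get(i, 0.0) * latent[j], 0.0),
                p.fwhm,
            )
            for i, p in enumerate(template.peaks)
        ]
        ab = gaussian_sum(wn, peaks) + baseline
        if template.noise_sd > 0:
            ab = ab + rng.normal(0.0, template.noise_sd, size=wn.size)
        spectra.append(Spectrum(wn, ab, ("simulated",)))
    return spectra, latent


@dataclass(frozen=True)
class MediationTruth:
    """Ground-truth path coefficients and noise for a simulated mediation."""

    a: float
    b: float
    c_prime: float
    a3: float = 0.0  # X*W slope on the a path
    b2: float = 0.0  # M*W slope on the b path
    sd_m: float = 0.1
    sd_y: float = 0.5
    intercept_m: float = 1.5
    intercept_y: float = 10.0
    x_range: tuple[float, float] = (0.02, 0.06)  # observed combined-absorbance range
    time_levels: tuple[int, ...] = (21, 28, 35)
    n: int = 35
    seed: int = 0

    def __post_init__(self):
        if self.sd_m < 0 or self.sd_y < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n < 4:
            raise ValueError("n must be >= 4")

    def conditional_indirect(self, w: float) -> float:
        """True indirect effect at moderator value w."""
        return (self.a + self.a3 * w) * (self.b + self.b2 * w)


def simulate_mediation(truth: MediationTruth) -> Dataset:
    """Draw one mediation dataset in the regenerant table schema.

    The predictor x is emitted as the combined absorbance (split 3%/97%
    between the two band columns, mirroring the fixture's proportions), the
    mediator as the CHG-context demethylation, and the outcome as sequence
    variation; the CG-context column is set to zero so total demethylation
    equals the mediator.  Mediator and outcome are clipped at zero to respect
    the schema's nonnegativity (with default intercepts and noise this
    essentially never binds).
    """
    rng = np.random.default_rng(truth.seed)
    x = rng.uniform(*truth.x_range, size=truth.n)
    w = rng.choice(np.asarray(truth.time_levels), size=truth.n)
    m = truth.intercept_m + (truth.a + truth.a3 * w) * x + rng.normal(0, truth.sd_m, truth.n)
    y = (
        truth.intercept_y
        + truth.c_prime * x
        + (truth.b + truth.b2 * w) * m
        + rng.normal(0, truth.sd_y, truth.n)
    )
    m = np.clip(m, 0.0, None)
    y = np.clip(y, 0.0, None)
    records = []
    for i in range(truth.n):
        f710 = 0.03 * x[i]
        records.append(
            RegenerantRecord(
                sample_no=i + 1,
                trial=f"M{i % 9 + 1}",
                f710_690=f710,
                f1010_940=x[i] - f710,
                f_combined=x[i],
                dmv=m[i],
                cg_dmv=0.0,
                chg_dmv=m[i],
                sv=y[i],
                time_days=int(w[i]),
            )
        )
    ds = Dataset(records=tuple(records), provenance=f"simulated (seed={truth.seed})")
    ds.validate()
    return ds
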