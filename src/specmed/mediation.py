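"""Simple mediation by OLS product of coefficients.

The model is the classical three-regression mediation triangle for a
predictor X, mediator M and outcome Y:

    M = i_M + a X + e_M
    Y = i_Y + c' X + b M + e_Y
    Y = i_C + c X + e_C

The indirect effect is IE = a*b, the direct effect c', and for OLS the exact
decomposition c = c' + a*b holds.  Inference on IE uses a seeded
case-resampling bootstrap (percentile or bias-corrected percentile interval)
and the Goodman normal-theory test
z = a b / sqrt(b^2 s_a^2 + a^2 s_b^2 - s_a^2 s_b^2), falling back to the
Sobel denominator (without the subtracted term) when the Goodman denominator
is nonpositive.  Mediation strength is summarised by the variance accounted
for, VAF = 100 * IE / c.

:class:`SimpleMediation` is the model object; its :meth:`~SimpleMediation.fit`
returns a :class:`MediationResults` carrying paths, bootstrap interval,
standardized effects, VAF, Goodman statistics and the three underlying OLS
fits, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "OLSFit",
    "BootConfig",
    "GoodmanTest",
    "MediationResults",
    "SimpleMediation",
    "SingularityError",
    "VarianceError",
    "fit_ols",
    "fit_simple_mediation",
    "goodman_test",
    "vaf",
    "cohen_f2",
]


class SingularityError(ValueError):
    """The design matrix is rank deficient."""


class VarianceError(ValueError):
    """A model variable is (numerically) constant."""


@dataclass(frozen=True)
class OLSFit:
    """A fitted OLS regression with classical (homoskedastic) inference."""

    coefficients: pd.Series
    standard_errors: pd.Series
    covariance: pd.DataFrame
    r2: float
    f_stat: float
    df_model: int
    df_resid: int
    n: int

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.coefficients.index if n != "const")


def fit_ols(y, X: pd.DataFrame, add_intercept: bool = True) -> OLSFit:
    """Ordinary least squares with classical standard errors.

    Parameters
    ----------
    y : array-like
        Response vector.
    X : DataFrame
        Predictor columns (no intercept column; one is added unless
        ``add_intercept=False``).

    Raises
    ------
    SingularityError
        If the design (with intercept) is rank deficient; the message names
        the offending columns.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify columns whose removal restores full column rank
        offenders = [
            c
            for c in design.columns
            if c != "const"
            and np.linalg.matrix_rank(design.drop(columns=[c]).to_numpy()) == rank
        ]
        raise SingularityError(f"rank-deficient design; offending column(s): {offenders}")
    res = sm.OLS(y, design).fit()
    return OLSFit(
        coefficients=res.params,
        standard_errors=res.bse,
        covariance=res.cov_params(),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n=int(res.nobs),
    )


@dataclass(frozen=True)
class BootConfig:
    """Case-resampling bootstrap settings."""

    n_boot: int = 5000
    seed: int = 0
    level: float = 0.95
    method: str = "percentile"  # or "bc" (bias-corrected percentile)

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.method not in ("percentile", "bc"):
            raise ValueError("method must be 'percentile' or 'bc'")


class GoodmanTest(NamedTuple):
    z: float
    p: float
    sobel_fallback: bool


def goodman_test(a: float, b: float, se_a: float, se_b: float) -> GoodmanTest:
    """Goodman (unbiased Sobel) test of the indirect effect a*b.

    Uses the denominator sqrt(b^2 se_a^2 + a^2 se_b^2 - se_a^2 se_b^2); when
    that quantity is nonpositive the Sobel denominator (without the
    subtracted term) is used instead and the fallback is flagged.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    var = b * b * se_a * se_a + a * a * se_b * se_b - se_a * se_a * se_b * se_b
    fallback = var <= 0
    if fallback:
        var = b * b * se_a * se_a + a * a * se_b * se_b
    if var <= 0:  # a = b = 0
        return GoodmanTest(0.0, 1.0, fallback)
    z = a * b / np.sqrt(var)
    return GoodmanTest(float(z), float(2.0 * stats.norm.sf(abs(z))), fallback)


def vaf(ie: float, total: float) -> float:
    """Variance accounted for by mediation, as a percentage: 100*IE/total."""
    if total == 0:
        raise ZeroDivisionError("VAF undefined for zero total effect")
    return 100.0 * ie / total


def cohen_f2(r2: float) -> float:
    """Cohen's effect size f^2 = r^2 / (1 - r^2) from a squared multiple correlation."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    return r2 / (1.0 - r2)


def _boot_indirect(x, m, y, boot: BootConfig) -> np.ndarray:
    """Bootstrap distribution of a*b by vectorised closed-form OLS refits.

    For each case-resample the a path is the simple-regression slope
    cov(x, m)/var(x) and (c', b) solve the 3x3 normal equations of
    y ~ 1 + x + m.  Exact OLS, evaluated for all resamples at once.
    """
    n = x.size
    rng = np.random.default_rng(boot.seed)
    idx = rng.integers(0, n, size=(boot.n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    xm, mm, ym = xb.mean(axis=1), mb.mean(axis=1), yb.mean(axis=1)
    xc, mc, yc = xb - xm[:, None], mb - mm[:, None], yb - ym[:, None]
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        det = sxx * smm - sxm * sxm
        b = (sxx * smy - sxm * sxy) / det
    return a * b


@dataclass(frozen=True)
class MediationResults:
    """Estimates, bootstrap interval and tests for one simple mediation fit."""

    a: float
    b: float
    c: float
    c_prime: float
    ie: float
    ie_ci: tuple[float, float]
    ci_level: float
    ie_partially_std: float
    ie_completely_std: float
    vaf: float  # percent
    goodman: GoodmanTest
    fits: dict[str, OLSFit]
    names: tuple[str, str, str] = ("x", "m", "y")
    boot: BootConfig | None = None

    @property
    def goodman_z(self) -> float:
        return self.goodman.z

    @property
    def goodman_p(self) -> float:
        return self.goodman.p

    @property
    def significant(self) -> bool:
        """Bootstrap CI for the indirect effect excludes zero."""
        lo, hi = self.ie_ci
        return lo > 0 or hi < 0

    def to_dict(self) -> dict:
        return {
            "x": self.names[0],
            "m": self.names[1],
            "y": self.names[2],
            "r2_total": self.fits["total"].r2,
            "r2_mediator": self.fits["mediator"].r2,
            "r2_outcome": self.fits["outcome"].r2,
            "c_prime": self.c_prime,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "ie": self.ie,
            "ci_lower": self.ie_ci[0],
            "ci_upper": self.ie_ci[1],
            "ci_level": self.ci_level,
            "ie_partially_std": self.ie_partially_std,
            "ie_completely_std": self.ie_completely_std,
            "vaf_percent": self.vaf,
            "goodman_z": self.goodman.z,
            "goodman_p": self.goodman.p,
            "sobel_fallback": self.goodman.sobel_fallback,
        }

    def summary(self) -> str:
        x, m, y = self.names
        lo, hi = self.ie_ci
        lines = [
            f"Simple mediation: {x} -> {m} -> {y}  (n = {self.fits['outcome'].n})",
            "-" * 64,
            f"  R2 (outcome model)        {self.fits['outcome'].r2:10.4f}",
            f"  c' (direct effect)        {self.c_prime:10.4f}",
            f"  a  ({x} -> {m})           {self.a:10.4f}",
            f"  b  ({m} -> {y} | {x})     {self.b:10.4f}",
            f"  c  (total effect)         {self.c:10.4f}",
            f"  IE = a*b                  {self.ie:10.4f}",
            f"  {100 * self.ci_level:.0f}% bootstrap CI          [{lo:.4f}, {hi:.4f}]",
            f"  completely std. IE        {self.ie_completely_std:10.4f}",
            f"  VAF                       {self.vaf:9.1f}%",
            f"  Goodman Z = {self.goodman.z:.3f}, p = {self.goodman.p:.4f}"
            + ("  (Sobel fallback)" if self.goodman.sobel_fallback else ""),
        ]
        return "\n".join(lines)


class SimpleMediation:
    """Product-of-coefficients mediation model for one predictor/mediator/outcome.

    Parameters
    ----------
    x, m, y : array-like
        Predictor, mediator and outcome vectors of equal length (n >= 10).
    names : tuple of str, optional
        Labels used in summaries and exports.
    """

    def __init__(self, x, m, y, names: tuple[str, str, str] = ("x", "m", "y")):
        x = np.asarray(x, dtype=float)
        m = np.asarray(m, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (x.shape == m.shape == y.shape) or x.ndim != 1:
            raise ValueError("x, m, y must be equal-length 1-d vectors")
        if x.size < 10:
            raise ValueError("mediation requires n >= 10")
        if not np.all(np.isfinite(np.concatenate([x, m, y]))):
            raise ValueError("x, m, y must be finite")
        for name, v in zip(names, (x, m, y)):
            if np.ptp(v) == 0:
                raise VarianceError(f"variable {name!r} is constant")
        self.x, self.m, self.y = x, m, y
        self.names = tuple(names)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, x: str, m: str, y: str) -> "SimpleMediation":
        return cls(frame[x], frame[m], frame[y], names=(x, m, y))

    def fit(self, boot: BootConfig | None = None) -> MediationResults:
        """Fit the three regressions and bootstrap the indirect effect."""
        if boot is None:
            boot = BootConfig()
        xn, mn, yn = self.names
        fit_a = fit_ols(self.m, pd.DataFrame({xn: self.x}))
        fit_out = fit_ols(self.y, pd.DataFrame({xn: self.x, mn: self.m}))
        fit_c = fit_ols(self.y, pd.DataFrame({xn: self.x}))
        a = float(fit_a.coefficients[xn])
        b = float(fit_out.coefficients[mn])
        c_prime = float(fit_out.coefficients[xn])
        c = float(fit_c.coefficients[xn])
        ie = a * b

        draws = _boot_indirect(self.x, self.m, self.y, boot)
        draws = draws[np.isfinite(draws)]
        alpha = 1.0 - boot.level
        if boot.method == "bc":
            # bias-corrected percentile: shift quantiles by the normal score
            # of the fraction of draws below the point estimate
            prop = np.clip(np.mean(draws < ie), 1e-6, 1 - 1e-6)
            z0 = stats.norm.ppf(prop)
            lo_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2))
            hi_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - alpha / 2))
        else:
            lo_q, hi_q = alpha / 2, 1 - alpha / 2
        ci = (float(np.quantile(draws, lo_q)), float(np.quantile(draws, hi_q)))

        sd_x = float(np.std(self.x, ddof=1))
        sd_y = float(np.std(self.y, ddof=1))
        good = goodman_test(
            a, b, float(fit_a.standard_errors[xn]), float(fit_out.standard_errors[mn])
        )
        return MediationResults(
            a=a,
            b=b,
            c=c,
            c_prime=c_prime,
            ie=ie,
            ie_ci=ci,
            ci_level=boot.level,
            ie_partially_std=ie / sd_y,
            ie_completely_std=ie * sd_x / sd_y,
            vaf=vaf(ie, c),
            goodman=good,
            fits={"mediator": fit_a, "outcome": fit_out, "total": fit_c},
            names=self.names,
            boot=boot,
        )


def fit_simple_mediation(x, m, y, boot: BootConfig | None = None) -> MediationResults:
    """Functional wrapper: build a :class:`SimpleMediation` and fit it."""
    return SimpleMediation(x, m, y).fit(boot=boot)
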