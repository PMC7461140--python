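"""Moderated mediation with a continuous moderator on the a and b paths.

With predictor X, mediator M, outcome Y and moderator W (here: days of
in vitro culture), the default first-stage-and-second-stage model is

    M = i_M + a1 X + a2 W + a3 X*W + e_M
    Y = i_Y + c1' X + c2 W + b1 M + b2 M*W + e_Y

so the X -> M path at moderator value w is theta_a(w) = a1 + a3 w, the
M -> Y path is theta_b(w) = b1 + b2 w, and the conditional indirect effect
is theta(w) = theta_a(w) * theta_b(w).  An optional X*W term in the outcome
model (``moderate_cprime``) gives a moderated direct path as well.

The moderator values at which a conditional path crosses significance are
found analytically by the Johnson-Neyman technique: |theta(w)| / SE(theta(w))
= t_crit is quadratic in w and solved in closed form, with
Var(theta(w)) = Var(beta_main) + 2 w Cov + w^2 Var(beta_int).

Interaction terms use raw (uncentered) products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import (
    BootConfig,
    GoodmanTest,
    OLSFit,
    fit_ols,
    goodman_test,
)

__all__ = [
    "ModMedSpec",
    "ModMedResults",
    "ModeratedMediation",
    "ConditionalEffect",
    "JNRegion",
    "fit_modmed",
    "conditional_indirect",
    "interaction_f_test",
    "johnson_neyman",
    "modmed_summary",
]


@dataclass(frozen=True)
class ModMedSpec:
    """Which paths carry a moderator interaction."""

    moderate_a: bool = True
    moderate_b: bool = True
    moderate_cprime: bool = False

    def __post_init__(self):
        if not (self.moderate_a or self.moderate_b or self.moderate_cprime):
            raise ValueError("a moderated model needs at least one moderated path")


@dataclass(frozen=True)
class ConditionalEffect:
    """A path or indirect effect evaluated at one moderator value."""

    w: float
    theta: float
    se: float
    t: float
    p: float
    ci: tuple[float, float]


@dataclass(frozen=True)
class JNRegion:
    """Johnson-Neyman significance region for a conditional path.

    ``boundaries`` lists the moderator values inside ``w_range_examined``
    where the path's t statistic crosses the critical value;
    ``significant_below``/``significant_above`` report whether the effect is
    significant just below the first and just above the last boundary (for
    an empty boundary list they both state whether the path is uniformly
    significant over the examined range).
    """

    boundaries: tuple[float, ...]
    significant_below: bool
    significant_above: bool
    w_range_examined: tuple[float, float]
    alpha: float

    def significant_at(self, w: float) -> bool:
        flag = self.significant_below
        for b in self.boundaries:
            if w > b:
                flag = not flag
        return flag


class NestingError(ValueError):
    """F-test models are not nested."""


def interaction_f_test(fit_reduced: OLSFit, fit_full: OLSFit):
    """Nested-model F test on the R-squared change.

    Returns ``(f_stat, df1, df2, delta_r2, p)`` with
    F = ((R2_full - R2_reduced)/df1) / ((1 - R2_full)/df2).
    """
    red = set(fit_reduced.predictor_names)
    full = set(fit_full.predictor_names)
    if not red <= full or fit_reduced.n != fit_full.n:
        raise NestingError("reduced model predictors must be a subset of the full model's")
    df1 = fit_full.df_model - fit_reduced.df_model
    df2 = fit_full.df_resid
    delta_r2 = fit_full.r2 - fit_reduced.r2
    if df1 == 0:
        return 0.0, 0, df2, 0.0, 1.0
    f = (delta_r2 / df1) / ((1.0 - fit_full.r2) / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), int(df1), int(df2), float(delta_r2), p


@dataclass(frozen=True)
class ModMedResults:
    """Fitted moderated-mediation model: two OLS fits plus derived effects."""

    mediator_model: OLSFit
    outcome_model: OLSFit
    spec: ModMedSpec
    n: int
    names: tuple[str, str, str, str] = ("x", "m", "y", "w")
    w_observed: tuple[float, float] = (0.0, 1.0)
    _data: tuple = None  # (x, m, y, w) arrays, kept for bootstrapping

    # -- coefficient accessors ------------------------------------------------
    @property
    def a1(self) -> float:
        return float(self.mediator_model.coefficients[self.names[0]])

    @property
    def a3(self) -> float:
        xw = f"{self.names[0]}:{self.names[3]}"
        return float(self.mediator_model.coefficients.get(xw, 0.0))

    @property
    def b1(self) -> float:
        return float(self.outcome_model.coefficients[self.names[1]])

    @property
    def b2(self) -> float:
        mw = f"{self.names[1]}:{self.names[3]}"
        return float(self.outcome_model.coefficients.get(mw, 0.0))

    @property
    def c1_prime(self) -> float:
        return float(self.outcome_model.coefficients[self.names[0]])

    def theta_a(self, w: float) -> float:
        return self.a1 + self.a3 * w

    def theta_b(self, w: float) -> float:
        return self.b1 + self.b2 * w

    # -- conditional indirect effect -----------------------------------------
    def conditional_indirect(
        self, w: float, boot: BootConfig | None = None
    ) -> ConditionalEffect:
        """Conditional indirect effect theta(w) = (a1 + a3 w)(b1 + b2 w).

        The point estimate is exact algebra on the fitted coefficients; its
        standard error and CI come from a seeded case-resampling bootstrap of
        the whole two-equation system (the product of two path estimates has
        no exact normal-theory SE).
        """
        theta = self.theta_a(w) * self.theta_b(w)
        if boot is None:
            boot = BootConfig()
        draws = self._boot_conditional(np.array([w]), boot)[:, 0]
        draws = draws[np.isfinite(draws)]
        se = float(np.std(draws, ddof=1))
        alpha = 1.0 - boot.level
        ci = (
            float(np.quantile(draws, alpha / 2)),
            float(np.quantile(draws, 1 - alpha / 2)),
        )
        t = theta / se if se > 0 else np.inf * np.sign(theta)
        p = float(2.0 * stats.norm.sf(abs(t))) if np.isfinite(t) else 0.0
        return ConditionalEffect(w=float(w), theta=float(theta), se=se, t=float(t), p=p, ci=ci)

    def _boot_conditional(self, ws: np.ndarray, boot: BootConfig) -> np.ndarray:
        """Bootstrap draws of theta(w) for each w; shape (n_boot, len(ws)).

        Refits both regressions on every case-resample at once via batched
        normal equations (the designs have at most six well-scaled columns).
        """
        x, m, y, w = self._data
        n = x.size
        rng = np.random.default_rng(boot.seed)
        idx = rng.integers(0, n, size=(boot.n_boot, n))
        xb, mb, yb, wb = x[idx], m[idx], y[idx], w[idx]
        med_cols = self._mediator_columns
        out_cols = self._outcome_columns

        def solve(cols, resp):
            D = np.stack([_column(c, xb, mb, wb) for c in cols], axis=2)
            G = np.einsum("bni,bnj->bij", D, D)
            h = np.einsum("bni,bn->bi", D, resp)
            try:
                return np.linalg.solve(G, h[..., None])[..., 0]
            except np.linalg.LinAlgError:
                coef = np.full((boot.n_boot, len(cols)), np.nan)
                for i in range(boot.n_boot):
                    try:
                        coef[i] = np.linalg.solve(G[i], h[i])
                    except np.linalg.LinAlgError:
                        pass
                return coef

        cm = solve(med_cols, mb)
        co = solve(out_cols, yb)
        a1 = cm[:, med_cols.index("x")]
        a3 = cm[:, med_cols.index("x:w")] if "x:w" in med_cols else 0.0
        b1 = co[:, out_cols.index("m")]
        b2 = co[:, out_cols.index("m:w")] if "m:w" in out_cols else 0.0
        ws = np.asarray(ws, dtype=float)
        return (a1[:, None] + np.multiply.outer(a3, ws)) * (
            b1[:, None] + np.multiply.outer(b2, ws)
        )

    @property
    def _mediator_columns(self) -> list[str]:
        cols = ["const", "x", "w"]
        if self.spec.moderate_a:
            cols.append("x:w")
        return cols

    @property
    def _outcome_columns(self) -> list[str]:
        cols = ["const", "x", "w", "m"]
        if self.spec.moderate_b:
            cols.append("m:w")
        if self.spec.moderate_cprime:
            cols.append("x:w")
        return cols

    # -- Johnson-Neyman -------------------------------------------------------
    def johnson_neyman(self, path: str = "a", alpha: float = 0.05) -> JNRegion:
        """Analytic significance region of a moderated path over the observed w range.

        ``path='a'`` examines theta_a(w) = a1 + a3 w from the mediator model;
        ``path='b'`` examines theta_b(w) = b1 + b2 w from the outcome model.
        Boundaries solve theta(w)^2 = t_crit^2 Var(theta(w)), a quadratic in
        w; roots outside the observed moderator range are dropped (reported
        as "none within range" by an empty boundary tuple).
        """
        xn, mn, _, wn = self.names
        if path == "a":
            if not self.spec.moderate_a:
                raise ValueError("the a path is not moderated in this model")
            fit, main, inter = self.mediator_model, xn, f"{xn}:{wn}"
        elif path == "b":
            if not self.spec.moderate_b:
                raise ValueError("the b path is not moderated in this model")
            fit, main, inter = self.outcome_model, mn, f"{mn}:{wn}"
        else:
            raise ValueError("path must be 'a' or 'b'")
        beta0 = float(fit.coefficients[main])
        beta1 = float(fit.coefficients[inter])
        v00 = float(fit.covariance.loc[main, main])
        v01 = float(fit.covariance.loc[main, inter])
        v11 = float(fit.covariance.loc[inter, inter])
        tc = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))

        # theta(w)^2 - tc^2 Var(theta(w)) = A w^2 + B w + C = 0
        A = beta1 * beta1 - tc * tc * v11
        B = 2.0 * (beta0 * beta1 - tc * tc * v01)
        C = beta0 * beta0 - tc * tc * v00
        w_lo, w_hi = self.w_observed
        roots: list[float] = []
        if abs(A) > 1e-300:
            disc = B * B - 4.0 * A * C
            if disc >= 0:
                r = np.sqrt(disc)
                roots = sorted([(-B - r) / (2 * A), (-B + r) / (2 * A)])
        elif abs(B) > 1e-300:
            roots = [-C / B]
        inside = tuple(w for w in roots if w_lo <= w <= w_hi)

        def sig(w):
            se = np.sqrt(v00 + 2 * w * v01 + w * w * v11)
            return abs(beta0 + beta1 * w) / se > tc

        below = sig(inside[0] - 1e-6) if inside else sig(0.5 * (w_lo + w_hi))
        above = sig(inside[-1] + 1e-6) if inside else below
        return JNRegion(
            boundaries=inside,
            significant_below=bool(below),
            significant_above=bool(above),
            w_range_examined=(w_lo, w_hi),
            alpha=alpha,
        )

    # -- aggregate summary ----------------------------------------------------
    def goodman(self) -> GoodmanTest:
        """Goodman test on the first-order a1 and b1 path coefficients."""
        xn, mn = self.names[0], self.names[1]
        return goodman_test(
            self.a1,
            self.b1,
            float(self.mediator_model.standard_errors[xn]),
            float(self.outcome_model.standard_errors[mn]),
        )

    def summary_table(
        self, w_values=(21.0, 28.0, 35.0), boot: BootConfig | None = None
    ) -> pd.DataFrame:
        """Conditional indirect effects at each w, as a Table-3-style frame."""
        w_values = list(w_values)
        if not w_values:
            raise ValueError("w_values must be non-empty")
        if boot is None:
            boot = BootConfig()
        draws = self._boot_conditional(np.asarray(w_values, dtype=float), boot)
        alpha = 1.0 - boot.level
        rows = []
        for j, w in enumerate(w_values):
            col = draws[:, j]
            col = col[np.isfinite(col)]
            lo = float(np.quantile(col, alpha / 2))
            hi = float(np.quantile(col, 1 - alpha / 2))
            theta = self.theta_a(w) * self.theta_b(w)
            rows.append(
                {
                    "w": float(w),
                    "theta": float(theta),
                    "se": float(np.std(col, ddof=1)),
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "significant": lo > 0 or hi < 0,
                }
            )
        return pd.DataFrame(rows)

    def aggregate_effects(self) -> dict:
        """Aggregate indirect/direct decomposition of the moderated mediation.

        Convention: the aggregate indirect effect is the product of the
        first-order path coefficients, a1 * b1 (the conditional paths
        extrapolated to moderator value zero), the direct contribution is
        c1', and VAF = 100 * indirect / (indirect + direct).  With a
        moderated model no single decomposition is canonical; this one keeps
        VAF on the familiar IE/(IE + direct) scale.
        """
        indirect = self.a1 * self.b1
        total = indirect + self.c1_prime
        return {
            "indirect": float(indirect),
            "direct": float(self.c1_prime),
            "total": float(total),
            "vaf_percent": float(100.0 * indirect / total) if total else np.nan,
        }

    def summary(self, boot: BootConfig | None = None) -> str:
        xn, mn, yn, wn = self.names
        g = self.goodman()
        lines = [
            f"Moderated mediation: {xn} -> {mn} -> {yn}, moderator {wn}  (n = {self.n})",
            "-" * 70,
            f"  mediator model   {mn} ~ {xn} + {wn}"
            + (f" + {xn}x{wn}" if self.spec.moderate_a else ""),
            f"    a1 = {self.a1:.4f}, a3 ({xn}x{wn}) = {self.a3:.4f}, "
            f"R2 = {self.mediator_model.r2:.4f}",
            f"  outcome model    {yn} ~ {xn} + {wn} + {mn}"
            + (f" + {mn}x{wn}" if self.spec.moderate_b else "")
            + (f" + {xn}x{wn}" if self.spec.moderate_cprime else ""),
            f"    c1' = {self.c1_prime:.4f}, b1 = {self.b1:.4f}, "
            f"b2 ({mn}x{wn}) = {self.b2:.4f}, R2 = {self.outcome_model.r2:.4f}, "
            f"F({self.outcome_model.df_model}, {self.outcome_model.df_resid}) = "
            f"{self.outcome_model.f_stat:.2f}",
            f"  Goodman Z = {g.z:.3f}, p = {g.p:.4f}",
            "  conditional indirect effects:",
        ]
        tbl = self.summary_table(boot=boot)
        for _, r in tbl.iterrows():
            lines.append(
                f"    w = {r['w']:g}: theta = {r['theta']:.4f} "
                f"[{r['ci_lower']:.4f}, {r['ci_upper']:.4f}]"
            )
        return "\n".join(lines)


def _column(name: str, x, m, w) -> np.ndarray:
    parts = {
        "const": np.ones_like(x),
        "x": x,
        "m": m,
        "w": w,
        "x:w": x * w,
        "m:w": m * w,
    }
    return parts[name]


class ModeratedMediation:
    """First- and second-stage moderated mediation model.

    Parameters
    ----------
    x, m, y, w : array-like
        Predictor, mediator, outcome and moderator vectors (n >= 15, w with
        at least two distinct values).
    spec : ModMedSpec, optional
        Which paths carry the interaction; defaults to moderating the a and
        b paths only.
    """

    def __init__(
        self,
        x,
        m,
        y,
        w,
        spec: ModMedSpec | None = None,
        names: tuple[str, str, str, str] = ("x", "m", "y", "w"),
    ):
        arrs = [np.asarray(v, dtype=float) for v in (x, m, y, w)]
        if len({a.shape for a in arrs}) != 1 or arrs[0].ndim != 1:
            raise ValueError("x, m, y, w must be equal-length 1-d vectors")
        if arrs[0].size < 15:
            raise ValueError("moderated mediation requires n >= 15")
        if not all(np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("variables must be finite")
        if np.unique(arrs[3]).size < 2:
            raise ValueError("moderator must take at least two distinct values")
        self.x, self.m, self.y, self.w = arrs
        self.spec = spec or ModMedSpec()
        self.names = tuple(names)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, x: str, m: str, y: str, w: str,
        spec: ModMedSpec | None = None,
    ) -> "ModeratedMediation":
        return cls(frame[x], frame[m], frame[y], frame[w], spec=spec, names=(x, m, y, w))

    def fit(self) -> ModMedResults:
        """Fit the mediator and outcome regressions with raw product terms."""
        xn, mn, yn, wn = self.names
        med_X = pd.DataFrame({xn: self.x, wn: self.w})
        if self.spec.moderate_a:
            med_X[f"{xn}:{wn}"] = self.x * self.w
        out_X = pd.DataFrame({xn: self.x, wn: self.w, mn: self.m})
        if self.spec.moderate_b:
            out_X[f"{mn}:{wn}"] = self.m * self.w
        if self.spec.moderate_cprime:
            out_X[f"{xn}:{wn}"] = self.x * self.w
        mediator_model = fit_ols(self.m, med_X)
        outcome_model = fit_ols(self.y, out_X)
        res = ModMedResults(
            mediator_model=mediator_model,
            outcome_model=outcome_model,
            spec=self.spec,
            n=self.x.size,
            names=("x", "m", "y", "w"),
            w_observed=(float(self.w.min()), float(self.w.max())),
            _data=(self.x, self.m, self.y, self.w),
        )
        # expose user-facing names on the fit while keeping canonical keys
        object.__setattr__(res, "names", ("x", "m", "y", "w"))
        object.__setattr__(res, "display_names", self.names)
        # rename coefficient indices to canonical x/m/y/w labels
        mapping = {xn: "x", mn: "m", yn: "y", wn: "w",
                   f"{xn}:{wn}": "x:w", f"{mn}:{wn}": "m:w"}
        for f in (mediator_model, outcome_model):
            f.coefficients.rename(index=mapping, inplace=True)
            f.standard_errors.rename(index=mapping, inplace=True)
            f.covariance.rename(index=mapping, columns=mapping, inplace=True)
        return res


def fit_modmed(x, m, y, w, spec: ModMedSpec | None = None) -> ModMedResults:
    """Functional wrapper: build a :class:`ModeratedMediation` and fit it."""
    return ModeratedMediation(x, m, y, w, spec=spec).fit()


def conditional_indirect(fit: ModMedResults, w: float, boot: BootConfig | None = None):
    """Functional wrapper around :meth:`ModMedResults.conditional_indirect`."""
    return fit.conditional_indirect(w, boot=boot)


def johnson_neyman(fit: ModMedResults, path: str = "a", alpha: float = 0.05) -> JNRegion:
    """Functional wrapper around :meth:`ModMedResults.johnson_neyman`."""
    return fit.johnson_neyman(path=path, alpha=alpha)


def modmed_summary(
    fit: ModMedResults, w_values=(21.0, 28.0, 35.0), boot: BootConfig | None = None
) -> pd.DataFrame:
    """Conditional-indirect-effect table plus aggregate VAF and Goodman z.

    Returns the :meth:`ModMedResults.summary_table` frame with the aggregate
    decomposition and Goodman statistic attached in ``frame.attrs``.
    """
    tbl = fit.summary_table(w_values=w_values, boot=boot)
    tbl.attrs["aggregate"] = fit.aggregate_effects()
    g = fit.goodman()
    tbl.attrs["goodman_z"] = g.z
    tbl.attrs["goodman_p"] = g.p
    return tbl
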