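"""Parametric variogram models: WLS fitting, AICc selection, derived range.

Five families are supported, each parameterized by a nugget ``c0`` (the
semivariance at zero distance — community variation below the sampling
interval), a partial sill ``c1`` (the sill is ``c0 + c1``), and a rate/range
parameter ``a``:

======================  ==========================================================
exponential             c0 + c1 * (1 - exp(-h / a))
gaussian                c0 + c1 * (1 - exp(-h^2 / a^2))
spherical               c0 + c1 * (1.5 h/a - 0.5 h^3/a^3), clamped at c0+c1 (h>=a)
linear_piecewise        c0 + c1 * h / a, clamped at c0 + c1 for h >= a
logistic                c0 + c1 * a h^2 / (1 + a h^2)
======================  ==========================================================

For the spherical and piecewise-linear families the range is ``a`` itself;
for the asymptotic families the range is the distance at which the model
reaches 95% of its sill.  Fitting minimizes the pair-count-weighted residual
sum of squares over the empirical distance classes, and family selection
uses the small-sample corrected AIC (AICc) with the residual-variance
parameter counted (K = 4 for all five families).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .variogram import EmpiricalVariogram

__all__ = [
    "FAMILIES",
    "VariogramModelFit",
    "model_value",
    "derived_range",
    "wls_fit",
    "aicc",
    "select_model",
]

FAMILIES = ("exponential", "gaussian", "spherical", "linear_piecewise",
            "logistic")

#: Fraction of the sill defining the range of asymptotic families.
RANGE_SILL_FRACTION = 0.95
N_MODEL_PARAMS = 3  # c0, c1, a


def model_value(family: str, c0: float, c1: float, a: float, h) -> np.ndarray:
    """Evaluate a variogram model at distance(s) h >= 0."""
    if a <= 0:
        raise ValueError("rate/range parameter a must be positive")
    if c0 < 0 or c1 < 0:
        raise ValueError("c0 and c1 must be nonnegative")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be nonnegative")
    if family == "exponential":
        out = c0 + c1 * (1.0 - np.exp(-h / a))
    elif family == "gaussian":
        out = c0 + c1 * (1.0 - np.exp(-(h ** 2) / (a ** 2)))
    elif family == "spherical":
        hc = np.minimum(h, a)
        out = c0 + c1 * (1.5 * hc / a - 0.5 * (hc / a) ** 3)
    elif family == "linear_piecewise":
        out = c0 + c1 * np.minimum(h, a) / a
    elif family == "logistic":
        out = c0 + c1 * a * h ** 2 / (1.0 + a * h ** 2)
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    return out if out.shape else float(out)


@dataclass
class VariogramModelFit:
    """A fitted variogram model and its derived quantities.

    ``scaled_nugget`` (c0 / s²) and ``scaled_range`` (range / h_max) are
    populated by :func:`select_model` or :meth:`with_scaling` once the
    site-level totals are known.
    """

    family: str
    c0: float
    c1: float
    a: float
    rss_weighted: float = float("nan")
    aicc: float = float("nan")
    converged: bool = True
    n_classes: int = 0
    scaled_nugget: float = float("nan")
    scaled_range: float = float("nan")
    aicc_table: dict = field(default_factory=dict)

    @property
    def sill(self) -> float:
        return self.c0 + self.c1

    @property
    def range_km(self) -> float:
        return derived_range(self)

    def __call__(self, h):
        return model_value(self.family, self.c0, self.c1, self.a, h)

    def with_scaling(self, s2: float, h_max: float) -> "VariogramModelFit":
        self.scaled_nugget = self.c0 / s2 if s2 > 0 else float("nan")
        rng = self.range_km
        self.scaled_range = rng / h_max if h_max > 0 else float("nan")
        return self

    def to_dict(self) -> dict:
        return {"family": self.family, "c0": self.c0, "c1": self.c1,
                "a": self.a, "sill": self.sill, "range_km": self.range_km,
                "aicc": self.aicc, "rss_weighted": self.rss_weighted,
                "converged": self.converged,
                "scaled_nugget": self.scaled_nugget,
                "scaled_range": self.scaled_range}


def derived_range(fit: VariogramModelFit) -> float:
    """Range of a fitted model.

    The spherical and piecewise-linear families reach their sill exactly at
    ``a``.  The asymptotic families never reach it, so the range is the
    distance at which the model attains 95% of the sill, solved in closed
    form (exponential, gaussian, logistic all invert analytically).  When
    95% of the sill falls below the nugget (c1 nearly zero relative to c0),
    the range is undefined and NaN is returned.
    """
    c0, c1, a = fit.c0, fit.c1, fit.a
    if a <= 0:
        raise ValueError("a must be positive")
    if fit.family in ("spherical", "linear_piecewise"):
        return float(a)
    sill = c0 + c1
    target = RANGE_SILL_FRACTION * sill - c0  # partial semivariance to reach
    if target <= 0 or c1 <= 0:
        return float("nan")
    if fit.family == "exponential":
        return float(-a * math.log(1.0 - target / c1))
    if fit.family == "gaussian":
        return float(a * math.sqrt(-math.log(1.0 - target / c1)))
    if fit.family == "logistic":
        if target >= c1:
            return float("nan")
        return float(math.sqrt(target / (a * (c1 - target))))
    # fall back to bracketing bisection for any future family
    upper = a
    while model_value(fit.family, c0, c1, a, upper) < RANGE_SILL_FRACTION * sill:
        upper *= 2.0
        if upper > 1e9:
            return float("nan")
    return float(brentq(
        lambda h: model_value(fit.family, c0, c1, a, h) - RANGE_SILL_FRACTION * sill,
        0.0, upper, xtol=1e-6))


def aicc(rss_weighted: float, n_classes: int, n_params: int = N_MODEL_PARAMS) -> float:
    """Small-sample corrected AIC for a least-squares fit.

    AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n - K - 1) with n the number of
    distance classes and K = n_params + 1 (the residual variance counts as
    a parameter).
    """
    n = n_classes
    k = n_params + 1
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: need n_classes > {k + 1}")
    if rss_weighted <= 0:
        rss_weighted = 1e-300  # perfect fit; keep the ordering finite
    return float(n * math.log(rss_weighted / n) + 2 * k
                 + 2 * k * (k + 1) / (n - k - 1))


def _usable_classes(empirical: EmpiricalVariogram):
    mask = empirical.usable()
    h = empirical.classing.class_centers[mask]
    g = empirical.gamma[mask]
    w = empirical.classing.n_pairs[mask].astype(float)
    return h, g, w


def wls_fit(empirical: EmpiricalVariogram, family: str) -> VariogramModelFit:
    """Fit one family by pair-count-weighted least squares.

    Minimizes sum_h n_h (gamma(h) - gamma_model(h))^2 subject to c0, c1 >= 0
    and a > 0.  Nonlinear least squares is sensitive to starting values, so
    a small grid of starts is tried (two nugget fractions of the first-class
    semivariance crossed with three range fractions of the cutoff) and the
    best converged solution kept.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    h, g, w = _usable_classes(empirical)
    if len(h) < N_MODEL_PARAMS + 1:
        raise ValueError("need at least 4 usable distance classes to fit")
    sw = np.sqrt(w)
    gmax = float(g.max())
    cutoff = empirical.classing.cutoff_km

    def resid(p):
        c0, c1, a = p
        return sw * (g - model_value(family, c0, c1, a, h))

    # logistic's a is a curvature (km^-2): map the range-like starts through
    # the 95% rule so each family starts in a comparable regime
    def a_start(frac):
        r = max(frac * cutoff, 1e-6)
        if family == "logistic":
            return 19.0 / r ** 2  # a h^2/(1+a h^2)=0.95 at h=r
        if family == "exponential":
            return r / 3.0
        if family == "gaussian":
            return r / math.sqrt(3.0)
        return r

    best = None
    for c0_frac in (0.25, 0.5):
        for r_frac in (0.25, 0.5, 1.0):
            c0_0 = max(c0_frac * g[0], 1e-8)
            c1_0 = max(gmax - c0_0, 1e-8)
            x0 = np.array([c0_0, c1_0, a_start(r_frac)])
            try:
                sol = least_squares(resid, x0,
                                    bounds=([0.0, 0.0, 1e-9],
                                            [np.inf, np.inf, np.inf]),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:  # pragma: no cover - optimizer failure path
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol.x)
    if best is None:
        return VariogramModelFit(family=family, c0=np.nan, c1=np.nan,
                                 a=np.nan, converged=False,
                                 n_classes=len(h))
    rss, (c0, c1, a) = best
    fit = VariogramModelFit(family=family, c0=float(c0), c1=float(c1),
                            a=float(a), rss_weighted=rss, converged=True,
                            n_classes=len(h))
    try:
        fit.aicc = aicc(rss, len(h))
    except ValueError:
        fit.aicc = float("nan")
    return fit


def select_model(empirical: EmpiricalVariogram, s2: float | None = None,
                 h_max: float | None = None) -> VariogramModelFit:
    """Fit all five families and return the minimum-AICc fit.

    The winner carries the full per-family AICc table in ``aicc_table`` and,
    when ``s2`` / ``h_max`` are given, the scaled nugget (c0 / s²) and
    scaled range (range / h_max).
    """
    fits = {}
    for family in FAMILIES:
        try:
            fits[family] = wls_fit(empirical, family)
        except ValueError:
            continue
    usable = {f: ft for f, ft in fits.items()
              if ft.converged and np.isfinite(ft.aicc)}
    if not usable:
        raise RuntimeError("no variogram family converged")
    # deterministic tie-break: AICc then family name
    winner = min(usable.values(), key=lambda ft: (ft.aicc, ft.family))
    winner.aicc_table = {f: ft.to_dict() for f, ft in fits.items()}
    if s2 is None:
        s2 = float("nan")
    if h_max is None:
        h_max = empirical.classing.h_max
    if np.isfinite(s2):
        winner.with_scaling(s2, h_max)
    else:
        winner.scaled_range = (winner.range_km / h_max
                               if h_max and h_max > 0 else float("nan"))
    if winner.c1 < 1e-8 * max(winner.c0, 1.0):
        warnings.warn("selected model is essentially pure nugget (c1 ~ 0)",
                      UserWarning, stacklevel=2)
    return winner
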