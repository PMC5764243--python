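"""Multiscale ordination: variogram decomposition and spatial diagnostics.

Inserting the fitted/residual split of an RDA into the empirical
multivariate variogram partitions the per-class semivariance as

    gamma(h) = gamma_fit(h) + gamma_res(h) + gamma_cross(h)

where the first two terms are variograms of the fitted and residual values
and the cross term is twice the per-class covariance of fitted and residual
differences.  Three diagnostics then probe the spatial adequacy of the
ordination model:

* scale dependence — is gamma_fit + gamma_res inside a Bonferroni-corrected
  point confidence envelope around gamma?  (a class outside means the
  cross term, hence the biotic-environmental relationship, is
  scale-dependent);
* residual autocorrelation — per-class Mantel permutation tests between
  residual community distances and class membership;
* residual stationarity — does gamma_res reach a sill and stay there over
  the upper distance classes (no missing spatially structured driver)?
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .rda import RDAModel
from .variogram import DistanceClassing, pair_semivariances

logger = logging.getLogger(__name__)

__all__ = [
    "MSOResult",
    "mso_decompose",
    "scale_dependence_test",
    "mantel_residual_tests",
    "stationarity_check",
    "plot_mso",
]

#: Classes with fewer pairs than this are excluded from the multiple-test
#: count m and skipped by the Mantel tests.
MIN_PAIRS_FOR_TESTS = 5


@dataclass
class MSOResult:
    """Per-distance-class variogram decomposition and diagnostic flags."""

    classing: DistanceClassing
    gamma: np.ndarray
    gamma_fit: np.ndarray
    gamma_res: np.ndarray
    gamma_cross: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    ci_upper: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale_dependent: np.ndarray = field(default=None)  # type: ignore[assignment]
    mantel_r: np.ndarray = field(default=None)  # type: ignore[assignment]
    mantel_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    mantel_significant: np.ndarray = field(default=None)  # type: ignore[assignment]
    stationarity_ok: bool | None = None

    def testable(self) -> np.ndarray:
        """Classes that enter the multiple-testing count m."""
        return self.classing.n_pairs >= MIN_PAIRS_FOR_TESTS

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "class_center_km": self.classing.class_centers,
            "n_pairs": self.classing.n_pairs,
            "gamma": self.gamma,
            "gamma_fit": self.gamma_fit,
            "gamma_res": self.gamma_res,
            "gamma_cross": self.gamma_cross,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "scale_flag": self.scale_dependent,
            "mantel_r": self.mantel_r,
            "mantel_p": self.mantel_p,
            "mantel_sig": self.mantel_significant,
        })


def mso_decompose(rda_model: RDAModel, classing: DistanceClassing) -> MSOResult:
    """Decompose the empirical variogram into fitted/residual/cross parts.

    Applies the variogram sum separately to the fitted and residual matrices
    of the RDA; the cross component is recovered as gamma - gamma_fit -
    gamma_res, which equals twice the per-class covariance of fitted and
    residual differences.
    """
    if list(rda_model.sample_ids) != list(classing.sample_ids):
        raise ValueError("rda model and classing sample ids do not match")
    Y = rda_model.Y_centered
    F = rda_model.fitted
    R = rda_model.residual

    m = classing.n_classes
    gamma = np.full(m, np.nan)
    g_fit = np.full(m, np.nan)
    g_res = np.full(m, np.nan)
    se = np.full(m, np.nan)
    for k, pairs in enumerate(classing.pair_lists):
        if len(pairs) == 0:
            continue
        sv = pair_semivariances(Y, pairs)
        gamma[k] = sv.mean()
        g_fit[k] = pair_semivariances(F, pairs).mean()
        g_res[k] = pair_semivariances(R, pairs).mean()
        if len(sv) > 1:
            se[k] = sv.std(ddof=1) / np.sqrt(len(sv))
    g_cross = gamma - g_fit - g_res
    return MSOResult(classing=classing, gamma=gamma, gamma_fit=g_fit,
                     gamma_res=g_res, gamma_cross=g_cross, se=se)


def scale_dependence_test(mso: MSOResult, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni envelope test for scale dependence of the fit.

    Builds the envelope gamma(h) +/- z_{1-alpha/(2m)} * se(gamma(h)) over
    the m testable classes and flags a class when gamma_fit + gamma_res
    falls outside it (i.e. the cross term differs from zero there).  The
    relationship is scale-dependent overall if any class is flagged.
    Flags are stored on ``mso`` and returned.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    testable = mso.testable() & np.isfinite(mso.se)
    skipped = (mso.classing.n_pairs > 0) & ~testable
    if skipped.any():
        warnings.warn(f"{int(skipped.sum())} class(es) with < "
                      f"{MIN_PAIRS_FOR_TESTS} pairs excluded from the "
                      "scale-dependence envelope", UserWarning, stacklevel=2)
    m = int(testable.sum())
    nc = mso.classing.n_classes
    lo = np.full(nc, np.nan)
    hi = np.full(nc, np.nan)
    flags = np.zeros(nc, dtype=bool)
    if m > 0:
        z = norm.ppf(1.0 - alpha / (2.0 * m))
        lo[testable] = mso.gamma[testable] - z * mso.se[testable]
        hi[testable] = mso.gamma[testable] + z * mso.se[testable]
        s = mso.gamma_fit + mso.gamma_res
        flags[testable] = (s[testable] < lo[testable]) | (s[testable] > hi[testable])
    mso.ci_lower, mso.ci_upper, mso.scale_dependent = lo, hi, flags
    return flags


def _mantel_r(values: np.ndarray, indicator: np.ndarray) -> float:
    v = values - values.mean()
    w = indicator - indicator.mean()
    denom = np.sqrt((v ** 2).sum() * (w ** 2).sum())
    if denom == 0:
        return np.nan
    return float((v * w).sum() / denom)


def mantel_residual_tests(rda_model: RDAModel, classing: DistanceClassing,
                          alpha: float = 0.05, n_perm: int = 999,
                          rng=None, mso: MSOResult | None = None):
    """Bonferroni-adjusted per-class Mantel tests on the RDA residuals.

    For each distance class, the Mantel statistic is the correlation (over
    all station pairs within the cutoff) between the Euclidean distances of
    the residual rows and the binary membership matrix of the class.  The
    permutation null permutes station labels (simultaneous row/column
    permutation of the residual distance matrix); the two-sided p-value is
    compared against the Bonferroni level alpha / m, m counting only
    classes with at least ``MIN_PAIRS_FOR_TESTS`` pairs.

    Returns ``(r, p, significant)`` arrays, also stored on ``mso`` if given.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if list(rda_model.sample_ids) != list(classing.sample_ids):
        raise ValueError("rda model and classing sample ids do not match")
    rng = np.random.default_rng(rng)

    n = len(rda_model.sample_ids)
    D = squareform(pdist(rda_model.residual))
    iu = np.triu_indices(n, k=1)
    d_vec = D[iu]

    nc = classing.n_classes
    n_pairs = classing.n_pairs
    testable = n_pairs >= MIN_PAIRS_FOR_TESTS
    if np.any((n_pairs > 0) & ~testable):
        warnings.warn("class(es) with too few pairs skipped by Mantel tests",
                      UserWarning, stacklevel=2)
    m = int(testable.sum())

    # per-class binary membership over the upper triangle
    indicators = np.zeros((nc, len(d_vec)))
    pair_pos = {}
    pos = np.zeros((n, n), dtype=int)
    pos[iu] = np.arange(len(d_vec))
    for k, pairs in enumerate(classing.pair_lists):
        if len(pairs) == 0:
            continue
        indicators[k, pos[pairs[:, 0], pairs[:, 1]]] = 1.0
        pair_pos[k] = True

    r_obs = np.full(nc, np.nan)
    for k in range(nc):
        if testable[k]:
            r_obs[k] = _mantel_r(d_vec, indicators[k])

    exceed = np.zeros(nc)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d_perm = D[np.ix_(perm, perm)][iu]
        for k in range(nc):
            if testable[k] and np.isfinite(r_obs[k]):
                r_p = _mantel_r(d_perm, indicators[k])
                if np.isfinite(r_p) and abs(r_p) >= abs(r_obs[k]) - 1e-15:
                    exceed[k] += 1

    p = np.full(nc, np.nan)
    p[testable] = (exceed[testable] + 1.0) / (n_perm + 1.0)
    sig = np.zeros(nc, dtype=bool)
    if m > 0:
        sig[testable] = p[testable] < alpha / m
    if mso is not None:
        mso.mantel_r, mso.mantel_p, mso.mantel_significant = r_obs, p, sig
    return r_obs, p, sig


def stationarity_check(mso: MSOResult, alpha: float = 0.05) -> bool:
    """Test whether gamma_res has levelled off over the larger classes.

    Fits a pair-count-weighted least-squares line to gamma_res over the
    upper half of the usable classes; the residuals are stationary when the
    slope's (1 - alpha) confidence interval covers zero.  The result is
    stored as ``mso.stationarity_ok`` and returned.
    """
    import statsmodels.api as sm

    usable = np.isfinite(mso.gamma_res)
    idx = np.nonzero(usable)[0]
    if len(idx) < 4:
        raise ValueError("stationarity check needs at least 4 usable classes")
    upper = idx[len(idx) // 2:]
    h = mso.classing.class_centers[upper]
    g = mso.gamma_res[upper]
    w = mso.classing.n_pairs[upper].astype(float)
    X = sm.add_constant(h)
    res = sm.WLS(g, X, weights=w).fit()
    lo, hi = res.conf_int(alpha=alpha)[1]
    ok = bool(lo <= 0.0 <= hi)
    mso.stationarity_ok = ok
    return ok


def plot_mso(mso: MSOResult, ax=None):
    """Plot the decomposition: empirical envelope, fit diamonds, residual squares.

    Requires matplotlib; returns the axes.  Solid squares mark classes with
    significant residual Mantel tests.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    h = mso.classing.class_centers
    ax.plot(h, mso.gamma, "k-", lw=1, label="empirical")
    if mso.ci_lower is not None:
        ax.plot(h, mso.ci_lower, "k--", lw=0.8)
        ax.plot(h, mso.ci_upper, "k--", lw=0.8)
    ax.plot(h, mso.gamma_fit, "D", mfc="none", mec="tab:blue", label="fitted")
    filled = (mso.mantel_significant
              if mso.mantel_significant is not None
              else np.zeros(len(h), dtype=bool))
    ax.plot(h[~filled], mso.gamma_res[~filled], "s", mfc="none",
            mec="tab:orange", label="residual")
    if filled.any():
        ax.plot(h[filled], mso.gamma_res[filled], "s", color="tab:orange")
    ax.plot(h, mso.gamma_fit + mso.gamma_res, "+", color="gray",
            label="fit + res")
    for xk, nk in zip(h, mso.classing.n_pairs):
        ax.annotate(str(nk), (xk, 0), xytext=(0, -12),
                    textcoords="offset points", ha="center", fontsize=7)
    ax.set_xlabel("distance class (km)")
    ax.set_ylabel("semivariance (Hellinger²)")
    ax.legend(fontsize=8)
    return ax
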