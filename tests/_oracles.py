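"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: marginal
likelihoods come from numerical integration of likelihood x prior over
(intercept, slope, sigma), and posterior summaries from literal sums
over explicitly enumerated models.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

_EPSREL = 2e-4  # plenty for the 1% comparisons these oracles support


def _setup(y, x, g):
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = y - y.mean()
    ols = float(xc @ yc / sxx)
    resid_sd = float(np.sqrt(np.sum((yc - ols * xc) ** 2) / n))

    def log_f1(b0, b, s):
        resid = y - b0 - b * xc
        ll = -n * np.log(s) - 0.5 * np.sum(resid**2) / s**2 - 0.5 * n * np.log(2 * np.pi)
        lp_b = (
            -0.5 * np.log(2 * np.pi)
            + 0.5 * np.log(g * sxx)
            - np.log(s)
            - 0.5 * g * sxx * b**2 / s**2
        )
        return ll + lp_b - np.log(s)

    def log_f0(b0, s):
        resid = y - b0
        ll = -n * np.log(s) - 0.5 * np.sum(resid**2) / s**2 - 0.5 * n * np.log(2 * np.pi)
        return ll - np.log(s)

    return y, n, xc, sxx, ols, resid_sd, log_f1, log_f0


def _integrate_model(y, x, g, weight=None):
    """∫ w(b) L(y|b0,b,s) p(b|s) db0 db ds / σ-prior, by adaptive quadrature.

    The (b0, b) axes are rescaled by s around the conditional posterior
    centers (ȳ and OLS/(1+g)), so the integrand has O(1) width for every
    s and the adaptive rule converges quickly; this centering uses only
    completion-of-squares facts, not the closed-form marginal under test.
    """
    y, n, xc, sxx, ols, resid_sd, log_f1, _ = _setup(y, x, g)
    b_center = ols / (1 + g)
    b_scale = 1.0 / np.sqrt((1 + g) * sxx)
    shift = log_f1(y.mean(), ols, resid_sd)
    w = weight if weight is not None else (lambda b: 1.0)

    def f(s, u, u0):
        b0 = y.mean() + s * u0 / np.sqrt(n)
        b = b_center + s * u * b_scale
        jac = s * s / np.sqrt(n) * b_scale
        return w(b) * np.exp(log_f1(b0, b, s) - shift) * jac

    val, _ = integrate.tplquad(
        f,
        -12, 12,                      # u0
        lambda u0: -12, lambda u0: 12,  # u
        lambda u0, u: resid_sd / 20, lambda u0, u: resid_sd * 40,  # s
        epsrel=_EPSREL,
    )
    return np.log(val) + shift


def quadrature_log_bayes_factor(y: np.ndarray, x: np.ndarray, g: float) -> float:
    """log [ p(y|M1) / p(y|M0) ] for a one-covariate model by 3-D quadrature.

    M1: y_i = b0 + b * xc_i + e, prior p(b0, s) ~ 1/s and
    b ~ N(0, s^2 / (g * xc'xc)); M0 drops the slope. Integrands are
    shifted by their log peak to avoid underflow.
    """
    log_m1 = _integrate_model(y, x, g)
    y, n, xc, sxx, ols, resid_sd, _, log_f0 = _setup(y, x, g)
    null_sd = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    shift0 = log_f0(y.mean(), null_sd)

    def f0(s, u0):
        b0 = y.mean() + s * u0 / np.sqrt(n)
        return np.exp(log_f0(b0, s) - shift0) * s / np.sqrt(n)

    val0, _ = integrate.dblquad(
        f0,
        -12, 12,
        lambda u0: null_sd / 20, lambda u0: null_sd * 40,
        epsrel=_EPSREL,
    )
    return log_m1 - (np.log(val0) + shift0)


def quadrature_posterior_slope_mean(y: np.ndarray, x: np.ndarray, g: float) -> float:
    """E[b | y, M1] for the one-covariate model by numerical integration."""
    log_denom = _integrate_model(y, x, g)
    log_numer_signed = _integrate_model(y, x, g, weight=lambda b: b)
    return np.exp(log_numer_signed - log_denom)


def brute_force_pips(posterior_probs: np.ndarray, k: int) -> np.ndarray:
    """Literal indicator-weighted sum over explicitly listed models."""
    pips = np.zeros(k)
    for mask, p in enumerate(posterior_probs):
        for cov in range(k):
            if (mask >> cov) & 1:
                pips[cov] += p
    return pips
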