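"""Johnson SU marginals and normal-score transforms.

The acute percent change of the biomarker (and the residuals of its
covariate regressions) is skewed and heavy-tailed, so a normal marginal is
a poor fit.  The Johnson SU family,

    Z = gamma + delta * asinh((X - xi) / lam),   Z ~ N(0, 1),

has unbounded support, closed-form cdf/quantile, and contains near-normal
shapes as ``delta -> inf``, which makes it the natural marginal for the
normal-score transform underlying the Gaussian copula: ``normal_score``
maps draws from a fitted SU law to standard normal deviates exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "JohnsonSUParams",
    "FittingError",
    "fit_johnson_su",
    "johnson_cdf",
    "johnson_quantile",
    "normal_score",
    "su_mean_sd",
    "standardized_su",
]

_MIN_SAMPLES = 50


class FittingError(RuntimeError):
    """Raised when the SU maximum-likelihood optimizer fails to converge."""


@dataclass(frozen=True)
class JohnsonSUParams:
    """Parameters of a Johnson SU distribution.

    gamma, delta are dimensionless shapes (delta > 0); xi, lam are
    location/scale on the biomarker percent-change scale (lam > 0).
    """

    gamma: float
    delta: float
    xi: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.delta > 0 and self.lam > 0):
            raise ValueError(
                f"delta and lam must be positive, got delta={self.delta}, lam={self.lam}"
            )


def johnson_cdf(params: JohnsonSUParams, x):
    """SU cdf: Phi(gamma + delta * asinh((x - xi) / lam)). Vectorized in x."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("johnson_cdf requires finite x")
    z = params.gamma + params.delta * np.arcsinh((x - params.xi) / params.lam)
    out = ndtr(z)
    return out if out.ndim else float(out)


def johnson_quantile(params: JohnsonSUParams, p):
    """SU quantile: xi + lam * sinh((Phi^-1(p) - gamma) / delta). Vectorized."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("quantile requires p strictly inside (0, 1)")
    out = params.xi + params.lam * np.sinh((ndtri(p) - params.gamma) / params.delta)
    return out if out.ndim else float(out)


def normal_score(params: JohnsonSUParams, x):
    """Latent-normal score Phi^-1(F(x)) = gamma + delta * asinh((x - xi)/lam).

    Computed directly on the asinh scale, so it stays finite and strictly
    increasing even in the far tails where F(x) underflows to 0 or 1.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("normal_score requires finite x")
    out = params.gamma + params.delta * np.arcsinh((x - params.xi) / params.lam)
    return out if out.ndim else float(out)


def _su_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    return _su_negloglik_grad(theta, x)[0]


def _su_negloglik_grad(theta: np.ndarray, x: np.ndarray):
    """Negative SU log-likelihood and its analytic gradient on the
    (gamma, log delta, xi, log lam) scale."""
    gamma, log_delta, xi, log_lam = theta
    delta = np.exp(log_delta)
    lam = np.exp(log_lam)
    u = (x - xi) / lam
    s2 = 1.0 + u * u
    s = np.sqrt(s2)
    a = np.arcsinh(u)
    z = gamma + delta * a
    # log pdf = log(delta) - log(lam) - 0.5*log(2*pi) - 0.5*log(1+u^2) - z^2/2
    ll = (
        np.log(delta)
        - np.log(lam)
        - 0.5 * np.log(2 * np.pi)
        - 0.5 * np.log1p(u * u)
        - 0.5 * z * z
    )
    n = x.size
    g_gamma = np.sum(z)
    g_logdelta = np.sum(z * a) * delta - n
    g_xi = -np.sum(u / (lam * s2) + z * delta / (lam * s))
    g_loglam = -np.sum(-1.0 + u * u / s2 + z * delta * u / s)
    grad = np.array([g_gamma, g_logdelta, g_xi, g_loglam])
    return -float(np.sum(ll)), grad


def _moment_init(x: np.ndarray) -> np.ndarray:
    """Quantile-based starting values on the (gamma, log delta, xi, log lam) scale."""
    q = np.quantile(x, [0.1, 0.25, 0.5, 0.75, 0.9])
    iqr = max(q[3] - q[1], 1e-8)
    # delta from tail spread relative to the IQR; skew from quartile asymmetry
    spread = (q[4] - q[0]) / iqr
    delta0 = float(np.clip(2.6 / max(spread - 1.0, 0.15), 0.3, 8.0))
    skew = ((q[3] - q[2]) - (q[2] - q[1])) / iqr
    gamma0 = float(np.clip(-3.0 * skew * delta0, -3.0, 3.0))
    lam0 = iqr * delta0 / 1.35
    xi0 = q[2] + lam0 * np.sinh(gamma0 / delta0)
    return np.array([gamma0, np.log(delta0), xi0, np.log(lam0)])


def fit_johnson_su(samples) -> JohnsonSUParams:
    """Fit a Johnson SU distribution by maximum likelihood.

    Uses quantile-based starting values and L-BFGS-B on
    (gamma, log delta, xi, log lam); retries from a near-normal start if the
    first attempt stalls.  Falls back to a near-normal SU (moment-matched,
    delta large) with a loud warning only if both attempts fail, so the
    copula machinery above never receives an unusable marginal.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < _MIN_SAMPLES:
        raise ValueError(f"need at least {_MIN_SAMPLES} finite samples, got {x.size}")
    if np.std(x) == 0:
        raise ValueError("samples have zero variance; SU fit is undefined")

    starts = [_moment_init(x)]
    # near-normal start: SU(0, delta) with delta large approximates N(mean, sd)
    m, s = float(np.mean(x)), float(np.std(x))
    starts.append(np.array([0.0, np.log(3.0), m, np.log(3.0 * s)]))

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for theta0 in starts:
            res = optimize.minimize(
                _su_negloglik_grad,
                theta0,
                args=(x,),
                jac=True,
                method="L-BFGS-B",
                bounds=[(-20, 20), (np.log(1e-3), np.log(50.0)), (None, None),
                        (np.log(1e-6 * s + 1e-300), np.log(1e3 * s))],
                options={"maxiter": 500},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
            if best is not None and res.success:
                break  # fall through to the next start only on failure

    if best is None or not np.isfinite(best.fun):
        logger.warning(
            "Johnson SU MLE failed (%s); falling back to a moment-matched "
            "near-normal SU", None if best is None else best.message
        )
        return JohnsonSUParams(gamma=0.0, delta=10.0, xi=m, lam=10.0 * s)

    gamma, log_delta, xi, log_lam = best.x
    return JohnsonSUParams(
        gamma=float(gamma), delta=float(np.exp(log_delta)),
        xi=float(xi), lam=float(np.exp(log_lam)),
    )


def su_mean_sd(params: JohnsonSUParams) -> tuple[float, float]:
    """Exact mean and SD of an SU law (closed-form lognormal-type moments)."""
    mean, var = stats.johnsonsu.stats(
        params.gamma, params.delta, loc=params.xi, scale=params.lam, moments="mv"
    )
    return float(mean), float(np.sqrt(var))


def standardized_su(gamma: float, delta: float, mean: float = 0.0, sd: float = 1.0) -> JohnsonSUParams:
    """SU params with the given shapes, rescaled to a target mean and SD.

    Convenience for generators that need a skewed residual law with an
    exact first and second moment.
    """
    base = JohnsonSUParams(gamma=gamma, delta=delta, xi=0.0, lam=1.0)
    m0, s0 = su_mean_sd(base)
    lam = sd / s0
    xi = mean - m0 * lam
    return JohnsonSUParams(gamma=gamma, delta=delta, xi=xi, lam=lam)
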