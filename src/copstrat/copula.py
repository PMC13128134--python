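"""Gaussian copula over the two counterfactual acute changes.

The joint law of (W(0), W(1)) — the acute biomarker change a subject would
show without and with treatment — is never observed for the same subject.
We couple the two marginals through a bivariate normal on their normal
scores with correlation ``rho``, the cross-world sensitivity parameter.
Conditioning on the observed treated-arm change w1 then gives a tractable
conditional law for the unobserved control-side change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import ndtr, ndtri

from ._seeding import substream
from .distributions import (
    JohnsonSUParams,
    johnson_cdf,
    johnson_quantile,
    normal_score,
)

__all__ = [
    "NormalMarginal",
    "CopulaSpec",
    "DegenerateCopulaError",
    "conditional_cdf",
    "conditional_sample",
    "conditional_normal_mean",
]


@dataclass(frozen=True)
class NormalMarginal:
    """Plain normal marginal, the delta -> inf limit of the SU family."""

    mu: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")


Marginal = Union[JohnsonSUParams, NormalMarginal]


class DegenerateCopulaError(ValueError):
    """|rho| = 1 has no conditional density; use conditional_sample."""


def _score(marginal: Marginal, x):
    if isinstance(marginal, NormalMarginal):
        return (np.asarray(x, dtype=float) - marginal.mu) / marginal.sd
    return normal_score(marginal, x)


def _cdf(marginal: Marginal, x):
    if isinstance(marginal, NormalMarginal):
        return ndtr((np.asarray(x, dtype=float) - marginal.mu) / marginal.sd)
    return johnson_cdf(marginal, x)


def _quantile(marginal: Marginal, p):
    if isinstance(marginal, NormalMarginal):
        return marginal.mu + marginal.sd * ndtri(np.asarray(p, dtype=float))
    return johnson_quantile(marginal, p)


def _from_score(marginal: Marginal, z):
    """Inverse of _score, evaluated on the latent scale (no cdf round trip)."""
    z = np.asarray(z, dtype=float)
    if isinstance(marginal, NormalMarginal):
        return marginal.mu + marginal.sd * z
    return marginal.xi + marginal.lam * np.sinh((z - marginal.gamma) / marginal.delta)


@dataclass(frozen=True)
class CopulaSpec:
    """Gaussian copula with marginals for the control (0) and treated (1) side."""

    rho: float
    marginal0: Marginal
    marginal1: Marginal

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")


def conditional_cdf(spec: CopulaSpec, w0, w1):
    """F_{W(0)|W(1)}(w0 | w1) under the Gaussian copula.

    Equals Phi( (Phi^-1[F0(w0)] - rho * Phi^-1[F1(w1)]) / sqrt(1 - rho^2) );
    non-decreasing in w0.
    """
    if abs(spec.rho) >= 1.0:
        raise DegenerateCopulaError(
            "|rho| = 1 is a point mass; draw from conditional_sample instead"
        )
    z0 = _score(spec.marginal0, w0)
    z1 = _score(spec.marginal1, w1)
    out = ndtr((z0 - spec.rho * z1) / np.sqrt(1.0 - spec.rho**2))
    return out if np.ndim(out) else float(out)


def conditional_sample(
    spec: CopulaSpec, w1: float, n_draws: int, seed: int
) -> np.ndarray:
    """Draw n_draws values of W(0) given W(1) = w1. Reproducible under seed.

    Latent route: z1 = Phi^-1[F1(w1)], z0 ~ N(rho*z1, 1 - rho^2),
    w0 = F0^-1[Phi(z0)].  At rho = 1 the conditional law is the point mass
    F0^-1(F1(w1)); at rho = -1 the antitonic counterpart F0^-1(1 - F1(w1)).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    z1 = float(_score(spec.marginal1, w1))
    if spec.rho >= 1.0:
        return np.full(n_draws, float(_from_score(spec.marginal0, z1)))
    if spec.rho <= -1.0:
        return np.full(n_draws, float(_from_score(spec.marginal0, -z1)))
    rng = substream(seed, "copula", int(round(w1 * 1e6)))
    z0 = spec.rho * z1 + np.sqrt(1.0 - spec.rho**2) * rng.standard_normal(n_draws)
    return np.asarray(_from_score(spec.marginal0, z0))


def conditional_normal_mean(
    mu0: float, mu1: float, sd0: float, sd1: float, rho: float, w1: float
) -> float:
    """Bivariate-normal conditional expectation E[W(0) | W(1) = w1].

    The closed-form special case used for back-of-envelope reasoning about
    how far an observed treated-arm change regresses toward the control
    mean: mu0 + rho * (sd0/sd1) * (w1 - mu1).
    """
    if not (sd0 > 0 and sd1 > 0):
        raise ValueError("sd0 and sd1 must be positive")
    return mu0 + rho * (sd0 / sd1) * (w1 - mu1)
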