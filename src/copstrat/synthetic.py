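"""Synthetic randomized-trial generator with known potential outcomes.

Emulates the structure of the large SGLT-2i kidney-outcome trials: baseline
covariates (eGFR, log proteinuria, age, SBP, sex, diabetes), an acute
percent change of eGFR at one month with covariate-dependent means
(control mean ~ -0.6%, treated ~ -6.4%, SD ~ 12.7%, skewed Johnson SU
residuals, latent cross-world residual correlation rho_true), and
competing clinical events over ~2 years: a kidney-failure-like primary
event (~4%) generated from a subdistribution-proportional-hazards mixture
so Fine-Gray fits are correctly specified, and a death-like competing
event (~6%) from an exponential hazard.

Both arms' potential outcomes are drawn for every subject, so the
generator doubles as the Monte-Carlo oracle (``true_cate``) against which
the identification machinery is tested without any cross-world assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import substream
from .distributions import JohnsonSUParams, standardized_su

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_trial",
    "generate_competing_risks",
    "true_cate",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = [
    "subject_id", "trial", "arm", "time_years", "event_type",
    "delta_egfr_pct", "egfr0", "log_upcr", "age", "sbp", "female", "diabetes",
]

COVARIATE_COLS = ("egfr0", "log_upcr", "age", "sbp", "female", "diabetes")
_CONT = ("egfr0", "log_upcr", "age", "sbp")


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults reproduce trial-like marginals; see module docstring."""

    n_per_arm: int = 4000
    trial: str = "SYNTH-1"
    rho_true: float = 0.8
    seed: int = 0

    # acute-change model: W(a) = intercept_a + X*slopes_a + resid_a
    mean_w0: float = -0.6
    mean_w1: float = -6.4
    sd_w: float = 12.7
    slopes0: dict = field(default_factory=lambda: {
        "egfr0": 0.04, "log_upcr": -0.25, "age": -0.015,
        "sbp": -0.008, "female": 0.3, "diabetes": -0.4,
    })
    slopes1: dict = field(default_factory=lambda: {
        "egfr0": 0.05, "log_upcr": -0.30, "age": -0.020,
        "sbp": -0.010, "female": 0.3, "diabetes": -0.5,
    })
    # residual shape (left-skewed SU); scale solved to hit sd_w
    resid_shape0: tuple = (-0.6, 2.2)
    resid_shape1: tuple = (-0.8, 2.0)

    # covariate law (Table-1-like)
    cov_means: dict = field(default_factory=lambda: {
        "egfr0": 61.9, "log_upcr": 5.5, "age": 62.8, "sbp": 137.2,
    })
    cov_sds: dict = field(default_factory=lambda: {
        "egfr0": 22.3, "log_upcr": 1.8, "age": 9.8, "sbp": 16.8,
    })
    cov_corr: dict = field(default_factory=lambda: {
        ("egfr0", "log_upcr"): -0.30, ("egfr0", "age"): -0.20,
        ("age", "sbp"): 0.15,
    })
    p_female: float = 0.31
    p_diabetes: float = 0.92

    # cause-1 (kidney-failure-like) subdistribution mixture:
    # Pr(T<=t, E=1 | lp) = 1 - (1 - p_base*(1 - exp(-t/tau1)))^exp(lp)
    p_base: float = 0.05
    tau1: float = 2.0
    coef_w: float = -0.025         # per % acute change: declines raise risk
    coef_arm1: float = -0.40       # direct protective treatment effect
    coef_x1: dict = field(default_factory=lambda: {
        "egfr0": -0.015, "log_upcr": 0.15, "age": 0.008,
        "sbp": 0.003, "female": -0.10, "diabetes": 0.20,
    })
    # cause-2 (death-like) exponential hazard: rate2 * exp(lp2)
    rate2: float = 0.027
    coef_arm2: float = -0.10
    coef_x2: dict = field(default_factory=lambda: {
        "egfr0": -0.010, "age": 0.030,
    })

    # censoring
    admin_horizon: float = 2.6
    censor_rate: float = 0.02

    # negative control: shared frailty linking the acute effect to the
    # control-arm event process (breaks the no-confounding assumption)
    violate_no_confounding: bool = False
    frailty_sd: float = 0.5


@dataclass
class SyntheticTruth:
    """Full potential-outcome table; the observed dataset is its masking."""

    table: pd.DataFrame  # per subject: covariates, W0, W1, eps0, eps1, T0, E0, T1, E1
    config: GeneratorConfig
    residual0: JohnsonSUParams = None
    residual1: JohnsonSUParams = None


def _draw_covariates(cfg: GeneratorConfig, n: int, rng) -> pd.DataFrame:
    sds = np.array([cfg.cov_sds[c] for c in _CONT])
    corr = np.eye(len(_CONT))
    idx = {c: i for i, c in enumerate(_CONT)}
    for (a, b), r in cfg.cov_corr.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    cov = corr * np.outer(sds, sds)
    mu = np.array([cfg.cov_means[c] for c in _CONT])
    X = rng.multivariate_normal(mu, cov, size=n)
    df = pd.DataFrame(X, columns=list(_CONT))
    df["egfr0"] = df["egfr0"].clip(lower=10.0)
    df["female"] = (rng.random(n) < cfg.p_female).astype(float)
    df["diabetes"] = (rng.random(n) < cfg.p_diabetes).astype(float)
    return df


def _lp1(cfg: GeneratorConfig, w: np.ndarray, X: pd.DataFrame, arm: int,
         frailty: np.ndarray) -> np.ndarray:
    lp = cfg.coef_w * (w - cfg.mean_w0)
    for c, b in cfg.coef_x1.items():
        lp = lp + b * (X[c].to_numpy() - cfg.cov_means.get(c, 0.0))
    lp = lp + cfg.coef_arm1 * arm
    if arm == 0:
        lp = lp + frailty
    return lp


def _draw_events(cfg: GeneratorConfig, w: np.ndarray, X: pd.DataFrame,
                 arm: int, frailty: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Potential (T, E) under arm a via the subdistribution mixture."""
    n = len(w)
    lp1 = _lp1(cfg, w, X, arm, frailty)
    elp = np.exp(lp1)
    u = rng.random(n)
    p_cause1 = 1.0 - (1.0 - cfg.p_base) ** elp
    is1 = u < p_cause1
    T = np.empty(n)
    E = np.where(is1, 1, 2)
    # invert the conditional subdistribution cdf for cause-1 times
    inner = (1.0 - (1.0 - u[is1]) ** (1.0 / elp[is1])) / cfg.p_base
    T[is1] = -cfg.tau1 * np.log1p(-np.clip(inner, 0.0, 1.0 - 1e-12))
    # cause-2 times: exponential in X and arm
    lp2 = np.full(n, cfg.coef_arm2 * arm, dtype=float)
    for c, b in cfg.coef_x2.items():
        lp2 += b * (X[c].to_numpy() - cfg.cov_means.get(c, 0.0))
    T2 = rng.exponential(1.0, size=n) / (cfg.rate2 * np.exp(lp2))
    T[~is1] = T2[~is1]
    return T, E


def generate_trial(config: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic trial and its potential-outcome truth table."""
    cfg = config
    if not -1.0 <= cfg.rho_true <= 1.0:
        raise ValueError("rho_true must be in [-1, 1]")
    n = 2 * cfg.n_per_arm
    X = _draw_covariates(cfg, n, substream(cfg.seed, "covariates"))

    # latent standardized residual pairs with correlation rho_true
    rng_r = substream(cfg.seed, "residuals")
    z1 = rng_r.standard_normal(n)
    z_ind = rng_r.standard_normal(n)
    z0 = cfg.rho_true * z1 + np.sqrt(max(1.0 - cfg.rho_true**2, 0.0)) * z_ind

    # residual marginals scaled so total SD(W) hits the target
    def _resid_params(shape, slopes):
        lin = np.zeros(n)
        for c, b in slopes.items():
            lin += b * X[c].to_numpy()
        lin_var = float(np.var(lin))
        resid_sd = float(np.sqrt(max(cfg.sd_w**2 - lin_var, 1.0)))
        return standardized_su(shape[0], shape[1], mean=0.0, sd=resid_sd), lin

    su0, lin0 = _resid_params(cfg.resid_shape0, cfg.slopes0)
    su1, lin1 = _resid_params(cfg.resid_shape1, cfg.slopes1)

    def _from_score(p: JohnsonSUParams, z):
        return p.xi + p.lam * np.sinh((z - p.gamma) / p.delta)

    r0 = _from_score(su0, z0)
    r1 = _from_score(su1, z1)
    w0 = (cfg.mean_w0 - np.mean(lin0)) + lin0 + r0
    w1 = (cfg.mean_w1 - np.mean(lin1)) + lin1 + r1

    frailty = np.zeros(n)
    if cfg.violate_no_confounding:
        frailty = substream(cfg.seed, "frailty").standard_normal(n) * cfg.frailty_sd
        w1 = w1 + frailty  # frailty shifts the acute effect under treatment

    T0, E0 = _draw_events(cfg, w0, X, 0, frailty, substream(cfg.seed, "events0"))
    T1, E1 = _draw_events(cfg, w1, X, 1, frailty, substream(cfg.seed, "events1"))

    rng_a = substream(cfg.seed, "assignment")
    arm = np.zeros(n, dtype=int)
    arm[rng_a.permutation(n)[: cfg.n_per_arm]] = 1

    rng_c = substream(cfg.seed, "censoring")
    C = np.minimum(cfg.admin_horizon,
                   rng_c.exponential(1.0 / max(cfg.censor_rate, 1e-12), size=n))

    T_obs = np.where(arm == 1, T1, T0)
    E_pot = np.where(arm == 1, E1, E0)
    Y = np.minimum(T_obs, C)
    observed = T_obs <= C
    E_obs = np.where(observed, E_pot, 0)
    W_obs = np.where(arm == 1, w1, w0)

    truth = pd.DataFrame({
        "subject_id": np.arange(n),
        "W0": w0, "W1": w1, "eps0": z0, "eps1": z1,
        "T0": T0, "E0": E0, "T1": T1, "E1": E1,
        "arm": arm, "censor_time": C,
    })
    truth = pd.concat([truth, X], axis=1)

    dataset = pd.DataFrame({
        "subject_id": np.arange(n),
        "trial": cfg.trial,
        "arm": arm,
        "time_years": np.maximum(Y, 1e-6),
        "event_type": E_obs,
        "delta_egfr_pct": W_obs,
    })
    dataset = pd.concat([dataset, X], axis=1)[DATASET_COLUMNS]
    return dataset, SyntheticTruth(table=truth, config=cfg,
                                   residual0=su0, residual1=su1)


def generate_competing_risks(
    n: int, coef: float, seed: int, *, p_base: float = 0.35, tau: float = 1.0,
    rate2: float = 0.25, censor_rate: float = 0.20, admin_horizon: float = 3.0,
    no_competing: bool = False,
) -> pd.DataFrame:
    """Minimal one-covariate competing-risks dataset from the same
    subdistribution mixture; the true Fine-Gray coefficient of ``x`` is
    ``coef`` exactly.  Used for estimator parameter-recovery checks."""
    rng = substream(seed, "fg-toy")
    x = rng.standard_normal(n)
    elp = np.exp(coef * x)
    u = rng.random(n)
    is1 = u < 1.0 - (1.0 - p_base) ** elp
    T = np.empty(n)
    E = np.where(is1, 1, 2)
    inner = (1.0 - (1.0 - u[is1]) ** (1.0 / elp[is1])) / p_base
    T[is1] = -tau * np.log1p(-np.clip(inner, 0.0, 1.0 - 1e-12))
    T[~is1] = rng.exponential(1.0 / rate2, size=(~is1).sum())
    if no_competing:
        # administratively censor would-be competing events instead
        E[~is1] = 0
        T[~is1] = admin_horizon
    C = np.minimum(admin_horizon, rng.exponential(1.0 / censor_rate, size=n))
    Y = np.minimum(T, C)
    E_obs = np.where(T <= C, E, 0)
    return pd.DataFrame({"time_years": Y, "event_type": E_obs, "x": x})


def true_cate(
    truth: SyntheticTruth, w1: float, k: float, endpoint: str = "primary",
    bandwidth: float = 1.0,
) -> tuple[float, float]:
    """Monte-Carlo oracle risk reduction at W(1) ~= w1, horizon k.

    Uses both arms' potential outcomes of subjects with |W(1) - w1| <
    bandwidth; no censoring or identification assumptions involved.
    Returns (risk reduction, Monte-Carlo SE).
    """
    tb = truth.table
    band = tb[np.abs(tb["W1"].to_numpy() - w1) < bandwidth]
    if len(band) < 500:
        raise ValueError(
            f"only {len(band)} truth rows within {bandwidth} of w1={w1}; "
            "increase n or bandwidth"
        )
    if endpoint == "primary":
        i1 = (band["T1"] <= k) & (band["E1"] == 1)
        i0 = (band["T0"] <= k) & (band["E0"] == 1)
    elif endpoint == "competing":
        i1 = (band["T1"] <= k) & (band["E1"] == 2)
        i0 = (band["T0"] <= k) & (band["E0"] == 2)
    elif endpoint == "composite":
        i1 = band["T1"] <= k
        i0 = band["T0"] <= k
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    diff = i0.to_numpy(dtype=float) - i1.to_numpy(dtype=float)
    return float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(len(diff)))
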