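"""Conditional-average-treatment-effect estimation across the w1 grid.

Given trial data, the estimator answers: among patients whose acute
biomarker change under treatment equals w1, what is the treatment's effect
on the absolute risk of the clinical endpoint by horizon k, as a function
of the unidentifiable cross-world residual correlation rho_eps?

Pipeline per trial:

1. regress the acute change on baseline covariates in each arm (OLS),
   fit Johnson SU laws to the residuals;
2. fit the arm-specific outcome models (Fine-Gray per cause, Cox for the
   composite) with a restricted-cubic-spline biomarker term;
3. for each grid value w1: draw covariate profiles from f(x | w1) by SIR,
   evaluate the treated-arm risk directly at (w1, x), and the control-arm
   risk by mapping w1 to the latent residual scale, drawing the control
   residual from the conditional normal with correlation rho_eps, and
   mapping back through the control residual quantile function;
4. report the risk reduction (control minus treated risk) with bootstrap
   percentile confidence intervals, pooling trials by relative sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr, ndtri

from ._seeding import child_seed, substream
from .distributions import JohnsonSUParams, fit_johnson_su, normal_score
from .hazard import DesignSpec, HazardFit, default_knots, fit_cox, fit_fine_gray, predict_risk_many
from .sir import SIRConfig, sir_sample

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "COVARIATE_COLS",
    "BiomarkerModel",
    "CATEResult",
    "prepare_dataset",
    "fit_biomarker_regressions",
    "estimate_cate",
    "estimate_cate_pooled",
    "pool_trials",
    "interaction_contrast",
    "bootstrap_cis",
]

REQUIRED_COLUMNS = [
    "subject_id", "trial", "arm", "time_years", "event_type",
    "delta_egfr_pct", "egfr0", "log_upcr", "age", "sbp", "female", "diabetes",
]
COVARIATE_COLS = ("egfr0", "log_upcr", "age", "sbp", "female", "diabetes")

ENDPOINTS = ("primary", "competing", "composite")


@dataclass
class BiomarkerModel:
    """Arm-specific acute-change regressions plus residual marginals."""

    beta0: pd.Series
    beta1: pd.Series
    resid0: np.ndarray
    resid1: np.ndarray
    fr0: JohnsonSUParams
    fr1: JohnsonSUParams
    sd0: float
    sd1: float
    residual_cdf: str = "parametric"  # or "empirical"

    def _sorted(self, arm: int) -> np.ndarray:
        r = self.resid1 if arm else self.resid0
        return np.sort(r)

    def score_resid1(self, r: np.ndarray) -> np.ndarray:
        """epsilon_1 = Phi^-1(F_r(1)(r)) for treated-arm residuals."""
        if self.residual_cdf == "parametric":
            return normal_score(self.fr1, r)
        s = self._sorted(1)
        n = s.size
        p = np.clip((np.searchsorted(s, r, side="right") - 0.5) / n,
                    0.5 / n, 1 - 0.5 / n)
        return ndtri(p)

    def inv_score_resid0(self, eps: np.ndarray) -> np.ndarray:
        """r_0 = F_r(0)^-1(Phi(epsilon)) for control-arm residuals."""
        if self.residual_cdf == "parametric":
            p = self.fr0
            # keep sinh finite even for degenerate fits with tiny delta;
            # downstream risks saturate long before this bound matters
            return p.xi + p.lam * np.sinh(
                np.clip((eps - p.gamma) / p.delta, -700.0, 700.0))
        s = self._sorted(0)
        q = ndtr(eps)
        return np.quantile(s, np.clip(q, 0.0, 1.0))


@dataclass
class CATEResult:
    """Risk-reduction curve over the w1 grid at one rho_eps and horizon."""

    endpoint: str
    horizon: float
    rho_eps: float
    grid: np.ndarray
    estimate: np.ndarray              # risk reduction: control - treated
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None
    per_trial: Optional[dict] = None
    weights: Optional[dict] = None
    n: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def raw_delta(self) -> np.ndarray:
        """Treated-minus-control risk difference (the unflipped estimand)."""
        return -self.estimate

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "endpoint": self.endpoint, "rho_eps": self.rho_eps,
            "w1": self.grid, "estimate": self.estimate,
        })
        if self.ci_lower is not None:
            df["ci_lower"] = self.ci_lower
            df["ci_upper"] = self.ci_upper
        df["n_pooled"] = self.n
        return df


def prepare_dataset(
    raw: pd.DataFrame, trim_quantiles: Optional[tuple[float, float]] = (0.005, 0.995),
) -> tuple[pd.DataFrame, dict]:
    """Validate, drop incomplete rows, trim extreme acute changes.

    Trimming bounds are the pooled quantiles of the acute change across all
    rows (both arms, all trials); returns the clean dataset and a count log.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    df = raw.copy()
    n_input = len(df)
    df = df.dropna(subset=REQUIRED_COLUMNS)
    n_complete = len(df)
    n_trimmed = 0
    if trim_quantiles is not None and n_complete:
        lo, hi = np.quantile(df["delta_egfr_pct"].to_numpy(dtype=float),
                             list(trim_quantiles))
        keep = (df["delta_egfr_pct"] >= lo) & (df["delta_egfr_pct"] <= hi)
        n_trimmed = int((~keep).sum())
        df = df[keep]
    report = {
        "n_input": n_input,
        "n_dropped_missing": n_input - n_complete,
        "n_trimmed": n_trimmed,
        "n_final": len(df),
    }
    logger.info("prepare_dataset: %s", report)
    return df.reset_index(drop=True), report


def fit_biomarker_regressions(
    df: pd.DataFrame,
    covariate_cols: Sequence[str] = COVARIATE_COLS,
    residual_cdf: str = "parametric",
) -> BiomarkerModel:
    """OLS of the acute change on baseline covariates, separately per arm,
    with Johnson SU fits to each arm's residuals."""
    out = {}
    for arm in (0, 1):
        sub = df[df["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"no rows in arm {arm}")
        cols = [c for c in covariate_cols if sub[c].nunique() > 1]
        X = sm.add_constant(sub[cols].astype(float), has_constant="add")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError(
                f"collinear covariates in arm {arm} regression: {list(X.columns)}"
            )
        fit = sm.OLS(sub["delta_egfr_pct"].astype(float), X).fit()
        beta = fit.params.copy()
        for c in covariate_cols:  # dropped-constant columns get a 0 slope
            if c not in beta.index:
                beta[c] = 0.0
        resid = fit.resid.to_numpy()
        out[arm] = (beta, resid, float(np.std(resid, ddof=X.shape[1])))
    fr0 = fit_johnson_su(out[0][1])
    fr1 = fit_johnson_su(out[1][1])
    return BiomarkerModel(
        beta0=out[0][0], beta1=out[1][0],
        resid0=out[0][1], resid1=out[1][1],
        fr0=fr0, fr1=fr1, sd0=out[0][2], sd1=out[1][2],
        residual_cdf=residual_cdf,
    )


def _fit_outcome(df_arm: pd.DataFrame, endpoint: str, design: DesignSpec) -> HazardFit:
    if endpoint == "composite":
        return fit_cox(df_arm, design)
    event = 1 if endpoint == "primary" else 2
    return fit_fine_gray(df_arm, design, event_of_interest=event)


def _regression_mean(beta: pd.Series, X: pd.DataFrame) -> np.ndarray:
    m = np.full(len(X), float(beta.get("const", 0.0)))
    for c in X.columns:
        m += float(beta.get(c, 0.0)) * X[c].to_numpy(dtype=float)
    return m


def estimate_cate(
    df: pd.DataFrame,
    endpoint: str = "primary",
    k: float = 2.0,
    rho_eps: float = 0.8,
    w1_grid: Sequence[float] = tuple(range(-20, 21)),
    J: int = 100,
    sir_config: Optional[SIRConfig] = None,
    seed: int = 0,
    covariate_cols: Sequence[str] = COVARIATE_COLS,
    n_knots: Optional[int] = 4,
    residual_cdf: str = "parametric",
) -> CATEResult:
    """Run the full single-trial estimation at one rho_eps.

    ``covariate_cols`` may be empty, in which case the biomarker regressions
    are intercept-only and the covariate-mixing (SIR) step degenerates to
    a single empty profile.
    """
    if not -1.0 <= rho_eps <= 1.0:
        raise ValueError(f"rho_eps must be in [-1, 1], got {rho_eps}")
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    grid = np.asarray(list(w1_grid), dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("w1_grid must be strictly increasing")

    covariate_cols = tuple(covariate_cols)
    w_all = df["delta_egfr_pct"].to_numpy(dtype=float)
    w_lo, w_hi = w_all.min(), w_all.max()
    if grid.min() < w_lo or grid.max() > w_hi:
        logger.warning("grid extends beyond observed acute-change support "
                       "[%.1f, %.1f]; extrapolating", w_lo, w_hi)

    bm = fit_biomarker_regressions(df, covariate_cols, residual_cdf=residual_cdf)

    spline = default_knots(w_all, n_knots) if n_knots else None
    design = DesignSpec(spline=spline, covariate_cols=covariate_cols)
    treated = df[df["arm"] == 1]
    control = df[df["arm"] == 0]
    fit1 = _fit_outcome(treated, endpoint, design)
    fit0 = _fit_outcome(control, endpoint, design)

    if sir_config is None:
        sir_config = SIRConfig(n_proposal=10 * len(treated), n_resample=1000,
                               seed=child_seed(seed, "sir-default"))

    estimates = np.empty(grid.size)
    ess_log = []
    for gi, w1 in enumerate(grid):
        if covariate_cols:
            sir = sir_sample(
                treated[list(covariate_cols)], float(w1), bm.beta1, bm.sd1,
                replace(sir_config, seed=child_seed(seed, "sir", gi)),
            )
            Xhat = sir.samples
            ess_log.append(sir.effective_sample_size)
        else:
            Xhat = pd.DataFrame(index=[0])

        Xc1 = Xhat[list(fit1.covariate_cols)].to_numpy(dtype=float) \
            if fit1.covariate_cols else np.empty((len(Xhat), 0))
        risk1 = predict_risk_many(fit1, np.full(len(Xhat), w1), Xc1, k)

        # control side: latent-scale transfer of w1 through the copula
        r1 = w1 - _regression_mean(bm.beta1, Xhat[list(covariate_cols)]) \
            if covariate_cols else np.array([w1 - float(bm.beta1.get("const", 0.0))])
        eps1 = bm.score_resid1(np.asarray(r1, dtype=float))
        rng = substream(seed, "copula-draws", gi)
        if abs(rho_eps) >= 1.0:
            eps0 = np.sign(rho_eps) * eps1[:, None] * np.ones((1, J))
        else:
            eps0 = rho_eps * eps1[:, None] + np.sqrt(1 - rho_eps**2) * \
                rng.standard_normal((eps1.size, J))
        r0 = bm.inv_score_resid0(eps0.ravel())
        mu0 = _regression_mean(bm.beta0, Xhat[list(covariate_cols)]) \
            if covariate_cols else np.array([float(bm.beta0.get("const", 0.0))])
        w0 = np.repeat(mu0, J) + r0
        Xc0 = Xhat[list(fit0.covariate_cols)].to_numpy(dtype=float) \
            if fit0.covariate_cols else np.empty((len(Xhat), 0))
        risk0 = predict_risk_many(fit0, w0, np.repeat(Xc0, J, axis=0), k)

        estimates[gi] = float(np.mean(risk0) - np.mean(risk1))

    return CATEResult(
        endpoint=endpoint, horizon=k, rho_eps=rho_eps, grid=grid,
        estimate=estimates, n=len(df),
        diagnostics={
            "sir_ess_min": float(min(ess_log)) if ess_log else None,
            "fit1_meta": fit1.fit_meta, "fit0_meta": fit0.fit_meta,
            "biomarker_sd": (bm.sd0, bm.sd1),
        },
    )


def pool_trials(per_trial: Sequence[CATEResult]) -> CATEResult:
    """Sample-size-weighted pointwise average across trials."""
    if not per_trial:
        raise ValueError("no results to pool")
    ref = per_trial[0]
    for r in per_trial[1:]:
        if not np.array_equal(r.grid, ref.grid):
            raise ValueError("grid mismatch across trials")
        if (r.endpoint, r.horizon, r.rho_eps) != (ref.endpoint, ref.horizon, ref.rho_eps):
            raise ValueError("endpoint/horizon/rho mismatch across trials")
    ns = np.array([r.n for r in per_trial], dtype=float)
    w = ns / ns.sum()
    est = np.sum([wi * r.estimate for wi, r in zip(w, per_trial)], axis=0)
    return CATEResult(
        endpoint=ref.endpoint, horizon=ref.horizon, rho_eps=ref.rho_eps,
        grid=ref.grid.copy(), estimate=est, n=int(ns.sum()),
        per_trial={i: r.estimate for i, r in enumerate(per_trial)},
        weights={i: float(wi) for i, wi in enumerate(w)},
    )


def estimate_cate_pooled(df: pd.DataFrame, **kwargs) -> CATEResult:
    """Per-trial estimation followed by relative-sample-size pooling."""
    results = []
    seed = kwargs.pop("seed", 0)
    for t, (trial, sub) in enumerate(df.groupby("trial", sort=True)):
        results.append(estimate_cate(sub.reset_index(drop=True),
                                     seed=child_seed(seed, "trial", t), **kwargs))
    return pool_trials(results) if len(results) > 1 else results[0]


def interaction_contrast(result: CATEResult,
                         replicates: Optional[np.ndarray] = None) -> CATEResult:
    """Effect-modification curve: estimate(w1) minus estimate at w1 = 0.

    If 0 is not on the grid the nearest grid point is used (logged).  When
    bootstrap ``replicates`` (B x grid) are supplied, percentile CIs are
    computed on the within-replicate contrast.
    """
    idx = int(np.argmin(np.abs(result.grid)))
    if result.grid[idx] != 0:
        logger.info("grid has no 0; using nearest point %.3g", result.grid[idx])
    contrast = result.estimate - result.estimate[idx]
    lo = hi = None
    if replicates is not None:
        rc = replicates - replicates[:, [idx]]
        lo = np.quantile(rc, 0.025, axis=0, method="lower")
        hi = np.quantile(rc, 0.975, axis=0, method="higher")
    return CATEResult(
        endpoint=result.endpoint, horizon=result.horizon, rho_eps=result.rho_eps,
        grid=result.grid.copy(), estimate=contrast, ci_lower=lo, ci_upper=hi,
        n=result.n, diagnostics={"contrast_reference": float(result.grid[idx])},
    )


def _resample(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    parts = []
    for _, sub in df.groupby(["trial", "arm"], sort=True):
        idx = rng.integers(0, len(sub), size=len(sub))
        parts.append(sub.iloc[idx])
    return pd.concat(parts, ignore_index=True)


def bootstrap_cis(
    df: pd.DataFrame, B: int = 1000, seed: int = 0, max_failure_rate: float = 0.05,
    **estimate_kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Percentile bootstrap of the whole pipeline.

    Subjects are resampled with replacement within trial x arm strata; the
    full estimation (regressions, marginals, outcome fits, SIR, copula
    draws, pooling) is rerun per replicate.  Returns (lower, upper,
    replicate matrix, number of failed replicates); replicates whose fits
    fail are dropped and counted, erroring out past ``max_failure_rate``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    curves, n_failed = [], 0
    for b in range(B):
        rng = substream(seed, "bootstrap", b)
        try:
            res = estimate_cate_pooled(_resample(df, rng),
                                       seed=child_seed(seed, "boot-est", b),
                                       **estimate_kwargs)
            curves.append(res.estimate)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > max_failure_rate * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    mat = np.asarray(curves)
    # outward-rounding empirical percentiles: min/max at tiny B
    lower = np.quantile(mat, 0.025, axis=0, method="lower")
    upper = np.quantile(mat, 0.975, axis=0, method="higher")
    return lower, upper, mat, n_failed
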