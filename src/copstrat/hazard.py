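"""Time-to-event models for absolute-risk prediction.

Two regression models back the conditional risks in the estimator:

* a Cox proportional-hazards model for the composite endpoint, and
* a Fine-Gray subdistribution-hazard model for each competing endpoint,
  fitted by the weighted estimating-equation approach in which subjects
  failing from the competing cause stay in the risk set with
  inverse-probability-of-censoring weights from a product-limit estimate
  of the censoring distribution.

Both share one weighted Newton core (Breslow tie handling) and a Breslow
baseline cumulative (sub)hazard, so fitted models can be turned into
absolute risks Pr[T <= k, E = e | W, X] = 1 - exp(-Lambda0(k) * exp(lp)).

The biomarker enters through a restricted cubic (natural) spline basis,
linear beyond the boundary knots, with knots at the conventional default
quantiles for the chosen number of knots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SplineSpec",
    "DesignSpec",
    "HazardFit",
    "HazardFitError",
    "make_spline_basis",
    "default_knots",
    "fit_cox",
    "fit_fine_gray",
    "predict_risk",
    "predict_risk_many",
]

# default knot quantiles, indexed by number of knots (Harrell's rcs defaults)
_DEFAULT_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


class HazardFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class SplineSpec:
    """Restricted cubic spline with strictly increasing knots (>= 3)."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size < 3:
            raise ValueError("restricted cubic spline needs >= 3 knots")
        if not np.all(np.diff(k) > 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1


def default_knots(values: Sequence[float], n_knots: int = 4) -> SplineSpec:
    """Knots at the conventional default quantiles of the observed values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    qs = _DEFAULT_KNOT_QUANTILES.get(n_knots)
    if qs is None:
        qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(v, qs)
    if np.unique(knots).size < n_knots:
        raise HazardFitError(
            f"cannot place {n_knots} distinct knots: data too concentrated"
        )
    return SplineSpec(knots=tuple(float(k) for k in knots))


def make_spline_basis(values, spec: SplineSpec) -> np.ndarray:
    """Basis matrix with n_knots - 1 columns: the linear term plus the
    restricted cubic terms, each exactly linear beyond the boundary knots."""
    x = np.asarray(values, dtype=float).ravel()
    t = np.asarray(spec.knots, dtype=float)
    k = t.size
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        lam = (t[-1] - t[j]) / (t[-1] - t[-2])
        mu = (t[-2] - t[j]) / (t[-1] - t[-2])
        col = (
            np.clip(x - t[j], 0, None) ** 3
            - lam * np.clip(x - t[-2], 0, None) ** 3
            + mu * np.clip(x - t[-1], 0, None) ** 3
        ) / norm
        cols.append(col)
    return np.column_stack(cols)


@dataclass(frozen=True)
class DesignSpec:
    """Design of an outcome model: spline in the biomarker plus covariates.

    ``spline=None`` enters the biomarker linearly (one column).
    """

    spline: Optional[SplineSpec]
    covariate_cols: tuple[str, ...]
    biomarker_col: str = "delta_egfr_pct"
    time_col: str = "time_years"
    event_col: str = "event_type"


@dataclass
class HazardFit:
    """A fitted Cox or Fine-Gray model plus its Breslow baseline."""

    kind: str  # "cox_composite" | "fine_gray"
    event_of_interest: int
    design: DesignSpec
    covariate_cols: tuple[str, ...]  # after dropping degenerate columns
    coef: np.ndarray
    col_means: np.ndarray  # design centered here; baseline refers to the centroid
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    fit_meta: dict = field(default_factory=dict)

    def linear_predictor(self, w, X_cov: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if self.design.spline is None:
            wb = w.reshape(-1, 1)
        else:
            # the basis is linear beyond the boundary knots, so clipping far
            # outside the knot span only stops cubed overflow, not shape
            t = self.design.spline.knots
            span = t[-1] - t[0]
            w = np.clip(w, t[0] - 50.0 * span, t[-1] + 50.0 * span)
            wb = make_spline_basis(w, self.design.spline)
        M = np.column_stack([wb, np.asarray(X_cov, dtype=float)]) - self.col_means
        return M @ self.coef

    def cumhaz_at(self, k: float) -> float:
        if k <= 0:
            return 0.0
        idx = np.searchsorted(self.baseline_times, k, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.baseline_cumhaz[idx])


def _design_matrix(df: pd.DataFrame, design: DesignSpec):
    w = df[design.biomarker_col].to_numpy(dtype=float)
    wb = w.reshape(-1, 1) if design.spline is None else make_spline_basis(w, design.spline)
    keep, X_cols = [], []
    for c in design.covariate_cols:
        col = df[c].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            logger.warning("covariate %r is constant; dropped from the fit", c)
            continue
        keep.append(c)
        X_cols.append(col)
    X_cov = np.column_stack(X_cols) if X_cols else np.empty((len(df), 0))
    M = np.column_stack([wb, X_cov])
    return M, tuple(keep)


def _censoring_survival(time: np.ndarray, any_event: np.ndarray):
    """Product-limit estimate of the censoring survival G(t) (left-continuous
    evaluation provided via searchsorted on the returned step function)."""
    order = np.argsort(time, kind="mergesort")
    t, cens = time[order], (~any_event[order].astype(bool))
    uniq = np.unique(t[cens])
    n = t.size
    # number at risk just before each censoring time; censorings at that time
    at_risk = n - np.searchsorted(t, uniq, side="left")
    d = np.array([np.sum(cens & (t == u)) for u in uniq], dtype=float)
    surv = np.cumprod(1.0 - d / np.maximum(at_risk, 1))
    return uniq, surv


def _g_left(uniq: np.ndarray, surv: np.ndarray, times: np.ndarray) -> np.ndarray:
    """G(t-): censoring survival just before each requested time."""
    idx = np.searchsorted(uniq, times, side="left") - 1
    out = np.ones_like(times, dtype=float)
    ok = idx >= 0
    out[ok] = surv[idx[ok]]
    return out


def _newton_cox(M: np.ndarray, weight_matrix: np.ndarray, event_rows: np.ndarray,
                event_time_index: np.ndarray, n_events_at: np.ndarray,
                max_iter: int = 100, tol: float = 1e-6):
    """Weighted Cox partial-likelihood Newton solver, Breslow ties.

    weight_matrix[j, i] is the at-risk weight of subject i at the j-th
    distinct event time; event_rows are the indices of failing subjects and
    event_time_index their distinct-time slot.
    """
    n, p = M.shape
    beta = np.zeros(p)

    def negloglik_grad_hess(beta):
        lp = M @ beta
        lp -= lp.max()  # guard overflow; constants cancel in the ratios
        e = np.exp(lp)
        A = weight_matrix * e[None, :]
        S0 = A.sum(axis=1)  # (m,)
        S0 = np.maximum(S0, 1e-300)
        S1 = A @ M  # (m, p)
        E = S1 / S0[:, None]
        ll = float(lp[event_rows].sum() - (n_events_at * np.log(S0)).sum())
        grad = M[event_rows].sum(axis=0) - (n_events_at[:, None] * E).sum(axis=0)
        # Hessian of ll: -(sum_j d_j [S2_j/S0_j - E_j E_j^T])
        c = e * (weight_matrix.T @ (n_events_at / S0))  # (n,)
        H = -(M.T @ (c[:, None] * M)) + (E * n_events_at[:, None]).T @ E
        return -ll, -grad, -H

    nll, grad, hess = negloglik_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        gnorm = np.abs(grad).max() if grad.size else 0.0
        if gnorm < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            step = grad
        # Newton with step-halving
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            nll_new, grad_new, hess_new = negloglik_grad_hess(cand)
            if nll_new <= nll + 1e-12:
                beta, nll, grad, hess = cand, nll_new, grad_new, hess_new
                break
            scale *= 0.5
        else:
            break
    else:
        gnorm = np.abs(grad).max() if grad.size else 0.0
    if not converged and (np.abs(grad).max() if grad.size else 0.0) >= tol:
        raise HazardFitError(
            f"Newton did not converge: max |gradient| = {np.abs(grad).max():.3e}"
        )
    return beta, nll


def _fit_weighted(df: pd.DataFrame, design: DesignSpec, event_of_interest: int,
                  kind: str, fine_gray: bool) -> HazardFit:
    time = df[design.time_col].to_numpy(dtype=float)
    etype = df[design.event_col].to_numpy(dtype=int)
    if fine_gray:
        is_event = etype == event_of_interest
        is_compet = (etype != 0) & ~is_event
    else:
        is_event = etype != 0
        is_compet = np.zeros_like(is_event)
    n_events = int(is_event.sum())
    if n_events == 0:
        raise HazardFitError("no events of interest; cannot fit")

    M_raw, kept_cols = _design_matrix(df, design)
    col_means = M_raw.mean(axis=0)
    M = M_raw - col_means
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        raise HazardFitError("design matrix is rank deficient after centering")

    uniq_times = np.unique(time[is_event])
    m = uniq_times.size
    # at-risk weight matrix (m, n)
    Wm = (time[None, :] >= uniq_times[:, None]).astype(float)
    if fine_gray and is_compet.any():
        gt, gs = _censoring_survival(time, etype != 0)
        G_at_event = _g_left(gt, gs, uniq_times)  # G(t_j -)
        G_at_fail = _g_left(gt, gs, time)  # G(Y_i -)
        past_compet = is_compet[None, :] & (time[None, :] < uniq_times[:, None])
        ratio = G_at_event[:, None] / np.maximum(G_at_fail[None, :], 1e-300)
        Wm = np.where(past_compet, np.minimum(ratio, 1.0), Wm)

    event_rows = np.where(is_event)[0]
    event_time_index = np.searchsorted(uniq_times, time[event_rows])
    n_events_at = np.bincount(event_time_index, minlength=m).astype(float)

    beta, nll = _newton_cox(M, Wm, event_rows, event_time_index, n_events_at)

    # Breslow baseline cumulative (sub)hazard at the centered design
    lp = M @ beta
    lp_max = lp.max()
    S0_shifted = (Wm * np.exp(lp - lp_max)[None, :]).sum(axis=1)
    cumhaz = np.cumsum(
        n_events_at / np.maximum(S0_shifted, 1e-300) * np.exp(-lp_max))

    return HazardFit(
        kind=kind,
        event_of_interest=event_of_interest,
        design=design,
        covariate_cols=kept_cols,
        coef=beta,
        col_means=col_means,
        baseline_times=uniq_times,
        baseline_cumhaz=cumhaz,
        fit_meta={
            "n": len(df),
            "n_events": n_events,
            "n_competing": int(is_compet.sum()),
            "neg_log_partial_lik": float(nll),
            "dropped_covariates": tuple(
                c for c in design.covariate_cols if c not in kept_cols
            ),
        },
    )


def fit_cox(df: pd.DataFrame, design: DesignSpec) -> HazardFit:
    """Cox PH fit for the composite endpoint (any event), Breslow ties."""
    return _fit_weighted(df, design, event_of_interest=0, kind="cox_composite",
                         fine_gray=False)


def fit_fine_gray(df: pd.DataFrame, design: DesignSpec,
                  event_of_interest: int = 1) -> HazardFit:
    """Fine-Gray subdistribution-hazard fit for one cause.

    With no competing events present the weighted risk sets coincide with
    ordinary Cox risk sets and the fit reduces to Cox exactly (a notice is
    logged).
    """
    etype = df[design.event_col].to_numpy(dtype=int)
    n_compet = int(((etype != 0) & (etype != event_of_interest)).sum())
    if n_compet == 0:
        logger.info("no competing events present; Fine-Gray reduces to Cox")
    return _fit_weighted(df, design, event_of_interest=event_of_interest,
                         kind="fine_gray", fine_gray=True)


def predict_risk_many(fit: HazardFit, w, X_cov, k: float) -> np.ndarray:
    """Vectorized absolute risk Pr[T <= k, E = e | w, x] for rows of (w, x)."""
    if fit.baseline_times.size and k > fit.baseline_times[-1]:
        logger.warning(
            "horizon %.3g beyond last event time %.3g; risk held at the last "
            "event time", k, fit.baseline_times[-1],
        )
        k = float(fit.baseline_times[-1])
    H0 = fit.cumhaz_at(k)
    lp = fit.linear_predictor(np.atleast_1d(w), np.atleast_2d(X_cov))
    # extreme extrapolated predictors saturate at risk 1; cap before exp
    return -np.expm1(-H0 * np.exp(np.minimum(lp, 500.0)))


def predict_risk(fit: HazardFit, w: float, x, k: float) -> float:
    """Absolute risk at horizon k for a single subject profile."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return float(predict_risk_many(fit, np.array([w]), x, k)[0])
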