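"""Sampling-Importance-Resampling for the conditional covariate law f(x | w1).

The estimator needs covariate profiles distributed as the baseline
covariates of treated subjects whose acute change equals w1.  Rather than
regress a mixed continuous/binary covariate vector on w1, we propose from
an estimate of the unconditional covariate law f(x) — a multivariate
normal per stratum of the dichotomous covariates, strata drawn with their
empirical frequencies — and importance-weight each proposal by the
likelihood f_hat(w1 | x): the normal density of w1 at the fitted
regression mean X*beta(1) with the homoscedastic residual SD.  Since the
proposal already targets f(x), the f(x) factor cancels from the weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeding import substream

logger = logging.getLogger(__name__)

__all__ = ["SIRConfig", "SIRResult", "sir_sample"]

_MIN_STRATUM = 5


@dataclass(frozen=True)
class SIRConfig:
    n_proposal: int = 10000
    n_resample: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proposal < 1 or self.n_resample < 1:
            raise ValueError("counts must be >= 1")
        if self.n_resample > self.n_proposal:
            raise ValueError("n_resample must not exceed n_proposal")


@dataclass
class SIRResult:
    samples: pd.DataFrame          # n_resample rows of covariates
    effective_sample_size: float   # 1 / sum(normalized weights^2)
    proposals: pd.DataFrame
    weights: np.ndarray            # normalized proposal weights


def _strata(df: pd.DataFrame, binary_cols: list[str]) -> pd.Series:
    if not binary_cols:
        return pd.Series(0, index=df.index)
    codes = df[binary_cols].astype(int)
    key = codes.iloc[:, 0].astype(int)
    for c in binary_cols[1:]:
        key = key * 2 + codes[c].astype(int)
    return key


def _merge_small_strata(labels: pd.Series) -> pd.Series:
    """Fold strata with < _MIN_STRATUM rows into the nearest (largest) one."""
    counts = labels.value_counts()
    small = counts[counts < _MIN_STRATUM].index
    if len(small) == 0:
        return labels
    big = counts.idxmax()
    logger.warning(
        "%d stratum/strata with < %d rows merged into the modal stratum",
        len(small), _MIN_STRATUM,
    )
    return labels.where(~labels.isin(small), big)


def sir_sample(
    covariates: pd.DataFrame,
    w1: float,
    beta1: pd.Series,
    residual_sd: float,
    config: SIRConfig,
    binary_cols: tuple[str, ...] = ("female", "diabetes"),
) -> SIRResult:
    """Approximate draws from f(x | W(1) = w1) by SIR.

    ``covariates`` are the treated-arm baseline covariate rows; ``beta1``
    the fitted coefficients (indexed by column name, with 'const') of the
    treated-arm acute-change regression; ``residual_sd`` its residual SD.
    """
    if residual_sd <= 0:
        raise ValueError("residual_sd must be positive")
    rng = substream(config.seed, "sir", int(round(w1 * 1e6)))

    cols = list(covariates.columns)
    bin_cols = [c for c in binary_cols if c in cols]
    cont_cols = [c for c in cols if c not in bin_cols]

    labels = _merge_small_strata(_strata(covariates, bin_cols))
    uniq, counts = np.unique(labels.to_numpy(), return_counts=True)
    probs = counts / counts.sum()
    n_per = rng.multinomial(config.n_proposal, probs)

    pieces = []
    for lab, n_s in zip(uniq, n_per):
        if n_s == 0:
            continue
        sub = covariates.loc[labels == lab]
        block = pd.DataFrame(index=range(n_s), columns=cols, dtype=float)
        for c in bin_cols:
            vals = sub[c].to_numpy(dtype=float)
            # constant within a stratum by construction; mixed only after a
            # small-stratum merge, in which case resample empirically
            block[c] = vals[0] if np.unique(vals).size == 1 else rng.choice(vals, size=n_s)
        if cont_cols:
            mu = sub[cont_cols].mean().to_numpy()
            cov = np.cov(sub[cont_cols].to_numpy(dtype=float), rowvar=False)
            cov = np.atleast_2d(cov) + 1e-10 * np.eye(len(cont_cols))
            block[cont_cols] = rng.multivariate_normal(mu, cov, size=n_s,
                                                       method="cholesky")
        pieces.append(block)
    proposals = pd.concat(pieces, ignore_index=True)

    # importance weight: f_hat(w1 | x), normal around the regression mean
    design = proposals.copy()
    design.insert(0, "const", 1.0)
    mean_w1 = design[beta1.index].to_numpy(dtype=float) @ beta1.to_numpy(dtype=float)
    logw = stats.norm.logpdf(w1, loc=mean_w1, scale=residual_sd)
    if not np.isfinite(logw.max()) or logw.max() < -700.0:  # underflows to 0
        raise ValueError(
            f"all SIR importance weights vanished at w1={w1}: outside the "
            "support of the fitted biomarker regression"
        )
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    w /= total
    ess = 1.0 / float(np.sum(w**2))
    idx = rng.choice(len(proposals), size=config.n_resample, replace=True, p=w)
    return SIRResult(
        samples=proposals.iloc[idx].reset_index(drop=True),
        effective_sample_size=ess,
        proposals=proposals,
        weights=w,
    )
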