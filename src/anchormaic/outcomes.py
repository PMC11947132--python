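"""Weighted outcome models on the IPD trial.

Continuous endpoints use a weighted analysis of covariance: change score
regressed on a treatment indicator, study-center fixed effects, and baseline
OFF time. With no treatment-by-center interaction the treatment coefficient
equals the least-squares-mean difference between arms, which is what the
comparator publications report. Standard errors come from a
heteroskedasticity-robust sandwich that treats the estimated weights as
fixed; a patient-level bootstrap that re-estimates the weights per resample
is available as a cross-check.

Binary safety endpoints are contrasted via a weighted 2×2 table of
effective counts (sums of weights by arm × event status), rescaled so the
four cells sum to the effective sample size before the usual
1/a + 1/b + 1/c + 1/d log-odds variance — raw weight sums would overstate
precision. A Haldane–Anscombe +0.5 is applied to every cell when any cell
is empty, and flagged.
"""
from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import AgDSummary, ArmContrast
from .exceptions import MAICError
from .weights import center_covariates, effective_sample_size, estimate_weights

logger = logging.getLogger(__name__)

DEFAULT_ADJUSTERS = ("treatment", "center", "off_baseline")


def _design(ipd: pd.DataFrame, adjusters: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    n = len(ipd)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if "treatment" not in adjusters:
        raise MAICError("the treatment indicator must be among the adjusters")
    cols.append((ipd["arm"] == "active").to_numpy(float))
    names.append("treatment")
    if "center" in adjusters:
        levels = sorted(pd.unique(ipd["center"]))
        for lev in levels[1:]:  # reference = first level
            cols.append((ipd["center"] == lev).to_numpy(float))
            names.append(f"center[{lev}]")
    if "off_baseline" in adjusters:
        cols.append(ipd["off_baseline"].to_numpy(float))
        names.append("off_baseline")
    return np.column_stack(cols), names


def weighted_ancova(
    ipd: pd.DataFrame,
    weights: Optional[np.ndarray],
    endpoint: str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    source: str = "ipd_weighted",
) -> ArmContrast:
    """Weighted least-squares ANCOVA contrast of active vs anchor.

    ``weights=None`` means unit weights, under which the fit coincides with
    ordinary ANCOVA coefficient-for-coefficient.
    """
    y = ipd[endpoint].to_numpy(float)
    w = np.ones(len(ipd)) if weights is None else np.asarray(weights, float)
    for a in ("active", "anchor"):
        if w[(ipd["arm"] == a).to_numpy()].sum() <= 0.0:
            raise MAICError(f"arm {a!r} has zero total weight (or is absent)")
    X, names = _design(ipd, adjusters)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate an aliased column via the QR diagonal
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        aliased = [names[j] for j in range(X.shape[1]) if r[j] < 1e-8 * r.max()]
        raise MAICError(f"design matrix is rank deficient; aliased term(s): {aliased}")
    fit = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    i = names.index("treatment")
    model_terms = [t for t in names if t != "intercept"] if source == "ipd_weighted" else []
    return ArmContrast(
        endpoint=endpoint,
        scale="difference",
        estimate=float(fit.params[i]),
        se=float(fit.bse[i]),
        source=source,  # type: ignore[arg-type]
        n_or_ess=effective_sample_size(w),
        model_terms=model_terms,
    )


def weighted_logodds(
    ipd: pd.DataFrame,
    weights: Optional[np.ndarray],
    event_flag: str,
    source: str = "ipd_weighted",
) -> ArmContrast:
    """Active-vs-anchor log-odds ratio from ESS-scaled effective counts."""
    flags = ipd[event_flag].to_numpy(float)
    if set(np.unique(flags)) - {0.0, 1.0}:
        raise MAICError(f"safety flag {event_flag!r} must be 0/1")
    w = np.ones(len(ipd)) if weights is None else np.asarray(weights, float)
    active = (ipd["arm"] == "active").to_numpy()
    anchor = (ipd["arm"] == "anchor").to_numpy()
    if w[active].sum() <= 0.0 or w[anchor].sum() <= 0.0:
        raise MAICError("both arms need positive total weight")
    a = w[active & (flags == 1)].sum()
    b = w[active & (flags == 0)].sum()
    c = w[anchor & (flags == 1)].sum()
    d = w[anchor & (flags == 0)].sum()
    ess = effective_sample_size(w)
    scale = ess / w.sum()
    cells = np.array([a, b, c, d]) * scale
    terms = ["effective_counts"]
    if (cells == 0.0).any():
        cells = cells + 0.5
        terms.append("haldane_anscombe_0.5")
    a, b, c, d = cells
    est = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ArmContrast(
        endpoint=event_flag,
        scale="log_odds",
        estimate=est,
        se=se,
        source=source,  # type: ignore[arg-type]
        n_or_ess=ess,
        model_terms=terms if source == "ipd_weighted" else [],
    )


def bootstrap_ancova_se(
    ipd: pd.DataFrame,
    agd: AgDSummary,
    covariate_names: Sequence[str],
    endpoint: str,
    adjusters: Sequence[str] = DEFAULT_ADJUSTERS,
    n_resamples: int = 1000,
    seed: int = 0,
) -> float:
    """Patient-level bootstrap SE that re-estimates weights per resample."""
    if n_resamples < 100:
        raise MAICError("use at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n = len(ipd)
    estimates: list[float] = []
    failures = 0
    while len(estimates) < n_resamples:
        idx = rng.integers(0, n, n)
        sample = ipd.iloc[idx].reset_index(drop=True)
        try:
            centered = center_covariates(sample, agd, covariate_names)
            ws = estimate_weights(centered, covariate_names)
            c = weighted_ancova(sample, ws.weights, endpoint, adjusters)
        except MAICError:
            failures += 1
            if failures > n_resamples:  # pathological input
                raise
            continue
        estimates.append(c.estimate)
    if failures:
        logger.info("bootstrap: %d resamples redrawn after model failure", failures)
    return float(np.std(np.asarray(estimates), ddof=1))
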