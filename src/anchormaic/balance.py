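"""Before/after-matching baseline comparison tables.

Continuous covariates are compared with a two-sample Wald (normal) test on
summary statistics; categorical covariates with a Pearson chi-square without
continuity correction, falling back to the Fisher exact test when any
expected cell count is below 5. After matching, the effective sample size
replaces the raw n in every test, since weighting inflates variance and the
raw n would overstate precision.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AgDSummary, BalanceRow
from .exceptions import MAICError
from .weights import effective_sample_size

EXPECTED_COUNT_CUTOFF = 5.0


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    sw = w.sum()
    if sw <= 0.0:
        raise MAICError("group has zero total weight")
    m = float((w * x).sum() / sw)
    ess = effective_sample_size(w)
    # Σw(x−x̄)²/Σw rescaled by ESS/(ESS−1): reduces to the ordinary
    # unbiased estimator under unit weights.
    var = float((w * (x - m) ** 2).sum() / sw)
    if ess > 1.0:
        var *= ess / (ess - 1.0)
    return m, math.sqrt(var), ess


def weighted_summary(
    ipd: pd.DataFrame,
    weights: Optional[np.ndarray],
    covariate: str,
    by_arm: bool = False,
) -> dict[str, tuple[float, float, float]]:
    """Weighted (mean-or-proportion, SD, ESS) pooled and, optionally, per arm."""
    x = ipd[covariate].to_numpy(float)
    w = np.ones(len(ipd)) if weights is None else np.asarray(weights, float)
    if (w < 0).any():
        raise MAICError("weights must be nonnegative")
    out = {"pooled": _weighted_mean_sd(x, w)}
    if by_arm:
        for a in ("active", "anchor"):
            mask = (ipd["arm"] == a).to_numpy()
            out[a] = _weighted_mean_sd(x[mask], w[mask])
    return out


def wald_two_sample(
    mean1: float, sd1: float, n1: float, mean2: float, sd2: float, n2: float
) -> tuple[float, float]:
    """Normal-theory Wald test on two summary means; n may be a non-integer ESS."""
    if n1 <= 0 or n2 <= 0:
        raise MAICError("group sizes must be positive")
    if sd1 <= 0 or sd2 <= 0:
        raise MAICError("standard deviations must be positive")
    z = (mean1 - mean2) / math.sqrt(sd1 * sd1 / n1 + sd2 * sd2 / n2)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def categorical_test(count_table) -> tuple[str, float, float]:
    """Dispatch a 2×k count table to chi-square or (2×2) Fisher exact.

    Pearson without continuity correction when all expected counts are ≥ 5;
    otherwise the two-sided Fisher exact test (summing tables with
    probability ≤ the observed one). Returns (test_name, statistic, p);
    Fisher's statistic is the sample odds ratio.
    """
    t = np.asarray(count_table, float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise MAICError("count table must be a 2-d array of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise MAICError("a zero margin makes the categorical test undefined")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected >= EXPECTED_COUNT_CUTOFF).all():
        stat, p, _, _ = stats.chi2_contingency(t, correction=False)
        return "chi_square", float(stat), float(p)
    if t.shape != (2, 2):
        raise MAICError(
            "Fisher exact test is only implemented for 2x2 tables "
            f"(got {t.shape} with an expected count < {EXPECTED_COUNT_CUTOFF})"
        )
    odds, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return "fisher", float(odds), float(p)


def _binary_row_test(
    p_ipd: float, n_ipd: float, p_agd: float, n_agd: float
) -> tuple[str, float, float]:
    """Reconstruct integer counts (round(p·n)) and run the categorical test."""
    k1 = int(round(p_ipd * n_ipd))
    k2 = int(round(p_agd * n_agd))
    n1 = int(round(n_ipd))
    n2 = int(round(n_agd))
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return categorical_test(table)


def balance_table(
    ipd: pd.DataFrame,
    weights_or_none: Optional[np.ndarray],
    targets: AgDSummary,
    covariate_list: Sequence[str],
) -> list[BalanceRow]:
    """One row per covariate comparing (weighted) pooled IPD against the AgD target."""
    rows: list[BalanceRow] = []
    for name in covariate_list:
        tgt = targets.target(name)
        summ = weighted_summary(ipd, weights_or_none, name, by_arm=True)
        (m_pool, sd_pool, ess_pool) = summ["pooled"]
        n_or_ess = {
            "active": summ["active"][2],
            "anchor": summ["anchor"][2],
            "pooled": ess_pool,
            "agd": float(targets.n_total),
        }
        if tgt.kind == "continuous":
            if tgt.sd is None:
                raise MAICError(
                    f"continuous target {name!r} needs an SD for the Wald test"
                )
            if abs(m_pool - tgt.value) < 1e-12:
                # matched exactly: the Wald statistic is 0 by construction
                stat, p, test = 0.0, 1.0, "wald"
            else:
                stat, p = wald_two_sample(
                    m_pool, sd_pool, ess_pool, tgt.value, tgt.sd, targets.n_total
                )
                test = "wald"
        else:
            test, stat, p = _binary_row_test(
                m_pool, ess_pool, tgt.value, targets.n_total
            )
        rows.append(
            BalanceRow(
                covariate=name,
                kind=tgt.kind,
                ipd_value={
                    "active": summ["active"][0],
                    "anchor": summ["anchor"][0],
                    "pooled": m_pool,
                },
                ipd_sd={
                    "active": summ["active"][1],
                    "anchor": summ["anchor"][1],
                    "pooled": sd_pool,
                },
                agd_value=tgt.value,
                agd_sd=tgt.sd,
                n_or_ess=n_or_ess,
                test_name=test,
                statistic=float(stat),
                p_value=float(p),
            )
        )
    return rows


def balance_frame(rows: list[BalanceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])
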