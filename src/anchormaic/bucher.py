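"""Anchored (Bucher) indirect comparison.

Two arm-vs-anchor contrasts estimated against the same anchor (placebo) are
combined by differencing the estimates and summing the variances on an
additive scale: mean differences directly, odds ratios on the log scale
with the point estimate and confidence limits exponentiated afterwards.
The normal quantile is fixed at 1.959964 and p-values are two-sided Wald.
Sign convention: active minus comparator, so a negative mean difference
favors the active (IPD-trial) treatment on lower-is-better endpoints.
"""
from __future__ import annotations

import logging
import math
from typing import Sequence, Union

from scipy import stats

from .containers import AgDSummary, ArmContrast, IndirectResult
from .exceptions import MAICError

logger = logging.getLogger(__name__)

Z_95 = 1.959964


def _combine(c_active: ArmContrast, c_comparator: ArmContrast, scale: str):
    if c_active.endpoint != c_comparator.endpoint:
        raise MAICError(
            f"endpoint mismatch: {c_active.endpoint!r} vs {c_comparator.endpoint!r}"
        )
    for c in (c_active, c_comparator):
        if c.scale != scale:
            raise MAICError(
                f"contrast for {c.endpoint!r} is on scale {c.scale!r}, expected {scale!r}"
            )
    est = c_active.estimate - c_comparator.estimate
    se = math.sqrt(c_active.se**2 + c_comparator.se**2)
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return est, se, z, p


def bucher_difference(
    c_active: ArmContrast, c_comparator: ArmContrast
) -> IndirectResult:
    """Combine two mean-difference contrasts into an anchored mean difference."""
    est, se, z, p = _combine(c_active, c_comparator, "difference")
    return IndirectResult(
        endpoint=c_active.endpoint,
        scale="difference",
        estimate=est,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        se_combined=se,
        z=z,
        p_value=p,
        components=(c_active, c_comparator),
    )


def bucher_ratio(c_active: ArmContrast, c_comparator: ArmContrast) -> IndirectResult:
    """Combine two log-odds contrasts; estimate and CI are exponentiated to ORs."""
    est, se, z, p = _combine(c_active, c_comparator, "log_odds")
    return IndirectResult(
        endpoint=c_active.endpoint,
        scale="odds_ratio",
        estimate=math.exp(est),
        ci_low=math.exp(est - Z_95 * se),
        ci_high=math.exp(est + Z_95 * se),
        se_combined=se,
        z=z,
        p_value=p,
        components=(c_active, c_comparator),
    )


def compare_all(
    ipd_contrasts: Sequence[ArmContrast],
    published: Union[AgDSummary, Sequence[ArmContrast]],
) -> list[IndirectResult]:
    """One indirect result per endpoint shared between the IPD contrasts and
    the published ones, in the order of the IPD list; unmatched endpoints are
    logged and skipped."""
    if isinstance(published, AgDSummary):
        pub = {c.endpoint: c for c in published.published_contrasts}
    else:
        pub = {c.endpoint: c for c in published}
    results: list[IndirectResult] = []
    for c in ipd_contrasts:
        mate = pub.get(c.endpoint)
        if mate is None:
            logger.info("endpoint %r skipped: no published contrast", c.endpoint)
            continue
        if c.scale != mate.scale:
            logger.info(
                "endpoint %r skipped: scale mismatch (%s vs %s)",
                c.endpoint, c.scale, mate.scale,
            )
            continue
        if c.scale == "difference":
            results.append(bucher_difference(c, mate))
        else:
            results.append(bucher_ratio(c, mate))
    return results
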