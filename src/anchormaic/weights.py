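"""Method-of-moments MAIC weight estimation.

Weights take the exponential-tilting form w_i = exp(x̃_i·β) with x̃_i the
covariate vector centered on the aggregate targets. β minimizes the convex
objective Q(β) = Σ_i exp(x̃_i·β), whose gradient Σ_i x̃_i exp(x̃_i·β) = 0 is
exactly the condition that the weighted pooled means of the matched
covariates equal the targets. This is the estimator conventionally phrased
as "a logistic regression for the propensity of enrollment" in MAIC
reports: the same β solves the method-of-moments equations.

Newton's method with the analytic gradient/Hessian is used (Q is smooth and
strictly convex on the feasible set), with a quasi-Newton fallback when the
Hessian is ill-conditioned. Convergence requires a gradient max-norm below
1e-10·n, which makes the mean-matching contract assertable at 1e-8 relative
tolerance downstream.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import AgDSummary, WeightSet
from .exceptions import InfeasibleTargetError, MAICError

logger = logging.getLogger(__name__)

GRAD_TOL_PER_N = 1e-10
MAX_ITER = 500
RESCALE_MODES = ("raw", "sum_to_n", "mean_one")


def center_covariates(
    ipd: pd.DataFrame, targets: AgDSummary, covariate_names: Sequence[str]
) -> np.ndarray:
    """Return the matrix x̃ with one column per covariate, centered on its target."""
    cols = []
    for name in covariate_names:
        if name not in ipd.columns:
            raise MAICError(f"covariate {name!r} missing from the IPD table")
        tgt = targets.target(name)  # raises KeyError naming the covariate
        x = ipd[name].to_numpy(float)
        if np.isnan(x).any():
            raise MAICError(f"covariate {name!r} contains missing values")
        if tgt.kind == "binary" and set(np.unique(x)) - {0.0, 1.0}:
            raise MAICError(f"binary covariate {name!r} has non-0/1 values")
        c = x - tgt.value
        if np.ptp(c) == 0.0 and c[0] != 0.0:
            raise InfeasibleTargetError(
                f"covariate {name!r} is constant at {x[0]} but its target is "
                f"{tgt.value}; no weighting can match it"
            )
        cols.append(c)
    return np.column_stack(cols)


def _check_feasible(X: np.ndarray, names: Sequence[str]) -> None:
    offending = []
    for j, name in enumerate(names):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if (lo >= 0.0 and hi > 0.0) or (hi <= 0.0 and lo < 0.0):
            offending.append(name)
    if offending:
        raise InfeasibleTargetError(
            f"target mean(s) outside the convex hull of IPD values for "
            f"{offending}; matching is infeasible"
        )


def estimate_weights(
    centered: np.ndarray,
    covariate_names: Optional[Sequence[str]] = None,
    arms: Optional[np.ndarray] = None,
    max_iter: int = MAX_ITER,
) -> WeightSet:
    """Solve the tilting problem and return weights with diagnostics.

    Raises :class:`InfeasibleTargetError` when a target lies outside the
    convex hull of the IPD covariate values, and :class:`MAICError` for
    collinear or zero-variance centered covariates.
    """
    X = np.asarray(centered, float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(k)]
    if n <= k:
        raise MAICError(f"need more patients ({n}) than matched covariates ({k})")
    if not np.isfinite(X).all():
        raise MAICError("centered covariate matrix contains non-finite values")

    zero = [nm for j, nm in enumerate(covariate_names) if np.ptp(X[:, j]) == 0.0 and X[0, j] == 0.0]
    if zero:
        raise MAICError(
            f"centered covariate(s) {zero} are identically zero; remove them "
            "(β is unidentified)"
        )
    _check_feasible(X, covariate_names)
    if np.linalg.matrix_rank(X) < k:
        raise MAICError(
            f"matched covariates {list(covariate_names)} are collinear after "
            "centering; remove redundant covariates"
        )

    tol = GRAD_TOL_PER_N * n
    beta = np.zeros(k)
    converged = False
    iterations = 0
    grad_norm = np.inf
    for it in range(max_iter):
        eta = X @ beta
        if eta.max() > 500.0:
            worst = covariate_names[int(np.argmax(np.abs(beta)))]
            raise InfeasibleTargetError(
                f"weight solver diverging (β unbounded, worst covariate "
                f"{worst!r}); the target is at or outside the hull boundary"
            )
        w = np.exp(eta)
        grad = X.T @ w
        grad_norm = float(np.abs(grad).max())
        iterations = it
        if grad_norm <= tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.isfinite(step).all():
            logger.info("Hessian ill-conditioned at iter %d; BFGS fallback", it)
            res = optimize.minimize(
                lambda b: float(np.exp(X @ b).sum()),
                beta,
                jac=lambda b: X.T @ np.exp(X @ b),
                method="BFGS",
                options={"gtol": tol / 10.0, "maxiter": 10 * max_iter},
            )
            beta = res.x
            grad = X.T @ np.exp(X @ beta)
            grad_norm = float(np.abs(grad).max())
            converged = grad_norm <= tol
            break
        # damped Newton: Q is convex; accept the full step unless it raises Q
        # beyond float resolution (near the optimum the quadratic decrement
        # is smaller than eps·Q, so a strict-decrease test would stall).
        q0 = float(w.sum())
        t = 1.0
        for _ in range(60):
            cand = beta - t * step
            if float(np.exp(X @ cand).sum()) <= q0 * (1.0 + 1e-12):
                break
            t *= 0.5
        beta = beta - t * step
    else:
        iterations = max_iter

    w = np.exp(X @ beta)
    ws = WeightSet(
        weights=w,
        beta=beta,
        covariate_names=list(covariate_names),
        converged=converged,
        iterations=iterations,
        objective_value=float(w.sum()),
        ess_total=effective_sample_size(w),
        gradient_norm=grad_norm,
    )
    if arms is not None:
        arms = np.asarray(arms)
        ws.ess_by_arm = {
            str(a): effective_sample_size(w[arms == a]) for a in np.unique(arms)
        }
    if not converged:
        logger.warning(
            "weight solver did not converge (gradient max-norm %.3e > %.3e)",
            grad_norm, tol,
        )
    return ws


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (Σw)²/Σw²; equals n iff all weights are equal."""
    w = np.asarray(weights, float)
    s = w.sum()
    if w.size == 0 or s <= 0.0:
        raise MAICError("effective sample size undefined for all-zero weights")
    return float(s * s / (w @ w))


def rescale_weights(weightset: WeightSet, mode: str = "mean_one") -> WeightSet:
    """Multiply all weights by a positive constant; ESS and weighted means are unchanged.

    ``sum_to_n`` and ``mean_one`` coincide numerically (both give Σw = n);
    both are kept so exported weight files state the intended convention.
    """
    if mode not in RESCALE_MODES:
        raise MAICError(f"unknown rescale mode {mode!r}; choose from {RESCALE_MODES}")
    if not weightset.converged:
        raise MAICError("refusing to rescale a non-converged weight set")
    w = weightset.weights
    if mode == "raw":
        factor = 1.0
    else:
        factor = w.size / w.sum()
    out = WeightSet(
        weights=w * factor,
        beta=weightset.beta.copy(),
        covariate_names=list(weightset.covariate_names),
        converged=weightset.converged,
        iterations=weightset.iterations,
        objective_value=weightset.objective_value,
        ess_total=weightset.ess_total,
        ess_by_arm=dict(weightset.ess_by_arm),
        gradient_norm=weightset.gradient_norm,
        rescale_mode=mode,
    )
    return out
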