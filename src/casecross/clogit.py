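"""Conditional logistic regression, implemented from the likelihood up.

Each matched stratum contributes ``exp(b'x_case) / sum_j exp(b'x_j)`` to the
likelihood — the probability that, given one event in the stratum, it fell on
the case day. The log-likelihood, its gradient and the observed information
are exact analytic sums over strata, computed fully vectorised with
per-stratum max-subtraction for numerical stability. Fitting is
Newton-Raphson with step-halving from beta = 0; the conditional likelihood is
concave, so accepted steps never decrease it.

Internally each feature column is centred within stratum before fitting.
The conditional likelihood is invariant to stratum-constant shifts, so the
estimate is unchanged, while the information matrix becomes well conditioned
even for raw Kelvin-squared temperature columns.

Effect sizes are reported as percent increase per increment Delta (10 ug/m3
or 10 ppb by default): ``100*(exp(Delta*beta) - 1)`` with Wald confidence
limits ``100*(exp(Delta*(beta +- z975*SE)) - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import StratumSet

#: Normal 97.5th percentile used for all Wald intervals.
Z975 = 1.959964


class CollinearityError(ValueError):
    """Design has no information in, or linear dependence among, features."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the gradient tolerance."""


@dataclass
class FitResult:
    """Maximum conditional-likelihood fit.

    ``beta`` is per feature label on the native per-unit scale; ``cov`` is
    the inverse observed information at the optimum.
    """

    beta: pd.Series
    cov: pd.DataFrame
    loglik: float
    iterations: int
    converged: bool
    n_strata: int
    n_cases: int

    def se(self, label: str) -> float:
        return float(np.sqrt(self.cov.loc[label, label]))


@dataclass
class EffectEstimate:
    """Percent increase per `delta`-unit exposure increment, with Wald CI."""

    label: str
    delta: float
    percent: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    n_strata: int
    n_cases: int

    def covers_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


def _prepare(strata: StratumSet):
    X = np.asarray(strata.X, dtype=float)
    if not np.isfinite(X).all():
        bad = np.unique(strata.row_stratum[~np.isfinite(X).any(axis=1)])
        ids = strata.meta["stratum_id"].to_numpy()[bad[:5]]
        raise ValueError(f"non-finite features in strata {list(ids)}")
    starts = strata.starts
    counts = strata.counts
    # centre within stratum: estimate-invariant, numerically essential
    means = np.add.reduceat(X, starts, axis=0) / counts[:, None]
    Xc = X - np.repeat(means, counts, axis=0)
    return Xc, starts, counts


def loglik(
    beta: np.ndarray,
    strata: StratumSet,
    gradient: bool = False,
    hessian: bool = False,
):
    """Conditional log-likelihood at ``beta``; optionally gradient / Hessian.

    Returns ``ll`` or ``(ll, grad)`` or ``(ll, grad, hess)``.
    """
    Xc, starts, counts = _prepare(strata)
    return _loglik_centered(np.asarray(beta, float), Xc, starts, counts, gradient, hessian)


def _loglik_centered(beta, Xc, starts, counts, gradient=False, hessian=False):
    eta = Xc @ beta
    m = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - np.repeat(m, counts))
    denom = np.add.reduceat(w, starts)
    # case row is the first row of each stratum
    ll = float(np.sum(eta[starts] - m - np.log(denom)))
    if not (gradient or hessian):
        return ll
    p = w / np.repeat(denom, counts)
    grad = Xc[starts].sum(axis=0) - p @ Xc
    if not hessian:
        return ll, grad
    mu = np.add.reduceat(p[:, None] * Xc, starts, axis=0)  # (n_strata, k)
    H = -((Xc * p[:, None]).T @ Xc - mu.T @ mu)
    return ll, grad, H


def _check_design(Xc, labels, counts):
    """Reject features with no within-stratum variation or exact collinearity."""
    scale = Xc.std(axis=0)
    dead = scale < 1e-12
    if dead.any():
        names = [l for l, d in zip(labels, dead) if d]
        raise CollinearityError(
            f"features constant within every stratum (no information): {names}"
        )
    Xs = Xc / scale
    gram = Xs.T @ Xs / Xs.shape[0]
    eigvals, eigvecs = np.linalg.eigh(gram)
    if eigvals[0] < 1e-10 * max(eigvals[-1], 1.0):
        v = np.abs(eigvecs[:, 0])
        names = [labels[i] for i in np.nonzero(v > 0.3 * v.max())[0]]
        raise CollinearityError(f"collinear feature columns: {names}")
    return scale


def fit(
    strata: StratumSet,
    tol: float = 1e-8,
    max_iter: int = 50,
    on_fail: str = "raise",
) -> FitResult:
    """Newton-Raphson maximum conditional-likelihood fit from beta = 0.

    Convergence: max |gradient| < ``tol`` (on the internally standardised
    scale) or relative log-likelihood change < 1e-10. Step-halving keeps the
    log-likelihood non-decreasing. Non-convergence raises
    :class:`ConvergenceError` unless ``on_fail='return'``, in which case the
    result carries ``converged=False``.
    """
    labels = strata.feature_labels
    Xc, starts, counts = _prepare(strata)
    scale = _check_design(Xc, labels, counts)
    Xs = Xc / scale  # unit-scale columns for the solver

    k = Xs.shape[1]
    beta = np.zeros(k)
    ll, grad, H = _loglik_centered(beta, Xs, starts, counts, True, True)
    n_iter = 0
    converged = max(abs(g) for g in grad) < tol if k else True
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(f"singular information matrix: {exc}") from exc
        # step-halving: likelihood ascent guaranteed for concave ll
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = _loglik_centered(cand, Xs, starts, counts)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        rel_change = abs(ll_new - ll) / (abs(ll) + 1e-300)
        ll, grad, H = _loglik_centered(beta, Xs, starts, counts, True, True)
        if np.max(np.abs(grad)) < tol or rel_change < 1e-10:
            converged = np.max(np.abs(grad)) < tol or rel_change < 1e-10
            break
    else:
        converged = False

    if not converged and on_fail == "raise":
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(max |gradient| = {np.max(np.abs(grad)):.3g})"
        )

    info = -H
    try:
        cov_s = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(f"information matrix not invertible at optimum: {exc}") from exc
    # undo the column standardisation: beta_native = beta_std / scale
    beta_native = beta / scale
    cov_native = cov_s / np.outer(scale, scale)
    cov_native = (cov_native + cov_native.T) / 2.0

    return FitResult(
        beta=pd.Series(beta_native, index=labels),
        cov=pd.DataFrame(cov_native, index=labels, columns=labels),
        loglik=float(ll),
        iterations=n_iter,
        converged=bool(converged),
        n_strata=strata.n_strata,
        n_cases=strata.n_cases,
    )


def effect_from_beta(
    beta: float,
    se: float,
    label: str,
    delta: float = 10.0,
    n_strata: int = 0,
    n_cases: int = 0,
) -> EffectEstimate:
    """Percent-increase transform of a per-unit log coefficient and its SE."""
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    pct = 100.0 * (np.exp(delta * beta) - 1.0)
    lo = 100.0 * (np.exp(delta * (beta - Z975 * se)) - 1.0)
    hi = 100.0 * (np.exp(delta * (beta + Z975 * se)) - 1.0)
    z = beta / se if se > 0 else np.inf * np.sign(beta) if beta else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return EffectEstimate(
        label=label,
        delta=delta,
        percent=float(pct),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        beta=float(beta),
        se=float(se),
        n_strata=n_strata,
        n_cases=n_cases,
    )


def percent_increase(fit_result: FitResult, label: str, delta: float = 10.0) -> EffectEstimate:
    """Percent increase per ``delta`` units for one fitted feature."""
    if label not in fit_result.beta.index:
        raise KeyError(f"unknown feature label {label!r}; fitted: {list(fit_result.beta.index)}")
    return effect_from_beta(
        beta=float(fit_result.beta[label]),
        se=fit_result.se(label),
        label=label,
        delta=delta,
        n_strata=fit_result.n_strata,
        n_cases=fit_result.n_cases,
    )
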