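"""Thresholding rules converting posterior estimates into selected sets.

Three rules for Bayesian fits whose posterior-mode estimates are not
exactly zero:

* CI rule: select j iff the (1-alpha) normal interval
  [beta_j - Z_{alpha/2} se_j, beta_j + Z_{alpha/2} se_j] excludes 0.
* BIC thresholding: order candidates by descending |beta_j|, refit a Cox
  model on each prefix and pick the prefix minimizing
  BIC_j = -2 (l(beta_(1:j)) - l(0)) + j log(n).
* Modified BIC thresholding: force-include the largest-|beta| candidate,
  then greedily add the remaining candidate minimizing BIC at each step,
  and return the step with the overall minimum.

Both BIC rules prefilter to the top j_max nonzero |beta_j| (default 50),
include the null model at BIC_0 = 0, break ties toward the smaller model,
and use n = number of subjects. The refit log-likelihood is the maximized
Cox partial likelihood on the candidate columns (Newton, with a small
ridge fallback under rank deficiency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox_core import ConvergenceError, fit_cox_mle

__all__ = ["ThresholdSpec", "ci_rule", "bic_threshold", "modified_bic_threshold"]

_BIC_RIDGE = 1e-3


@dataclass
class ThresholdSpec:
    """Rule name plus its parameters."""

    rule: str
    alpha: float = 0.05
    j_max: int = 50

    def __post_init__(self):
        if self.rule not in ("ci", "bic", "modified_bic"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.j_max < 1:
            raise ValueError("j_max must be >= 1")

    @property
    def z_half_alpha(self) -> float:
        """Upper-tail normal critical value at alpha/2: P(Z > z) = alpha/2."""
        return float(stats.norm.ppf(1.0 - self.alpha / 2.0))


def ci_rule(beta_hat, se, alpha: float) -> np.ndarray:
    """Indices whose (1-alpha) CI excludes zero."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    if beta_hat.shape != se.shape:
        raise ValueError("beta_hat and se must be conformable")
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    z = ThresholdSpec(rule="ci", alpha=alpha).z_half_alpha
    return np.flatnonzero(np.abs(beta_hat) > z * se)


class _RefitCache:
    """Maximized Cox partial log-likelihood per candidate index set.

    Falls back to a ridge-stabilized refit when the Newton MLE is
    unidentifiable. Counts refits so rule complexity is observable.
    """

    def __init__(self, data, refit=None):
        self.data = data
        self.cache = {}
        self.n_refits = 0
        self._refit = refit if refit is not None else self._default_refit

    def _default_refit(self, cols):
        sub = self.data.select_columns(np.asarray(cols, dtype=int))
        try:
            return fit_cox_mle(sub, max_iter=60).extras["pl"]
        except (ConvergenceError, np.linalg.LinAlgError):
            return fit_cox_mle(sub, max_iter=60, ridge=_BIC_RIDGE).extras["pl"]

    def pl(self, cols):
        key = tuple(sorted(cols))
        if key not in self.cache:
            if len(key) == 0:
                self.cache[key] = self._refit(())
            else:
                self.n_refits += 1
                self.cache[key] = self._refit(key)
        return self.cache[key]


def _candidates(beta_hat, j_max):
    """Nonzero coefficients ordered by descending |beta|, capped at j_max."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    nz = np.flatnonzero(beta_hat != 0)
    order = nz[np.argsort(-np.abs(beta_hat[nz]), kind="stable")]
    return order[:j_max]


def _bic(pl_j, pl_0, j, n):
    return -2.0 * (pl_j - pl_0) + j * np.log(n)


def bic_threshold(beta_hat, data, j_max: int = 50, refit=None,
                  return_trace: bool = False):
    """Prefix-BIC rule on the descending-|beta| ordering.

    Returns the selected index set (possibly empty: the null model enters
    the comparison at BIC_0 = 0).
    """
    cand = _candidates(beta_hat, j_max)
    cache = _RefitCache(data, refit)
    if len(cand) == 0:
        return (np.array([], dtype=int), [0.0], cache) if return_trace \
            else np.array([], dtype=int)
    pl0 = cache.pl(())
    n = data.n
    trace = [0.0]  # BIC_0
    for j in range(1, len(cand) + 1):
        try:
            plj = cache.pl(cand[:j])
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"refit failed at prefix size {j}: {exc}; step skipped")
            trace.append(np.inf)
            continue
        trace.append(_bic(plj, pl0, j, n))
    best_j = int(np.argmin(trace))  # argmin takes the first (smallest) minimizer
    selected = np.sort(cand[:best_j])
    if return_trace:
        return selected, trace, cache
    return selected


def modified_bic_threshold(beta_hat, data, j_max: int = 50, refit=None,
                           return_trace: bool = False):
    """Greedy-forward BIC rule.

    The largest-|beta| candidate is included first; each later step adds
    the remaining candidate whose inclusion minimizes BIC; the returned
    model is the recorded step with minimum BIC (the null model included
    at BIC_0 = 0).
    """
    cand = _candidates(beta_hat, j_max)
    cache = _RefitCache(data, refit)
    if len(cand) == 0:
        return (np.array([], dtype=int), [0.0], cache) if return_trace \
            else np.array([], dtype=int)
    pl0 = cache.pl(())
    n = data.n
    current = [int(cand[0])]
    remaining = [int(c) for c in cand[1:]]
    trace = [0.0]
    models = [[]]
    try:
        trace.append(_bic(cache.pl(current), pl0, 1, n))
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"refit failed for the forced first variable: {exc}")
        trace.append(np.inf)
    models.append(list(current))
    while remaining:
        best_bic, best_var = np.inf, None
        for var in remaining:
            try:
                plj = cache.pl(current + [var])
            except (ConvergenceError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"refit failed adding variable {var}: {exc}; skipped")
                continue
            b = _bic(plj, pl0, len(current) + 1, n)
            if b < best_bic:
                best_bic, best_var = b, var
        if best_var is None:
            break
        current.append(best_var)
        remaining.remove(best_var)
        trace.append(best_bic)
        models.append(list(current))
    best_step = int(np.argmin(trace))
    selected = np.sort(np.array(models[best_step], dtype=int))
    if return_trace:
        return selected, trace, cache
    return selected
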