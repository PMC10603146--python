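"""Posterior-mode spike-and-slab Cox models fitted by EM.

Three prior families on the coefficients of a Cox partial likelihood:

* SSVS: beta_j | gamma_j ~ (1-gamma_j) N(0, tau^2) + gamma_j N(0, c^2 tau^2)
  with c = 1/tau, so the slab is N(0, 1).
* sslasso: beta_j | gamma_j ~ (1-gamma_j) DE(0, s0) + gamma_j DE(0, s1),
  slab scale s1 fixed (default 1), spike scale s0 tuned by CV.
* gsslasso: as sslasso with group-shared inclusion probabilities p_k under
  a beta(a, b) hyperprior (a = b = 1 gives the uniform prior).

The E-step computes inclusion responsibilities gamma_j from the two
mixture densities at the current beta; the M-step maximizes the expected
penalized partial likelihood — a ridge-type Newton update for SSVS, a
per-variable-weighted Cox lasso for the DE families. Inclusion
probabilities are updated as beta-posterior means, which under a = b = 1
reduce to the responsibilities themselves. Spike scales are tuned by
k-fold cross-validation of the partial-likelihood deviance on shared
folds. Covariates are standardized internally; coefficients and standard
errors are returned on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._coxnet import coxnet_path
from .cox_core import PreparedCox
from .penalized_cox import _standardize, make_folds

__all__ = [
    "SpikeSlabSpec",
    "SpikeSlabFit",
    "fit_ssvs_cox",
    "fit_sslasso_cox",
    "fit_gsslasso_cox",
    "posterior_se",
    "DEFAULT_TAU_GRID",
    "DEFAULT_S0_GRID",
]

DEFAULT_TAU_GRID = (0.001, 0.005, 0.01, 0.05, 0.1)
DEFAULT_S0_GRID = (0.005, 0.01, 0.02, 0.03, 0.05, 0.1)

#: |beta| floor in the DE-prior local curvature used for standard errors
_SE_BETA_FLOOR = 1e-3
_EM_TOL = 1e-6
_EM_MAX_ITER = 500


@dataclass
class SpikeSlabSpec:
    """Prior family and hyperparameters."""

    family: str
    tau: float = None
    s0: float = None
    s1: float = 1.0
    a: float = 1.0
    b: float = 1.0
    groups: np.ndarray = None

    def __post_init__(self):
        if self.family not in ("ssvs", "sslasso", "gsslasso"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "ssvs":
            if self.tau is None or self.tau <= 0:
                raise ValueError("ssvs requires tau > 0")
        else:
            if self.s0 is None or not 0 < self.s0 <= self.s1:
                raise ValueError("DE families require 0 < s0 <= s1")

    @property
    def c(self) -> float:
        """SSVS slab multiplier, fixed at 1/tau."""
        return 1.0 / self.tau


@dataclass
class SpikeSlabFit:
    """Posterior-mode fit with the quantities the selection rules need."""

    beta_hat: np.ndarray
    se: np.ndarray
    gamma_post: np.ndarray
    p_post: np.ndarray
    chosen_scale: float
    method: str
    converged: bool = True
    hyperparams: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @property
    def beta(self) -> np.ndarray:  # uniform access alongside ModelFit
        return self.beta_hat


def _log_normal_pdf(x, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2


def _log_de_pdf(x, s):
    return -np.log(2.0 * s) - np.abs(x) / s


def _responsibilities(p_incl, log_f1, log_f0):
    """gamma_j = P(gamma_j = 1 | beta_j) under mixture weights p_incl."""
    a1 = np.log(np.clip(p_incl, 1e-300, 1.0)) + log_f1
    a0 = np.log(np.clip(1.0 - p_incl, 1e-300, 1.0)) + log_f0
    m = np.maximum(a1, a0)
    w1 = np.exp(a1 - m)
    return w1 / (w1 + np.exp(a0 - m))


def _p_update(gamma, groups, a, b):
    """Beta-posterior-mean update of inclusion probabilities.

    Per-variable (groups None): p_j = (a-1+gamma_j)/(a+b-2+1), the
    responsibility itself when a = b = 1. Grouped: p_k shared in group k,
    p_k = (a-1+sum gamma)/(a+b-2+m_k).
    """
    if groups is None:
        p = (a - 1.0 + gamma) / (a + b - 2.0 + 1.0)
        return np.clip(p, 1e-8, 1.0 - 1e-8)
    p = np.empty_like(gamma)
    for g in np.unique(groups):
        mask = groups == g
        pk = (a - 1.0 + gamma[mask].sum()) / (a + b - 2.0 + mask.sum())
        p[mask] = pk
    return np.clip(p, 1e-8, 1.0 - 1e-8)


def _marginal_log_posterior(pc, beta, p_incl, log_f1, log_f0):
    """pl(beta) + sum_j log[(1-p_j) f0(beta_j) + p_j f1(beta_j)].

    The EM trace of this quantity is non-decreasing (flat prior on p)."""
    a1 = np.log(np.clip(p_incl, 1e-300, 1.0)) + log_f1
    a0 = np.log(np.clip(1.0 - p_incl, 1e-300, 1.0)) + log_f0
    m = np.maximum(a1, a0)
    return pc.pl(beta) + float(np.sum(m + np.log(np.exp(a1 - m) + np.exp(a0 - m))))


def _newton_ridge(pc, beta, prec, obj=None, max_steps=5, tol=1e-8):
    """Maximize pl(beta) - 0.5 * sum_j prec_j beta_j^2 by damped Newton."""
    if obj is None:
        obj = pc.pl(beta) - 0.5 * float(prec @ beta**2)
    for _ in range(max_steps):
        g = pc.grad(beta) - prec * beta
        info = pc.info(beta)
        info[np.diag_indices_from(info)] += prec
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            step = g / np.clip(np.diag(info), 1e-10, None)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            try:
                obj_new = pc.pl(cand) - 0.5 * float(prec @ cand**2)
            except FloatingPointError:
                obj_new = -np.inf
            if obj_new >= obj - 1e-12:
                break
            scale *= 0.5
        else:
            break
        moved = np.max(np.abs(cand - beta))
        beta, obj = cand, obj_new
        if moved < tol:
            break
    return beta


def _em_ssvs(pc, tau, max_iter=_EM_MAX_ITER, tol=_EM_TOL):
    """EM posterior mode under the Gaussian mixture; slab sd = c*tau = 1."""
    p = pc.p
    beta = np.zeros(p)
    gamma = np.full(p, 0.5)
    p_incl = np.full(p, 0.5)
    slab_sd = 1.0
    trace = []
    converged = False
    for _ in range(max_iter):
        log_f1 = _log_normal_pdf(beta, slab_sd)
        log_f0 = _log_normal_pdf(beta, tau)
        trace.append(_marginal_log_posterior(pc, beta, p_incl, log_f1, log_f0))
        gamma = _responsibilities(p_incl, log_f1, log_f0)
        p_incl = _p_update(gamma, None, 1.0, 1.0)
        prec = gamma / slab_sd**2 + (1.0 - gamma) / tau**2
        beta_new = _newton_ridge(pc, beta, prec)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    log_f1 = _log_normal_pdf(beta, slab_sd)
    log_f0 = _log_normal_pdf(beta, tau)
    gamma = _responsibilities(p_incl, log_f1, log_f0)
    prec = gamma / slab_sd**2 + (1.0 - gamma) / tau**2
    trace.append(_marginal_log_posterior(pc, beta, p_incl, log_f1, log_f0))
    return beta, gamma, p_incl, prec, trace, converged


def _em_de(pc, s0, s1, groups, a, b, max_iter=_EM_MAX_ITER, tol=_EM_TOL):
    """EM posterior mode under the double-exponential mixture.

    M-step: weighted Cox lasso with per-variable scale S_j,
    1/S_j = gamma_j/s1 + (1-gamma_j)/s0.
    """
    p = pc.p
    beta = np.zeros(p)
    gamma = np.full(p, 0.5)
    p_incl = np.full(p, 0.5)
    one_lam = np.array([1.0])
    trace = []
    converged = False
    for _ in range(max_iter):
        log_f1 = _log_de_pdf(beta, s1)
        log_f0 = _log_de_pdf(beta, s0)
        trace.append(_marginal_log_posterior(pc, beta, p_incl, log_f1, log_f0))
        gamma = _responsibilities(p_incl, log_f1, log_f0)
        p_incl = _p_update(gamma, groups, a, b)
        inv_scale = gamma / s1 + (1.0 - gamma) / s0
        # intermediate M-steps need not be exact; EM re-solves each round
        betas, _ = coxnet_path(pc.X, pc.delta, pc.first_tie, pc.last_tie,
                               one_lam, 1.0, inv_scale, beta,
                               5e-7, 100, 2000, 1e-4)
        beta_new = betas[0]
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    log_f1 = _log_de_pdf(beta, s1)
    log_f0 = _log_de_pdf(beta, s0)
    gamma = _responsibilities(p_incl, log_f1, log_f0)
    inv_scale = gamma / s1 + (1.0 - gamma) / s0
    # local curvature of the DE penalty at the mode, floored near zero
    prec = inv_scale / np.maximum(np.abs(beta), _SE_BETA_FLOOR)
    trace.append(_marginal_log_posterior(pc, beta, p_incl, log_f1, log_f0))
    return beta, gamma, p_incl, prec, trace, converged


def posterior_se(prec, pc, beta) -> np.ndarray:
    """SEs from the inverse penalized observed information at the mode.

    ``prec`` is the per-variable prior curvature. Falls back to the
    diagonal approximation if the penalized information is singular.
    """
    info = pc.info(np.asarray(beta, dtype=float))
    info[np.diag_indices_from(info)] += prec
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        if np.all(se > 0):
            return se
    except np.linalg.LinAlgError:
        pass
    warnings.warn("singular penalized information; using diagonal approximation")
    return 1.0 / np.sqrt(np.clip(np.diag(info), 1e-300, None))


def _cv_choose_scale(data, scales, fit_one, fold_labels):
    """CV deviance -2 [pl_full(b) - pl_train(b)] summed over folds, per scale."""
    pc_full = PreparedCox.from_dataset(data)
    n_folds = fold_labels.max() + 1
    dev = np.zeros(len(scales))
    for k in range(n_folds):
        train = np.flatnonzero(fold_labels != k)
        sub = data.subset(train)
        Xs, sd, _ = _standardize(sub.X)
        pc = PreparedCox(sub.time, sub.event, Xs)
        for i, sc in enumerate(scales):
            beta_std = fit_one(pc, sc)[0]
            b = beta_std / sd
            dev[i] += -2.0 * (pc_full.pl(b) - pc.pl(beta_std))
    best = int(np.argmin(dev))
    return best, dev


def _fit_spike_slab(data, family, scales, s1, a, b, groups, folds, seed,
                    fold_labels, max_iter):
    if fold_labels is None:
        fold_labels = make_folds(data.n, data.event, folds, seed)
    if family == "ssvs":
        def fit_one(pc, sc):
            return _em_ssvs(pc, sc, max_iter=max_iter)
    else:
        def fit_one(pc, sc):
            return _em_de(pc, sc, s1, groups, a, b, max_iter=max_iter)
    scales = list(scales)
    if len(scales) == 1:
        best, dev = 0, np.zeros(1)
    else:
        best, dev = _cv_choose_scale(data, scales, fit_one, fold_labels)
    chosen = scales[best]
    Xs, sd, _ = _standardize(data.X)
    pc = PreparedCox(data.time, data.event, Xs)
    beta_std, gamma, p_incl, prec, trace, converged = fit_one(pc, chosen)
    if not converged:
        warnings.warn(f"{family} EM did not converge in {max_iter} iterations; "
                      "returning the final iterate")
    se_std = posterior_se(prec, pc, beta_std)
    scale_key = "tau" if family == "ssvs" else "s0"
    p_post = p_incl
    if groups is not None:
        _, idx = np.unique(groups, return_index=True)
        p_post = p_incl[np.sort(idx)]
    return SpikeSlabFit(
        beta_hat=beta_std / sd,
        se=se_std / sd,
        gamma_post=gamma,
        p_post=p_post,
        chosen_scale=chosen,
        method=family,
        converged=converged,
        hyperparams={scale_key: chosen, "s1": s1, "a": a, "b": b,
                     "cv_deviance": dev.tolist(), "scale_grid": scales},
        extras={"beta_std": beta_std, "sd": sd, "prec": prec, "trace": trace,
                "fold_assignment": fold_labels, "p_incl_full": p_incl},
    )


def fit_ssvs_cox(data, tau_grid=DEFAULT_TAU_GRID, folds: int = 10, seed=None,
                 fold_labels=None, max_iter=_EM_MAX_ITER) -> SpikeSlabFit:
    """SSVS posterior mode; spike scale tau tuned by k-fold CV, c = 1/tau."""
    tau_grid = [float(t) for t in np.atleast_1d(tau_grid)]
    if any(t <= 0 for t in tau_grid):
        raise ValueError("tau grid must be positive")
    return _fit_spike_slab(data, "ssvs", tau_grid, None, 1.0, 1.0, None,
                           folds, seed, fold_labels, max_iter)


def fit_sslasso_cox(data, s0_grid=DEFAULT_S0_GRID, s1: float = 1.0, folds: int = 10,
                    seed=None, fold_labels=None, max_iter=_EM_MAX_ITER) -> SpikeSlabFit:
    """Spike-and-slab lasso Cox; spike scale s0 tuned by k-fold CV."""
    s0_grid = [float(s) for s in np.atleast_1d(s0_grid)]
    if any(not 0 < s <= s1 for s in s0_grid):
        raise ValueError("s0 grid must satisfy 0 < s0 <= s1")
    return _fit_spike_slab(data, "sslasso", s0_grid, s1, 1.0, 1.0, None,
                           folds, seed, fold_labels, max_iter)


def fit_gsslasso_cox(data, groups=None, s0_grid=DEFAULT_S0_GRID, s1: float = 1.0,
                     a: float = 1.0, b: float = 1.0, folds: int = 10, seed=None,
                     fold_labels=None, max_iter=_EM_MAX_ITER) -> SpikeSlabFit:
    """Group spike-and-slab lasso Cox with group-shared inclusion
    probabilities p_k ~ beta(a, b)."""
    groups = data.groups if groups is None else np.asarray(groups)
    if groups is None:
        raise ValueError("gsslasso requires group labels")
    if len(groups) != data.p:
        raise ValueError("groups must label every covariate")
    s0_grid = [float(s) for s in np.atleast_1d(s0_grid)]
    if any(not 0 < s <= s1 for s in s0_grid):
        raise ValueError("s0 grid must satisfy 0 < s0 <= s1")
    fit = _fit_spike_slab(data, "gsslasso", s0_grid, s1, a, b, groups,
                          folds, seed, fold_labels, max_iter)
    fit.extras["groups"] = groups
    return fit
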