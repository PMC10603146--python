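"""Penalized Cox regression: lasso, elastic net, ridge, adaptive lasso.

Objective (coefficients on the internally standardized scale):

    Q(beta) = -pl(beta) + lam * sum_j v_j (alpha |beta_j| + (1-alpha) beta_j^2)

with alpha = 1 for lasso, alpha = 0 for ridge and per-variable penalty
factors v_j = 1 except for the adaptive lasso, where v_j = 1/|ridge
estimate|. Hyperparameters are tuned by k-fold cross-validation of the
Verweij-van Houwelingen partial-likelihood deviance. Covariates are
standardized to unit variance for fitting; coefficients are returned on
the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._coxnet import coxnet_path
from .cox_core import ModelFit, PreparedCox
from .data import SurvivalDataset

__all__ = [
    "PenaltySpec",
    "CVResult",
    "ModelFit",
    "fit_penalized_cox",
    "cross_validate",
    "fit_adaptive_lasso",
    "select_nonzero",
    "make_folds",
    "lambda_max",
    "kkt_max_violation",
]

_KINDS = ("lasso", "elastic_net", "ridge", "adaptive_lasso")
#: ridge has no finite zeroing lambda; path top is scaled off the score instead
_RIDGE_LAMBDA_SCALE = 100.0
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
#: |ridge estimate| below this gets an infinite adaptive-lasso weight
ADAPTIVE_EPS = 1e-8


@dataclass
class PenaltySpec:
    """Penalty kind plus its hyperparameters."""

    kind: str
    lam: float = None
    alpha: float = 1.0
    weights: np.ndarray = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown penalty kind {self.kind!r}; expected one of {_KINDS}")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.kind == "lasso":
            self.alpha = 1.0
        elif self.kind == "ridge":
            self.alpha = 0.0
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("penalty weights must be strictly positive (or +inf)")

    @property
    def effective_alpha(self) -> float:
        return self.alpha


@dataclass
class CVResult:
    """Cross-validation surface and the chosen hyperparameters."""

    grid: list  # (lam, alpha) pairs
    cv_loss: np.ndarray
    chosen: dict
    fold_assignment: np.ndarray


def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    sd_safe = np.where(keep, sd, 1.0)
    return (X - mean) / sd_safe, sd_safe, keep


def make_folds(n: int, event, n_folds: int = 10, seed=None, max_redraws: int = 100):
    """Seeded fold labels; redrawn until every fold contains an event."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    event = np.asarray(event)
    for attempt in range(max_redraws):
        rng = np.random.default_rng(None if seed is None else seed + attempt)
        labels = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
        rng.shuffle(labels)
        ok = all(
            event[labels == k].sum() >= 1 and event[labels != k].sum() >= 1
            for k in range(n_folds)
        )
        if ok:
            return labels
    raise RuntimeError("could not draw folds with events in every fold: data too small")


def _prep(data, weights=None):
    Xs, sd, keep = _standardize(data.X)
    v = np.ones(data.p) if weights is None else np.asarray(weights, dtype=float).copy()
    v[~keep] = np.inf  # constant columns carry no information
    pc = PreparedCox(data.time, data.event, Xs)
    return pc, Xs, sd, v


def lambda_max(data, alpha: float = 1.0, weights=None) -> float:
    """Smallest lambda with an all-zero solution (alpha > 0), computed from
    the score at beta = 0 on the standardized scale."""
    pc, _, _, v = _prep(data, weights)
    g = np.abs(pc.grad(np.zeros(data.p)))
    finite = np.isfinite(v)
    if alpha > 0:
        vals = g[finite] / (alpha * v[finite])
        return float(vals.max()) if len(vals) else 0.0
    return _RIDGE_LAMBDA_SCALE * float(g[finite].max())


def default_lambda_grid(data, alpha: float = 1.0, weights=None, n_lambda: int = 100,
                        min_ratio: float = 0.01) -> np.ndarray:
    lmax = lambda_max(data, alpha=alpha, weights=weights)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


#: coefficient tolerance for final fits and for the cheaper CV fold fits;
#: 1e-5 changes fold deviances by O(1e-4), far below fold noise
_FIT_TOL = 5e-7
_CV_TOL = 1e-5


def _solve_path(pc: PreparedCox, sd, v, lambdas, alpha, beta_init=None, tol=_FIT_TOL,
                kkt_tol=2e-5):
    """Run the numba solver; returns coefficients on the original scale
    (n_lambda, p) and on the standardized scale."""
    p = pc.p
    beta0 = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float)
    lambdas = np.ascontiguousarray(lambdas, dtype=float)
    betas_std, conv = coxnet_path(pc.X, pc.delta, pc.first_tie, pc.last_tie,
                                  lambdas, float(alpha), np.ascontiguousarray(v, dtype=float),
                                  beta0, tol, 100, 2000, kkt_tol)
    if not conv.all():
        warnings.warn("coordinate descent did not fully converge at some lambda values")
    return betas_std / sd, betas_std


def fit_penalized_cox(data, spec: PenaltySpec) -> ModelFit:
    """Minimize the penalized negative partial log-likelihood at fixed
    hyperparameters. Shrunk-out coefficients are exactly zero."""
    if spec.lam is None:
        raise ValueError("PenaltySpec.lam must be set; use cross_validate to choose it")
    pc, _, sd, v = _prep(data, spec.weights)
    betas, betas_std = _solve_path(pc, sd, v, np.array([spec.lam]), spec.alpha)
    return ModelFit(
        beta=betas[0],
        method=spec.kind,
        hyperparams={"lambda": spec.lam, "alpha": spec.alpha},
        extras={"beta_std": betas_std[0], "penalty_weights": v, "sd": sd},
    )


def _cv_deviance_surface(data, alpha, lambdas, weights, fold_labels):
    """Verweij-van Houwelingen CV deviance for each lambda:
    -2 * sum_k [ pl_full(beta_-k) - pl_train_-k(beta_-k) ]."""
    pc_full = PreparedCox.from_dataset(data)
    n_folds = fold_labels.max() + 1
    dev = np.zeros(len(lambdas))
    for k in range(n_folds):
        train = np.flatnonzero(fold_labels != k)
        sub = data.subset(train)
        pc, _, sd, v = _prep(sub, weights)
        betas, _ = _solve_path(pc, sd, v, lambdas, alpha, tol=_CV_TOL, kkt_tol=5e-3)
        for il in range(len(lambdas)):
            b = betas[il]
            dev[il] += -2.0 * (pc_full.pl(b) - pc.pl(b * sd))
    return dev


def cross_validate(data, kind: str, lambda_grid=None, alpha_grid=None,
                   folds: int = 10, seed=None, weights=None,
                   fold_labels=None, n_lambda: int = 100,
                   min_ratio: float = 0.01) -> CVResult:
    """k-fold CV with grid search; elastic net sweeps (alpha, lambda).

    The loss is the cross-validated partial-likelihood deviance; ties are
    broken toward larger lambda (sparser model).
    """
    spec = PenaltySpec(kind=kind, lam=0.0, weights=weights)  # validates kind
    if fold_labels is None:
        fold_labels = make_folds(data.n, data.event, folds, seed)
    alphas = [spec.alpha]
    if kind == "elastic_net":
        alphas = list(DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid)
    grid, losses = [], []
    for alpha in alphas:
        lams = (default_lambda_grid(data, alpha=alpha, weights=weights,
                                    n_lambda=n_lambda, min_ratio=min_ratio)
                if lambda_grid is None else np.asarray(lambda_grid, dtype=float))
        dev = _cv_deviance_surface(data, alpha, lams, weights, fold_labels)
        grid.extend((float(l), float(alpha)) for l in lams)
        losses.append(dev)
    cv_loss = np.concatenate(losses)
    # minimizer; ties toward larger lambda
    best = min(range(len(grid)), key=lambda i: (cv_loss[i], -grid[i][0]))
    chosen = {"lambda": grid[best][0], "alpha": grid[best][1]}
    return CVResult(grid=grid, cv_loss=cv_loss, chosen=chosen, fold_assignment=fold_labels)


def fit_cv_penalized_cox(data, kind: str, folds: int = 10, seed=None, weights=None,
                         lambda_grid=None, alpha_grid=None, fold_labels=None,
                         n_lambda: int = 100, min_ratio: float = 0.01) -> ModelFit:
    """Cross-validate, then refit on the full data at the chosen point."""
    cv = cross_validate(data, kind, lambda_grid=lambda_grid, alpha_grid=alpha_grid,
                        folds=folds, seed=seed, weights=weights, fold_labels=fold_labels,
                        n_lambda=n_lambda, min_ratio=min_ratio)
    fit = fit_penalized_cox(
        data, PenaltySpec(kind=kind, lam=cv.chosen["lambda"], alpha=cv.chosen["alpha"],
                          weights=weights))
    fit.extras["cv"] = cv
    fit.hyperparams["folds"] = int(fold_labels.max() + 1) if fold_labels is not None else folds
    return fit


def fit_adaptive_lasso(data, folds: int = 10, seed=None, fold_labels=None,
                       n_lambda: int = 100, min_ratio: float = 0.01) -> ModelFit:
    """Two-stage adaptive lasso.

    Stage 1: cross-validated ridge gives initial estimates; stage 2 is a
    weighted lasso with w_j = 1/|ridge estimate_j| (standardized scale),
    lambda chosen by CV. Variables with |ridge estimate| below
    ADAPTIVE_EPS receive an infinite weight and are excluded.
    """
    if fold_labels is None:
        fold_labels = make_folds(data.n, data.event, folds, seed)
    ridge_fit = fit_cv_penalized_cox(data, "ridge", fold_labels=fold_labels,
                                     n_lambda=n_lambda, min_ratio=min_ratio)
    beta_tilde = ridge_fit.extras["beta_std"]
    w = np.empty(data.p)
    small = np.abs(beta_tilde) < ADAPTIVE_EPS
    w[~small] = 1.0 / np.abs(beta_tilde[~small])
    w[small] = np.inf
    if small.any():
        warnings.warn(f"{int(small.sum())} variables excluded by infinite adaptive weight")
    fit = fit_cv_penalized_cox(data, "lasso", weights=w, fold_labels=fold_labels,
                               n_lambda=n_lambda, min_ratio=min_ratio)
    fit.method = "adaptive_lasso"
    fit.hyperparams["ridge_lambda"] = ridge_fit.hyperparams["lambda"]
    fit.extras["ridge_fit"] = ridge_fit
    return fit


def select_nonzero(fit: ModelFit) -> np.ndarray:
    """Indices with exactly nonzero coefficients (0-based)."""
    return np.flatnonzero(np.asarray(fit.beta) != 0)


def kkt_max_violation(fit: ModelFit, data) -> float:
    """Max KKT violation of the penalized optimum on the standardized scale.

    Zero coefficients: |d pl/d beta_j| <= lam*alpha*v_j.
    Nonzero: d pl/d beta_j - 2*lam*(1-alpha)*v_j*beta_j = lam*alpha*v_j*sign.
    """
    lam = fit.hyperparams["lambda"]
    alpha = fit.hyperparams["alpha"]
    v = fit.extras["penalty_weights"]
    beta_std = fit.extras["beta_std"]
    Xs, _, _ = _standardize(data.X)
    pc = PreparedCox(data.time, data.event, Xs)
    g = pc.grad(beta_std)
    viol = 0.0
    for j in range(data.p):
        if not np.isfinite(v[j]):
            continue
        thr = lam * alpha * v[j]
        if beta_std[j] == 0.0:
            viol = max(viol, abs(g[j]) - thr)
        else:
            resid = g[j] - 2.0 * lam * (1.0 - alpha) * v[j] * beta_std[j] \
                - thr * np.sign(beta_std[j])
            viol = max(viol, abs(resid))
    return viol
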