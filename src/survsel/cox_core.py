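"""Cox partial-likelihood machinery shared by all fitting modules.

Breslow convention for tied event times; the risk set at an event time t
is ``{i : T_i >= t}`` (the failing subject is at risk of its own event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelFit",
    "CoxModelState",
    "PreparedCox",
    "ConvergenceError",
    "partial_log_likelihood",
    "partial_ll_gradient",
    "observed_information",
    "fit_cox_mle",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge or is unidentifiable."""


@dataclass
class ModelFit:
    """Result of a (penalized) Cox fit.

    ``beta`` is on the original covariate scale. ``se`` is None for
    penalized fits where no standard error is defined.
    """

    beta: np.ndarray
    method: str
    se: np.ndarray = None
    hyperparams: dict = field(default_factory=dict)
    converged: bool = True
    extras: dict = field(default_factory=dict)


@dataclass
class CoxModelState:
    """Coefficients plus derived per-subject risk quantities."""

    beta: np.ndarray
    linear_predictor: np.ndarray
    risk_sets: list

    @classmethod
    def from_beta(cls, beta, data):
        beta = np.asarray(beta, dtype=float)
        eta = data.X @ beta
        event_times = data.time[data.event == 1]
        risk_sets = [np.flatnonzero(data.time >= t) for t in np.sort(event_times)]
        return cls(beta=beta, linear_predictor=eta, risk_sets=risk_sets)


class PreparedCox:
    """Time-sorted arrays and tie-group maps for fast repeated evaluation.

    ``first_tie[i]`` / ``last_tie[i]`` are the first / last sorted
    positions sharing sorted time i, so that suffix sums indexed at
    ``first_tie`` give risk-set totals under the T >= t convention.
    """

    def __init__(self, time, event, X):
        time = np.asarray(time, dtype=float)
        self.order = np.argsort(time, kind="stable")
        t = time[self.order]
        self.first_tie = np.searchsorted(t, t, side="left").astype(np.int64)
        self.last_tie = (np.searchsorted(t, t, side="right") - 1).astype(np.int64)
        self.delta = np.ascontiguousarray(np.asarray(event)[self.order], dtype=float)
        self.X = np.ascontiguousarray(np.asarray(X, dtype=float)[self.order])
        self.n, self.p = self.X.shape
        self.n_events = int(self.delta.sum())

    @classmethod
    def from_dataset(cls, data):
        return cls(data.time, data.event, data.X)

    def _risk_terms(self, eta):
        """(es, H, G, log_rs): exp(eta-max), cumulative d/S and d/S^2 sums,
        and log risk-set mass at each subject's own time (unshifted)."""
        m = eta.max() if len(eta) else 0.0
        es = np.exp(eta - m)
        rs = np.cumsum(es[::-1])[::-1]
        rs_tie = rs[self.first_tie]
        inc1 = np.where(self.delta > 0, self.delta / rs_tie, 0.0)
        inc2 = np.where(self.delta > 0, self.delta / rs_tie**2, 0.0)
        H = np.cumsum(inc1)[self.last_tie]
        G = np.cumsum(inc2)[self.last_tie]
        return es, H, G, np.log(rs_tie) + m

    def pl(self, beta) -> float:
        """Breslow partial log-likelihood, log-sum-exp stabilized."""
        eta = self.X @ np.asarray(beta, dtype=float)
        _, _, _, log_rs = self._risk_terms(eta)
        val = float(np.sum(self.delta * (eta - log_rs)))
        if not np.isfinite(val):
            raise FloatingPointError("partial log-likelihood overflowed")
        return val

    def grad(self, beta) -> np.ndarray:
        """Score vector d pl / d beta."""
        eta = self.X @ np.asarray(beta, dtype=float)
        es, H, _, _ = self._risk_terms(eta)
        return self.X.T @ (self.delta - es * H)

    def info(self, beta) -> np.ndarray:
        """Observed information: -d2 pl / d beta d beta', p x p.

        -d2 pl = sum_i exp(eta_i) H_i x_i x_i' - sum_k d_k mu_k mu_k'
        with mu_k the risk-set covariate mean at event time t_k.
        """
        eta = self.X @ np.asarray(beta, dtype=float)
        es, H, _, _ = self._risk_terms(eta)
        A = self.X.T @ (self.X * (es * H)[:, None])
        M1 = np.cumsum((self.X * es[:, None])[::-1], axis=0)[::-1]
        rs = np.cumsum(es[::-1])[::-1]
        ev = self.delta > 0
        mu = M1[self.first_tie[ev]] / rs[self.first_tie[ev]][:, None]
        return A - mu.T @ mu


def partial_log_likelihood(beta, data) -> float:
    """pl(beta) = sum_i delta_i [beta'x_i - log sum_{i' in R(t_i)} exp(beta'x_i')]."""
    if data.n == 0:
        raise ValueError("empty dataset")
    return PreparedCox.from_dataset(data).pl(beta)


def partial_ll_gradient(beta, data) -> np.ndarray:
    """Score vector of the Breslow partial log-likelihood."""
    return PreparedCox.from_dataset(data).grad(beta)


def observed_information(beta, data) -> np.ndarray:
    """Negative Hessian of pl at beta."""
    return PreparedCox.from_dataset(data).info(beta)


def fit_cox_mle(data=None, max_iter: int = 100, tol: float = 1e-9, ridge: float = 0.0,
                prepared: PreparedCox = None) -> ModelFit:
    """Newton-Raphson Cox MLE with step-halving.

    For low-dimensional use only (adaptive-lasso checks, BIC refits).
    ``ridge`` adds a small quadratic penalty for near-singular refits.

    Raises
    ------
    ConvergenceError
        If the information matrix is singular (unidentifiable model) or
        the iteration does not converge.
    """
    pc = prepared if prepared is not None else PreparedCox.from_dataset(data)
    p = pc.p
    if pc.n_events == 0:
        raise ConvergenceError("no events: partial likelihood is flat")
    beta = np.zeros(p)
    pl = pc.pl(beta) - 0.5 * ridge * beta @ beta
    for _ in range(max_iter):
        g = pc.grad(beta) - ridge * beta
        info = pc.info(beta) + ridge * np.eye(p)
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        if not np.all(np.isfinite(step)):
            raise ConvergenceError("non-finite Newton step")
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            try:
                pl_new = pc.pl(cand) - 0.5 * ridge * cand @ cand
            except FloatingPointError:
                pl_new = -np.inf
            if pl_new >= pl - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step-halving failed to improve pl")
        beta = cand
        if abs(pl_new - pl) <= tol * (abs(pl) + 1.0):
            pl = pl_new
            break
        pl = pl_new
    else:
        raise ConvergenceError(f"Newton did not converge in {max_iter} iterations")
    info = pc.info(beta) + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular information at optimum: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return ModelFit(beta=beta, method="cox_mle", se=se, extras={"pl": pl})
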