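"""Synthetic survival data with block-autoregressive collinearity.

Covariates are standard normal in blocks with within-block correlation
rho^|i-j| and independence across blocks. True effects are sparse and
negative (protective), event times are exponential with a 4-year baseline
median, and exponential censoring is calibrated by Monte-Carlo bisection
to a target censoring proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .data import SurvivalDataset

__all__ = [
    "SimulationDesign",
    "TrueModel",
    "DESIGNS",
    "LOW_RANGE",
    "HIGH_RANGE",
    "make_covariates",
    "make_true_model",
    "simulate_event_times",
    "simulate_censoring_times",
    "calibrate_censoring",
    "generate_replicate",
]

#: Coefficient ranges for the two signal strengths (all effects protective).
LOW_RANGE = (-0.4, -0.1)
HIGH_RANGE = (-1.0, -0.5)


@dataclass
class TrueModel:
    """Generating coefficient vector and its support."""

    beta: np.ndarray
    support: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        nz = np.flatnonzero(self.beta)
        if set(nz) != set(self.support.tolist()):
            raise ValueError("support must equal the nonzero positions of beta")


@dataclass
class SimulationDesign:
    """All generator parameters of one simulated-data design."""

    design_id: int
    n: int = 450
    p: int = 200
    q: int = 5
    beta_range: tuple = LOW_RANGE
    rho: float = 0.9
    block_size: int = 50
    median_survival: float = 4.0
    target_censoring: float = 0.5
    censor_rate_c: float = None  # filled by calibrate_censoring
    seed: int = 0
    #: place all true variables inside the first block (stress-test option)
    support_in_one_block: bool = False
    #: redraw coefficient values every replicate (default) or fix them
    redraw_coefficients: bool = True

    def __post_init__(self):
        if self.p % self.block_size != 0:
            raise ValueError(f"p={self.p} must be a multiple of block_size={self.block_size}")
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.q > self.p:
            raise ValueError(f"q={self.q} cannot exceed p={self.p}")
        lo, hi = self.beta_range
        if lo > hi:
            raise ValueError("beta_range must be an (lo, hi) interval")
        if not 0 < self.target_censoring < 1:
            raise ValueError("target_censoring must be in (0, 1)")
        if self.median_survival <= 0:
            raise ValueError("median_survival must be positive")

    @property
    def baseline_rate(self) -> float:
        """Exponential baseline hazard: median m gives rate ln(2)/m."""
        return np.log(2.0) / self.median_survival

    @property
    def groups(self) -> np.ndarray:
        """Block label per covariate."""
        return np.repeat(np.arange(self.p // self.block_size), self.block_size)


#: The four benchmark designs: n=450, p=200, 4 blocks of 50, rho=0.9.
DESIGNS = {
    1: SimulationDesign(design_id=1, q=5, beta_range=LOW_RANGE),
    2: SimulationDesign(design_id=2, q=5, beta_range=HIGH_RANGE),
    3: SimulationDesign(design_id=3, q=10, beta_range=LOW_RANGE),
    4: SimulationDesign(design_id=4, q=10, beta_range=HIGH_RANGE),
}


def _ar_chol(block_size: int, rho: float) -> np.ndarray:
    idx = np.arange(block_size)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return linalg.cholesky(cov, lower=True)


def make_covariates(n: int, p: int, rho: float, block_size: int, seed=None) -> np.ndarray:
    """n x p standard-normal covariates, AR(rho) within blocks of block_size.

    Within a block, cov(col_i, col_j) = rho^|i-j|; distinct blocks are
    independent; rows are i.i.d.
    """
    if p % block_size != 0:
        raise ValueError(f"p={p} must be a multiple of block_size={block_size}")
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    if rho == 0:
        return z
    L = _ar_chol(block_size, rho)
    X = np.empty_like(z)
    for b in range(p // block_size):
        cols = slice(b * block_size, (b + 1) * block_size)
        X[:, cols] = z[:, cols] @ L.T
    return X


def make_true_model(p: int, q: int, beta_range, seed=None,
                    support_in_one_block: bool = False, block_size: int = 50) -> TrueModel:
    """Sparse coefficient vector: q entries uniform in beta_range, 0 elsewhere.

    Support positions are drawn uniformly without replacement over all p
    positions, or within the first block when ``support_in_one_block``.
    """
    if q > p:
        raise ValueError(f"q={q} cannot exceed p={p}")
    lo, hi = beta_range
    if lo > hi:
        raise ValueError("empty beta_range")
    rng = np.random.default_rng(seed)
    beta = np.zeros(p)
    if q == 0:
        return TrueModel(beta=beta, support=np.array([], dtype=int))
    pool = min(block_size, p) if support_in_one_block else p
    if support_in_one_block and q > pool:
        raise ValueError("q exceeds block size for within-block placement")
    support = np.sort(rng.choice(pool, size=q, replace=False))
    beta[support] = rng.uniform(lo, hi, size=q)
    return TrueModel(beta=beta, support=support)


def simulate_event_times(X, beta, median_survival: float, seed=None) -> np.ndarray:
    """Exponential event times with rate lambda0 * exp(beta'x_i).

    lambda0 = ln(2)/median_survival, i.e. the stated median is the
    baseline (x = 0) median.
    """
    if median_survival <= 0:
        raise ValueError("median_survival must be positive")
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != len(beta):
        raise ValueError("X and beta dimensions do not conform")
    rng = np.random.default_rng(seed)
    lam0 = np.log(2.0) / median_survival
    rate = lam0 * np.exp(X @ beta)
    return rng.exponential(1.0 / rate)


def simulate_censoring_times(n: int, c: float, seed=None) -> np.ndarray:
    """Exponential censoring times with rate c."""
    if c <= 0:
        raise ValueError("censoring rate must be positive")
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / c, size=n)


def calibrate_censoring(design: SimulationDesign, true_model: TrueModel = None,
                        target: float = None, seed=None, n_mc: int = 100_000,
                        tol: float = 0.005, max_iter: int = 60) -> float:
    """Exponential censoring rate c giving P(C < T) near ``target``.

    Monte-Carlo bisection: one large pool of (x, event-time) pairs is
    simulated once, then P(censored) is a monotone function of c on that
    pool and is bisected. Raises if the bracket cannot be expanded or
    bisection fails to converge.
    """
    target = design.target_censoring if target is None else target
    if not 0 < target < 1:
        raise ValueError("target censoring must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if true_model is None:
        true_model = make_true_model(
            design.p, design.q, design.beta_range, seed=rng.integers(2**31),
            support_in_one_block=design.support_in_one_block, block_size=design.block_size)
    X = make_covariates(n_mc, design.p, design.rho, design.block_size,
                        seed=rng.integers(2**31))
    T = simulate_event_times(X, true_model.beta, design.median_survival,
                             seed=rng.integers(2**31))
    # one shared uniform draw: C = -log(U)/c is monotone in c pointwise
    u = rng.uniform(size=n_mc)
    log_u = -np.log(u)

    def censored_frac(c):
        return float(np.mean(log_u / c < T))

    lo, hi = 1e-8, design.baseline_rate
    for _ in range(200):
        if censored_frac(hi) >= target:
            break
        hi *= 2.0
    else:
        raise RuntimeError("failed to bracket the censoring rate")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = censored_frac(mid)
        if abs(f - target) <= tol:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"censoring-rate bisection did not converge in {max_iter} iterations")


def generate_replicate(design: SimulationDesign, seed=None):
    """One simulated dataset: (SurvivalDataset, TrueModel).

    Observed time is min(event, censoring) with delta = 1 iff the event
    came first. Covariate group labels map each variable to its block.
    If the design's ``censor_rate_c`` is unset it is calibrated first
    (seeded from the design seed, once per design in benchmark use).
    """
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_model, s_x, s_t, s_c = [np.random.default_rng(c) for c in ss.spawn(4)]
    model_seed = design.seed if not design.redraw_coefficients else s_model.integers(2**31)
    true_model = make_true_model(
        design.p, design.q, design.beta_range, seed=model_seed,
        support_in_one_block=design.support_in_one_block, block_size=design.block_size)
    c = design.censor_rate_c
    if c is None:
        c = calibrate_censoring(design, seed=design.seed)
    X = make_covariates(design.n, design.p, design.rho, design.block_size,
                        seed=s_x.integers(2**31))
    T_event = simulate_event_times(X, true_model.beta, design.median_survival,
                                   seed=s_t.integers(2**31))
    C = simulate_censoring_times(design.n, c, seed=s_c.integers(2**31))
    time = np.minimum(T_event, C)
    event = (T_event <= C).astype(int)
    data = SurvivalDataset(time=time, event=event, X=X, groups=design.groups)
    return data, true_model
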