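"""Core dataset container shared by all fitting modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SurvivalDataset:
    """Right-censored survival data.

    Parameters
    ----------
    time : ndarray, shape (n,)
        Observed times (event or censoring), strictly positive.
    event : ndarray, shape (n,)
        Event indicators; 1 = failure/death observed, 0 = censored.
    X : ndarray, shape (n, p)
        Covariate matrix. May contain NaN before complete-case filtering.
    feature_names : list of str, length p
    groups : ndarray of shape (p,), optional
        Group label per covariate (any hashable dtype).
    """

    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    feature_names: list[str] = field(default=None)
    groups: np.ndarray = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = self.X.shape[0]
        if len(self.time) != n or len(self.event) != n:
            raise ValueError(
                f"length mismatch: time={len(self.time)}, event={len(self.event)}, "
                f"X has {n} rows"
            )
        ev = np.asarray(self.event, dtype=float)
        if not np.all(np.isin(ev[~np.isnan(ev)], (0.0, 1.0))):
            raise ValueError("event indicators must be 0 or 1")
        self.event = ev.astype(int)
        if np.any(self.time[~np.isnan(self.time)] <= 0):
            raise ValueError("observed times must be strictly positive")
        if self.feature_names is None:
            self.feature_names = [f"x{j + 1}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal number of covariate columns")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if len(self.groups) != self.X.shape[1]:
                raise ValueError("groups length must equal number of covariate columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, rows) -> "SurvivalDataset":
        """Row subset (fold splitting, complete-case filtering)."""
        rows = np.asarray(rows)
        return SurvivalDataset(
            time=self.time[rows],
            event=self.event[rows],
            X=self.X[rows],
            feature_names=list(self.feature_names),
            groups=None if self.groups is None else self.groups.copy(),
        )

    def select_columns(self, cols) -> "SurvivalDataset":
        cols = np.asarray(cols, dtype=int)
        return SurvivalDataset(
            time=self.time.copy(),
            event=self.event.copy(),
            X=self.X[:, cols],
            feature_names=[self.feature_names[j] for j in cols],
            groups=None if self.groups is None else self.groups[cols],
        )
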