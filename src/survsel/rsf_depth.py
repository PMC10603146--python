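"""Random survival forest with minimal-depth variable selection.

Forests are grown with scikit-survival (log-rank splitting, bootstrap
aggregation, mtry random candidates per node). Variable selection uses
the minimal-depth of the shallowest maximal subtree per variable: the
depth of the shallowest node split on v equals the depth of its
shallowest maximal subtree, since any v-split ancestor would itself be
shallower. Variables never split in a tree receive that tree's maximal
terminal depth + 1 as a sentinel. The default selection threshold is the
mean of the per-tree minimal-depth distribution under the null in which
every internal node splits on a given variable independently with
probability 1/p; a top-k variant is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.utils import check_random_state
from sksurv.ensemble import RandomSurvivalForest
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

__all__ = ["ForestModel", "DepthProfile", "fit_rsf", "minimal_depth", "select_by_minimal_depth"]


@dataclass
class ForestModel:
    """Fitted forest plus out-of-bag prediction error."""

    forest: RandomSurvivalForest
    ntree: int
    mtry: int
    nodesize: int
    oob_error: float
    p: int
    extras: dict = field(default_factory=dict)


@dataclass
class DepthProfile:
    """Per-variable average minimal depth and the null-mean threshold."""

    minimal_depth: np.ndarray
    threshold: float
    per_tree: np.ndarray = None  # (ntree, p), sentinel-filled


def _bootstrap_oob_mask(forest, n):
    """Out-of-bag mask per tree, (ntree, n).

    Reproduces sklearn's bootstrap draw: each tree's sample indices are
    ``randint(0, n, n)`` from its own seeded RandomState.
    """
    masks = np.empty((len(forest.estimators_), n), dtype=bool)
    for t, est in enumerate(forest.estimators_):
        rs = check_random_state(est.random_state)
        sampled = rs.randint(0, n, n)
        counts = np.bincount(sampled, minlength=n)
        masks[t] = counts == 0
    return masks


def _oob_error(forest, X, time, event):
    """1 - Harrell concordance of the OOB ensemble mortality."""
    n = X.shape[0]
    masks = _bootstrap_oob_mask(forest, n)
    if not masks.any(axis=0).all():
        raise RuntimeError("some subjects are never out-of-bag; increase ntree")
    risk_sum = np.zeros(n)
    counts = np.zeros(n)
    for t, est in enumerate(forest.estimators_):
        oob = masks[t]
        if oob.any():
            risk_sum[oob] += est.predict(X[oob])
            counts[oob] += 1
    mortality = risk_sum / counts
    cindex = concordance_index_censored(event.astype(bool), time, mortality)[0]
    return 1.0 - cindex


def fit_rsf(data, ntree: int = 1000, mtry: int = None, nodesize: int = 3,
            seed=None) -> ForestModel:
    """Grow a random survival forest (log-rank splits, bootstrap samples).

    Defaults follow the high-dimensional recommendations: ntree=1000,
    mtry=ceil(sqrt(p)), nodesize=3.
    """
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    if data.n_events == 0:
        raise ValueError("cannot grow a survival forest with no events")
    p = data.p
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must be in [1, {p}]")
    y = Surv.from_arrays(event=data.event.astype(bool), time=data.time)
    forest = RandomSurvivalForest(
        n_estimators=ntree,
        max_features=mtry,
        min_samples_leaf=nodesize,
        bootstrap=True,
        n_jobs=1,
        random_state=seed,
    )
    forest.fit(data.X, y)
    try:
        oob = _oob_error(forest, data.X, data.time, data.event)
    except RuntimeError:
        oob = np.nan
    return ForestModel(forest=forest, ntree=ntree, mtry=mtry, nodesize=nodesize,
                       oob_error=oob, p=p)


def _node_depths(tree):
    """Depth of every node in a fitted sklearn tree structure."""
    depth = np.zeros(tree.node_count, dtype=int)
    for i in range(tree.node_count):
        for child in (tree.children_left[i], tree.children_right[i]):
            if child >= 0:
                depth[child] = depth[i] + 1
    return depth


def _tree_minimal_depths(tree, p):
    """(min depth per variable with sentinel, null-mean threshold) for one tree.

    Sentinel for variables never split on: maximal terminal depth + 1.
    The null mean treats every internal node as splitting on a given
    variable independently with probability 1/p.
    """
    depth = _node_depths(tree)
    is_internal = tree.children_left >= 0
    sentinel = depth.max() + 1
    md = np.full(p, sentinel, dtype=float)
    feats = tree.feature[is_internal]
    deps = depth[is_internal]
    np.minimum.at(md, feats, deps)
    # null distribution from the count of internal nodes per depth level
    max_int_depth = deps.max() if len(deps) else 0
    n_at = np.bincount(deps, minlength=max_int_depth + 1)
    theta = 1.0 / p
    surv = np.cumprod((1.0 - theta) ** n_at)  # P(D > d), d = 0..max_int_depth
    probs = np.empty(max_int_depth + 2)
    prev = 1.0
    for d in range(max_int_depth + 1):
        probs[d] = prev - surv[d]
        prev = surv[d]
    probs[max_int_depth + 1] = prev  # never split: sentinel mass
    support = np.append(np.arange(max_int_depth + 1), sentinel)
    null_mean = float(support @ probs)
    return md, null_mean


def minimal_depth(model: ForestModel) -> DepthProfile:
    """Average minimal depth per variable over all trees, with the
    forest-average null-mean threshold."""
    p = model.p
    per_tree = np.empty((len(model.forest.estimators_), p))
    thresholds = np.empty(len(model.forest.estimators_))
    for t, est in enumerate(model.forest.estimators_):
        per_tree[t], thresholds[t] = _tree_minimal_depths(est.tree_, p)
    return DepthProfile(minimal_depth=per_tree.mean(axis=0),
                        threshold=float(thresholds.mean()),
                        per_tree=per_tree)


def select_by_minimal_depth(profile: DepthProfile, top_k: int = None) -> np.ndarray:
    """Variables with average minimal depth strictly below the threshold,
    or the top_k shallowest variables when ``top_k`` is given."""
    if top_k is not None:
        order = np.argsort(profile.minimal_depth, kind="stable")
        return np.sort(order[:top_k])
    return np.flatnonzero(profile.minimal_depth < profile.threshold)
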