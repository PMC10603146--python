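"""Simulation benchmark: methods x selection rules x designs -> TPR/TNR/FPR.

Each replicate generates one dataset per design (seed = seed_base + rep),
fits every requested method with a shared 10-fold assignment, applies the
applicable selection rules, and scores the selected set against the true
support. Cell means are arithmetic averages over replicates; failed fits
are excluded from their cell with an exclusion count, never imputed.

Rate denominators: TPR divides by q (true-variable count), TNR and FPR by
p - q, so TNR + FPR = 1. A flag reproduces the variant where all three
rates divide by p.
"""

from __future__ import annotations

import dataclasses
import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .penalized_cox import (
    fit_adaptive_lasso,
    fit_cv_penalized_cox,
    make_folds,
    select_nonzero,
)
from .rsf_depth import fit_rsf, minimal_depth, select_by_minimal_depth
from .selection_rules import bic_threshold, ci_rule, modified_bic_threshold
from .sim_designs import DESIGNS, SimulationDesign, calibrate_censoring, generate_replicate
from .spike_slab_cox import fit_gsslasso_cox, fit_sslasso_cox, fit_ssvs_cox

__all__ = [
    "OperatingCharacteristics",
    "BenchmarkTable",
    "operating_characteristics",
    "run_benchmark",
    "render_tables",
    "DEFAULT_RULES",
]

logger = logging.getLogger(__name__)

PENALIZED_METHODS = ("lasso", "elastic_net", "adaptive_lasso", "ridge")
BAYESIAN_METHODS = ("ssvs", "sslasso", "gsslasso")

DEFAULT_RULES = {
    "lasso": ("nonzero",),
    "elastic_net": ("nonzero",),
    "adaptive_lasso": ("nonzero",),
    "ridge": ("nonzero",),
    "rsf": ("mindepth",),
    "ssvs": ("ci_75", "ci_90", "ci_95", "bic", "modified_bic"),
    "sslasso": ("ci_75", "ci_90", "ci_95", "bic", "modified_bic"),
    "gsslasso": ("ci_75", "ci_90", "ci_95", "bic", "modified_bic"),
    "oracle": ("oracle",),
}

_CI_ALPHA = {"ci_75": 0.25, "ci_90": 0.10, "ci_95": 0.05}


@dataclass
class OperatingCharacteristics:
    """Selection quality of one selected set against one true support."""

    tpr: float
    tnr: float
    fpr: float
    n_selected: int


@dataclass
class BenchmarkTable:
    """Long-format per-replicate results plus aggregation metadata."""

    replicates: pd.DataFrame
    reps: int
    seed_base: int
    exclusions: pd.DataFrame = None
    designs: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean TPR/TNR/FPR (and +-1.96 sd/sqrt(reps) half-widths) per cell."""
        if self.replicates.empty:
            return pd.DataFrame(columns=["design", "method", "rule",
                                         "tpr", "tnr", "fpr", "n_selected", "n_reps"])
        g = self.replicates.groupby(["design", "method", "rule"], sort=False)
        mean = g[["tpr", "tnr", "fpr", "n_selected"]].mean()
        sd = g[["tpr", "tnr", "fpr"]].std(ddof=1)
        cnt = g.size().rename("n_reps")
        half = (1.96 * sd / np.sqrt(cnt.to_numpy()[:, None])).add_suffix("_ci95")
        return pd.concat([mean, half, cnt], axis=1).reset_index()


def operating_characteristics(selected, true_support, p: int,
                              paper_denominators: bool = False) -> OperatingCharacteristics:
    """TPR = |sel & supp|/q, TNR = |excluded irrelevant|/(p-q),
    FPR = |sel \\ supp|/(p-q); with ``paper_denominators`` all three divide
    by p instead."""
    selected = np.asarray(sorted(set(int(i) for i in np.atleast_1d(selected))), dtype=int) \
        if len(np.atleast_1d(selected)) else np.array([], dtype=int)
    true_support = np.asarray(sorted(set(int(i) for i in np.atleast_1d(true_support))),
                              dtype=int) if len(np.atleast_1d(true_support)) else \
        np.array([], dtype=int)
    for arr, name in ((selected, "selected"), (true_support, "true_support")):
        if len(arr) and (arr.min() < 0 or arr.max() >= p):
            raise ValueError(f"{name} contains indices outside [0, {p})")
    q = len(true_support)
    if q == 0:
        raise ValueError("TPR is undefined for an empty true support")
    if q >= p:
        raise ValueError("TNR/FPR are undefined when every variable is relevant")
    tp = len(np.intersect1d(selected, true_support, assume_unique=True))
    fp = len(selected) - tp
    tn = (p - q) - fp
    if paper_denominators:
        return OperatingCharacteristics(tpr=tp / p, tnr=tn / p, fpr=fp / p,
                                        n_selected=len(selected))
    return OperatingCharacteristics(tpr=tp / q, tnr=tn / (p - q), fpr=fp / (p - q),
                                    n_selected=len(selected))


def _fit_method(method, data, fold_labels, seed, kwargs):
    if method in ("lasso", "elastic_net", "ridge"):
        return fit_cv_penalized_cox(data, method, fold_labels=fold_labels, **kwargs)
    if method == "adaptive_lasso":
        return fit_adaptive_lasso(data, fold_labels=fold_labels, **kwargs)
    if method == "rsf":
        return fit_rsf(data, seed=seed, **kwargs)
    if method == "ssvs":
        return fit_ssvs_cox(data, fold_labels=fold_labels, **kwargs)
    if method == "sslasso":
        return fit_sslasso_cox(data, fold_labels=fold_labels, **kwargs)
    if method == "gsslasso":
        return fit_gsslasso_cox(data, fold_labels=fold_labels, **kwargs)
    raise ValueError(f"unknown method {method!r}")


def _apply_rule(rule, fit, data, true_model, j_max=50):
    if rule == "oracle":
        return true_model.support
    if rule == "nonzero":
        return select_nonzero(fit)
    if rule == "mindepth":
        return select_by_minimal_depth(minimal_depth(fit))
    if rule == "topk":
        return select_by_minimal_depth(minimal_depth(fit), top_k=15)
    if rule in _CI_ALPHA:
        return ci_rule(fit.beta_hat, fit.se, alpha=_CI_ALPHA[rule])
    if rule == "bic":
        return bic_threshold(fit.beta_hat, data, j_max=j_max)
    if rule == "modified_bic":
        return modified_bic_threshold(fit.beta_hat, data, j_max=j_max)
    raise ValueError(f"unknown rule {rule!r}")


def run_benchmark(designs, methods, rules=None, reps: int = 100, seed_base: int = 0,
                  method_kwargs=None, folds: int = 10, j_max: int = 50,
                  paper_denominators: bool = False) -> BenchmarkTable:
    """Run every method x rule over seeded replicates of each design.

    ``designs`` may contain design ids (1-4) or SimulationDesign objects.
    Censoring rates are calibrated once per design. All methods within a
    replicate see the identical dataset and CV fold assignment.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rules = dict(DEFAULT_RULES) if rules is None else {**DEFAULT_RULES, **rules}
    method_kwargs = method_kwargs or {}
    design_objs = {}
    for d in designs:
        des = DESIGNS[d] if not isinstance(d, SimulationDesign) else d
        if des.censor_rate_c is None:
            c = calibrate_censoring(des, seed=seed_base)
            des = dataclasses.replace(des, censor_rate_c=c)
            logger.info("design %s: calibrated censoring rate c=%.4f", des.design_id, c)
        design_objs[des.design_id] = des
    rows = []
    excl = []
    for did, des in design_objs.items():
        for rep in range(reps):
            seed = seed_base + rep
            data, tm = generate_replicate(des, seed=seed)
            fold_labels = make_folds(data.n, data.event, folds, seed=seed)
            for method in methods:
                t0 = _time.perf_counter()
                try:
                    fit = (None if method == "oracle"
                           else _fit_method(method, data, fold_labels, seed,
                                            method_kwargs.get(method, {})))
                except Exception as exc:  # noqa: BLE001 - excluded, never imputed
                    logger.warning("design %s rep %d: %s fit failed: %s",
                                   did, rep, method, exc)
                    excl.append({"design": did, "rep": rep, "method": method,
                                 "error": str(exc)})
                    continue
                logger.debug("design %s rep %d: %s fit in %.2fs",
                             did, rep, method, _time.perf_counter() - t0)
                for rule in rules.get(method, ()):
                    try:
                        sel = _apply_rule(rule, fit, data, tm, j_max=j_max)
                        oc = operating_characteristics(
                            sel, tm.support, data.p,
                            paper_denominators=paper_denominators)
                    except Exception as exc:  # noqa: BLE001
                        logger.warning("design %s rep %d: %s/%s rule failed: %s",
                                       did, rep, method, rule, exc)
                        excl.append({"design": did, "rep": rep,
                                     "method": f"{method}/{rule}", "error": str(exc)})
                        continue
                    rows.append({"design": did, "rep": rep, "method": method,
                                 "rule": rule, "tpr": oc.tpr, "tnr": oc.tnr,
                                 "fpr": oc.fpr, "n_selected": oc.n_selected,
                                 "censoring": 1.0 - data.event.mean()})
    replicates = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl)
    return BenchmarkTable(replicates=replicates, reps=reps, seed_base=seed_base,
                          exclusions=exclusions, designs=design_objs)


def render_tables(table: BenchmarkTable, out_dir) -> dict:
    """Write the wide summary (methods as column groups, designs as rows)
    and the long per-replicate file; returns the written paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    long_path = out / "replicates.csv"
    table.replicates.to_csv(long_path, index=False)
    paths["long"] = long_path
    summary = table.summary()
    wide_path = out / "summary_wide.csv"
    if len(summary):
        wide = summary.pivot_table(index="design", columns=["method", "rule"],
                                   values=["tpr", "tnr", "fpr"], sort=False)
        # column order: method, rule, metric
        wide = wide.reorder_levels([1, 2, 0], axis=1)
        metric_order = {"tpr": 0, "tnr": 1, "fpr": 2}
        wide = wide[sorted(wide.columns, key=lambda c: (c[0], c[1], metric_order[c[2]]))]
        wide.columns = ["|".join(c) for c in wide.columns]
        wide.to_csv(wide_path)
    else:
        pd.DataFrame().to_csv(wide_path)
    paths["wide"] = wide_path
    if table.exclusions is not None and len(table.exclusions):
        excl_path = out / "exclusions.csv"
        table.exclusions.to_csv(excl_path, index=False)
        paths["exclusions"] = excl_path
    return paths
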