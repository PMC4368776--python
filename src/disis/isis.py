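"""Iterative sure independence screening with lasso selection.

One round of marginal screening misses predictors whose effect is masked
by other features (marginally weak, jointly strong).  The iterative scheme
alternates:

1. screen: rank unselected features by |PCC| against the *residuals* of
   the current model (the original response at the first step) and recruit
   the top d - |M| of them;
2. select: lasso on current-members-plus-recruits against the *original*
   response, with a CV-chosen penalty, keeping the nonzero-coefficient set.

Because the residuals are exactly uncorrelated with the current members'
columns, recruits are judged on signal the current model does not already
explain — which is what lets a zero-marginal-correlation feature enter.
The loop stops when the model reaches the target size d, stalls, or
empties; the final coefficients are refit by OLS (lasso shrinkage is good
for selection, not for estimation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datasets import FeatureMatrix
from .regression import OLSFit, cv_lasso, ols_fit, residuals
from .screening import marginal_correlations, sis_screen

MAX_ITER = 50


@dataclass
class IterationRecord:
    s: int
    recruited: list[int]       # A_s
    selected: list[int]        # M_s
    lam: float
    size: int


@dataclass
class ISISTrace:
    iterations: list[IterationRecord] = field(default_factory=list)
    stop_reason: str = ""      # reached_d | size_unchanged | set_unchanged | empty_selection | max_iter


@dataclass
class SelectedModel:
    """A fitted sparse linear model over an index set M.

    ``marginal_r`` holds each selected feature's Pearson correlation with
    the *original* response on the data the model was fit to — the
    quantity that defines "marginally weak" (|r| < 0.1).
    """

    drug_name: str
    d: int
    final_set: list[int]
    feature_ids: list[str]          # namespaced ids, aligned with final_set
    feature_classes: list[str]
    intercept: float
    coefs: np.ndarray               # aligned with final_set
    marginal_r: np.ndarray
    ols: OLSFit | None = None
    trace: ISISTrace | None = None
    method: str = "isis"

    @property
    def size(self) -> int:
        return len(self.final_set)


def _stage_seed(seed: int, s: int) -> int:
    return (seed + 7919 * s) % (2**31 - 1)


def _finalize(
    X: FeatureMatrix,
    y: np.ndarray,
    members: list[int],
    d: int,
    trace: ISISTrace,
    drug_name: str,
    method: str = "isis",
) -> SelectedModel:
    members = sorted(members)
    r_all = marginal_correlations(X.values[:, members], y) if members else np.empty(0)
    if members:
        fit = ols_fit(X.values[:, members], y)
        intercept, coefs = fit.intercept, fit.coefs
    else:
        fit = None
        intercept, coefs = float(np.mean(y)), np.empty(0)
    return SelectedModel(
        drug_name=drug_name,
        d=d,
        final_set=members,
        feature_ids=[X.feature_ids[j] for j in members],
        feature_classes=[X.feature_class(j) for j in members],
        intercept=intercept,
        coefs=coefs,
        marginal_r=r_all,
        ols=fit,
        trace=trace,
        method=method,
    )


def isis_select(
    X: FeatureMatrix,
    y: np.ndarray | None = None,
    d: int = 10,
    seed: int = 0,
    drug_name: str | None = None,
) -> SelectedModel:
    """Run the iterative screen -> lasso -> residual loop up to model size d.

    The first screen recruits k1 = max(1, floor(2d/3)) features — leaving
    room for at least one residual round, which is the point of iterating.
    Every later screen recruits d - |M| features from outside the current
    set, scored against the residuals of the OLS fit on the current set;
    every lasso runs on the union against the original response with a
    freshly CV-selected penalty.  Deterministic given (X, y, d, seed).
    """
    yv = np.asarray(y.values if hasattr(y, "values") else y, dtype=float)
    n, p = X.n, X.p
    if not 2 <= d < n:
        raise ValueError(f"need 2 <= d < n (d={d}, n={n})")
    if p < d:
        raise ValueError(f"need p >= d (p={p}, d={d})")
    name = drug_name or (y.drug_name if hasattr(y, "drug_name") else "response")

    trace = ISISTrace()
    k1 = max(1, (2 * d) // 3)
    a1 = sis_screen(X, yv, k1)
    fit1 = cv_lasso(X.values[:, a1.recruited], yv, seed=_stage_seed(seed, 1))
    members = [a1.recruited[j] for j in fit1.active]
    trace.iterations.append(
        IterationRecord(s=1, recruited=a1.recruited, selected=sorted(members), lam=fit1.lam, size=len(members))
    )
    if not members:
        trace.stop_reason = "empty_selection"
        return _finalize(X, yv, members, d, trace, name)

    for s in range(2, MAX_ITER + 1):
        if len(members) >= d:
            trace.stop_reason = "reached_d"
            break
        prev = members
        fit_prev = ols_fit(X.values[:, prev], yv)
        r = residuals(fit_prev, X.values[:, prev], yv)
        a_s = sis_screen(X, r, d - len(prev), exclude=set(prev))
        cand = prev + a_s.recruited
        fit_s = cv_lasso(X.values[:, cand], yv, seed=_stage_seed(seed, s))
        new = [cand[j] for j in fit_s.active]
        trace.iterations.append(
            IterationRecord(s=s, recruited=a_s.recruited, selected=sorted(new), lam=fit_s.lam, size=len(new))
        )
        if not new:
            trace.stop_reason = "empty_selection"
            break
        if set(new) == set(prev):
            members = new
            trace.stop_reason = "set_unchanged"
            break
        if len(new) == len(prev):
            members = new
            trace.stop_reason = "size_unchanged"
            break
        members = new
        if len(members) >= d:
            trace.stop_reason = "reached_d"
            break
    else:
        trace.stop_reason = "max_iter"

    return _finalize(X, yv, members, d, trace, name)


def predict(model: SelectedModel, X_new: FeatureMatrix) -> np.ndarray:
    """Predict responses on new samples, matching features by namespaced id."""
    if not model.final_set:
        return np.full(X_new.n, model.intercept)
    cols = [X_new.column_index(fid) for fid in model.feature_ids]
    return model.intercept + X_new.values[:, cols] @ model.coefs


def trace_to_dict(model: SelectedModel) -> dict:
    t = model.trace
    return {
        "drug": model.drug_name,
        "method": model.method,
        "d": model.d,
        "final_set": model.feature_ids,
        "stop_reason": t.stop_reason if t else None,
        "iterations": [
            {
                "s": it.s,
                "recruited": it.recruited,
                "selected": it.selected,
                "lambda": it.lam,
                "size": it.size,
            }
            for it in (t.iterations if t else [])
        ],
    }


def write_trace(model: SelectedModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(trace_to_dict(model), fh, indent=2, sort_keys=True)
        fh.write("\n")
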