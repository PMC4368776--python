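"""Repeated cross-validation, model-size selection, and baselines.

The evaluation protocol: 10 repeats of 10-fold cross-validation, with
screening, penalty selection and the OLS refit all done inside each
training fold; each sample's out-of-fold predictions are averaged over
repeats and the Pearson correlation of those averages with the observed
responses is the performance score.  The target model size d is chosen
from the grid {2, 4, ..., 40} by maximising that correlation.

Two baselines frame the comparison:

* STF (simple top features): the top-m marginal correlates with an OLS
  refit, m matched to the iterative method's realised model size;
* ENR: a marginal screen at |r| >= 0.1 followed by elastic-net
  regression with CV-chosen mixing and penalty — the screen that, by
  design, cannot keep a marginally weak feature.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .datasets import FeatureMatrix
from .isis import SelectedModel, _finalize, isis_select, predict
from .regression import _standardize
from .screening import marginal_correlations, pearson_corr, sis_screen

logger = logging.getLogger(__name__)

D_GRID = tuple(range(2, 41, 2))

Fitter = Callable[[FeatureMatrix, np.ndarray, int], SelectedModel]


@dataclass
class CVResult:
    d: int
    mean_predictions: np.ndarray       # per sample, averaged over repeats
    pcc: float
    fold_assignments: list[np.ndarray] = field(default_factory=list)
    n_repeats: int = 10
    n_folds: int = 10


@dataclass
class DSelection:
    grid: tuple[int, ...]
    pcc_by_d: dict[int, float]
    chosen_d: int
    results: dict[int, CVResult] = field(default_factory=dict)


def _as_array(y) -> np.ndarray:
    return np.asarray(y.values if hasattr(y, "values") else y, dtype=float)


def cross_validate(
    X: FeatureMatrix,
    y,
    d: int,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    fitter: Fitter | None = None,
) -> CVResult:
    """Repeated k-fold CV; everything is fit inside the training folds only.

    Fold partitions are uniformly random per repeat (repeat r uses seed
    ``seed + r``).  A fold whose training responses are constant is
    skipped with a warning; its samples get no prediction that repeat.
    """
    yv = _as_array(y)
    n = X.n
    if n < n_folds:
        raise ValueError(f"n={n} < n_folds={n_folds}")
    if fitter is None:
        fitter = lambda Xt, yt, s: isis_select(Xt, yt, d=d, seed=s)
    preds = np.full((n_repeats, n), np.nan)
    assignments: list[np.ndarray] = []
    for rep in range(n_repeats):
        rep_seed = seed + rep
        rng = np.random.default_rng(rep_seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        fold_of = np.empty(n, dtype=int)
        for f, idx in enumerate(folds):
            fold_of[idx] = f
        assignments.append(fold_of)
        for f, test in enumerate(folds):
            train = np.setdiff1d(perm, test)
            if np.ptp(yv[train]) == 0:
                logger.warning("repeat %d fold %d skipped: constant training response", rep, f)
                continue
            model = fitter(X.subset_samples(train), yv[train], rep_seed)
            preds[rep, test] = predict(model, X.subset_samples(test))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_pred = np.nanmean(preds, axis=0)
    ok = ~np.isnan(mean_pred)
    pcc = pearson_corr(mean_pred[ok], yv[ok])
    return CVResult(
        d=d,
        mean_predictions=mean_pred,
        pcc=pcc,
        fold_assignments=assignments,
        n_repeats=n_repeats,
        n_folds=n_folds,
    )


def select_d(
    X: FeatureMatrix,
    y,
    grid: Sequence[int] = D_GRID,
    seed: int = 0,
    n_repeats: int = 10,
    n_folds: int = 10,
) -> DSelection:
    """Pick the model size maximising the CV correlation; ties go small."""
    if not grid:
        raise ValueError("empty d grid")
    n = X.n
    for d in grid:
        if d >= 0.9 * n:
            raise ValueError(f"d={d} too large for n={n} under {n_folds}-fold CV")
    results: dict[int, CVResult] = {}
    pcc_by_d: dict[int, float] = {}
    for d in grid:
        res = cross_validate(X, y, d, n_repeats=n_repeats, n_folds=n_folds, seed=seed)
        results[d] = res
        pcc_by_d[d] = res.pcc
    chosen = min(sorted(grid), key=lambda d: (-pcc_by_d[d], d))
    return DSelection(grid=tuple(grid), pcc_by_d=pcc_by_d, chosen_d=chosen, results=results)


def stf_fit(X: FeatureMatrix, y, m: int, drug_name: str | None = None) -> SelectedModel:
    """Simple-top-features baseline: top-m |PCC| ranking plus an OLS refit."""
    yv = _as_array(y)
    if not 1 <= m < X.n - 1:
        raise ValueError(f"need 1 <= m < n - 1 (m={m}, n={X.n})")
    name = drug_name or (y.drug_name if hasattr(y, "drug_name") else "response")
    top = sis_screen(X, yv, m)
    return _finalize(X, yv, top.recruited, m, trace=None, drug_name=name, method="stf")


def enr_fit(
    X: FeatureMatrix,
    y,
    screen_threshold: float = 0.1,
    seed: int = 0,
    n_folds: int = 10,
    drug_name: str | None = None,
) -> SelectedModel:
    """Marginal screen at |r| >= threshold, then elastic-net regression.

    An approximate re-implementation of the screen-then-elastic-net
    pipeline this package is compared against: mixing parameter on the
    grid 0.1..1.0, a 50-point penalty path, both chosen by seeded k-fold
    CV.  Reported coefficients are the elastic net's own (no OLS refit);
    the selected set is the nonzero-coefficient features.
    """
    yv = _as_array(y)
    name = drug_name or (y.drug_name if hasattr(y, "drug_name") else "response")
    r = marginal_correlations(X.values, yv)
    keep = np.flatnonzero(np.abs(r) >= screen_threshold)
    if keep.size == 0:
        raise ValueError(
            f"no features pass |r| >= {screen_threshold}; lower screen_threshold"
        )
    Xs, mean, std = _standardize(X.values[:, keep])
    model = ElasticNetCV(
        l1_ratio=[round(0.1 * i, 1) for i in range(1, 11)],
        alphas=50,
        cv=KFold(n_splits=n_folds, shuffle=True, random_state=seed),
        max_iter=20_000,
        n_jobs=None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, yv)
    coefs_std = model.coef_
    active_local = np.flatnonzero(coefs_std)
    final = [int(keep[j]) for j in active_local]
    coefs = coefs_std[active_local] / std[active_local]
    intercept = float(model.intercept_ - np.sum(coefs_std * mean / std))
    return SelectedModel(
        drug_name=name,
        d=len(final),
        final_set=final,
        feature_ids=[X.feature_ids[j] for j in final],
        feature_classes=[X.feature_class(j) for j in final],
        intercept=intercept,
        coefs=coefs,
        marginal_r=r[final] if final else np.empty(0),
        ols=None,
        trace=None,
        method="enr",
    )


@dataclass
class MethodComparison:
    models: dict[str, SelectedModel]
    cv: dict[str, CVResult]
    matched_m: int


def compare_methods(
    X: FeatureMatrix,
    y,
    d: int,
    methods: Sequence[str] = ("isis", "stf", "enr"),
    seed: int = 0,
    n_repeats: int = 10,
    n_folds: int = 10,
    screen_threshold: float = 0.1,
) -> MethodComparison:
    """Matched-size comparison of the iterative method against baselines.

    The STF model size is matched to the iterative method's realised
    |final_set| on the full data, as a fair like-for-like comparison
    requires.
    """
    yv = _as_array(y)
    models: dict[str, SelectedModel] = {}
    cv: dict[str, CVResult] = {}
    isis_model = isis_select(X, yv, d=d, seed=seed)
    m = max(1, isis_model.size)
    if "isis" in methods:
        models["isis"] = isis_model
        cv["isis"] = cross_validate(X, yv, d, n_repeats=n_repeats, n_folds=n_folds, seed=seed)
    if "stf" in methods:
        models["stf"] = stf_fit(X, yv, m)
        cv["stf"] = cross_validate(
            X, yv, d, n_repeats=n_repeats, n_folds=n_folds, seed=seed,
            fitter=lambda Xt, yt, s: stf_fit(Xt, yt, m),
        )
    if "enr" in methods:
        models["enr"] = enr_fit(X, yv, screen_threshold=screen_threshold, seed=seed)
        cv["enr"] = cross_validate(
            X, yv, d, n_repeats=n_repeats, n_folds=n_folds, seed=seed,
            fitter=lambda Xt, yt, s: enr_fit(Xt, yt, screen_threshold=screen_threshold, seed=s),
        )
    return MethodComparison(models=models, cv=cv, matched_m=m)


def plot_pcc_curve(selection: DSelection, path: str, drug: str = "") -> None:
    """CV correlation against candidate model size, chosen d marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ds = sorted(selection.grid)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ds, [selection.pcc_by_d[d] for d in ds], "o-", color="tab:blue")
    ax.plot(
        selection.chosen_d, selection.pcc_by_d[selection.chosen_d],
        "^", color="tab:red", markersize=10, label=f"chosen d = {selection.chosen_d}",
    )
    ax.set_xlabel("number of selected features d")
    ax.set_ylabel("CV Pearson correlation")
    if drug:
        ax.set_title(drug)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_method_comparison(pcc_by_method: dict[str, dict[str, float]], path: str) -> None:
    """Grouped bars of CV correlation per drug and method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as _np

    drugs = sorted(pcc_by_method)
    methods = sorted({m for d in pcc_by_method.values() for m in d})
    x = _np.arange(len(drugs))
    width = 0.8 / max(1, len(methods))
    fig, ax = plt.subplots(figsize=(max(5, 0.8 * len(drugs) + 2), 3.5))
    for i, m in enumerate(methods):
        vals = [pcc_by_method[d].get(m, _np.nan) for d in drugs]
        ax.bar(x + (i - (len(methods) - 1) / 2) * width, vals, width, label=m)
    ax.set_xticks(x)
    ax.set_xticklabels(drugs, rotation=45, ha="right")
    ax.set_ylabel("CV Pearson correlation")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_evaluation_report(comparison: MethodComparison, drug: str, path: str) -> None:
    """One row per method: realised size and CV correlation."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["drug", "method", "d", "n_selected", "cv_pcc"])
        for name, res in sorted(comparison.cv.items()):
            model = comparison.models[name]
            w.writerow([drug, name, res.d, model.size, f"{res.pcc:.10g}"])
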