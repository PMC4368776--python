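"""Coefficient significance, weak-marginal features, and redundancy scores.

A *marginally weak* feature has |Pearson r| < 0.1 with the response —
below the screening cutoff the elastic-net pipeline applies — yet can
carry a regression coefficient that a t-test declares nonzero at
alpha = 0.01.  Those features (weak marginal, significant joint) are the
headline class this package exists to surface.

Redundancy of a selected set is summarised by the mean redundancy score
(MRS): the mean pairwise similarity over unordered feature pairs, measured
either by |PCC| or by mutual information from equal-width binning.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .isis import SelectedModel
from .regression import OLSFit
from .screening import pearson_corr

WEAK_THRESHOLD = 0.1
ALPHA = 0.01


@dataclass
class CoefficientTest:
    feature_id: str
    coef: float
    se: float
    t_statistic: float
    p_value: float
    significant: bool
    marginal_r: float
    weak_marginal: bool
    exact_fit: bool = False


def coef_t_tests(
    ols: OLSFit,
    marginal_r: np.ndarray,
    feature_ids: list[str] | None = None,
    alpha: float = ALPHA,
    weak_threshold: float = WEAK_THRESHOLD,
) -> list[CoefficientTest]:
    """Two-sided t-test of H0: beta_j = 0 for every fitted coefficient.

    t_j = beta_j / SE_j with n - |M| - 1 degrees of freedom; this is the
    same test as the df-1 F-test of the nested model without x_j.  Features
    with |marginal_r| below ``weak_threshold`` are flagged weak-marginal.
    """
    if ols.df < 1:
        raise ValueError("no residual degrees of freedom")
    marginal_r = np.asarray(marginal_r, dtype=float)
    k = len(ols.coefs)
    ids = feature_ids if feature_ids is not None else [f"x{j}" for j in range(k)]
    out: list[CoefficientTest] = []
    for j in range(k):
        se = float(ols.standard_errors[j])
        b = float(ols.coefs[j])
        if se == 0.0 or ols.exact_fit:
            t = np.inf if b != 0 else 0.0
            p = 0.0 if b != 0 else 1.0
            exact = True
        else:
            t = b / se
            p = float(2.0 * stats.t.sf(abs(t), ols.df))
            exact = False
        out.append(
            CoefficientTest(
                feature_id=ids[j],
                coef=b,
                se=se,
                t_statistic=float(t),
                p_value=p,
                significant=p <= alpha,
                marginal_r=float(marginal_r[j]),
                weak_marginal=abs(marginal_r[j]) < weak_threshold,
                exact_fit=exact,
            )
        )
    return out


def weak_but_significant(tests: list[CoefficientTest]) -> list[CoefficientTest]:
    """The features a marginal screen discards but the joint model needs."""
    return [t for t in tests if t.weak_marginal and t.significant]


@dataclass
class RedundancyReport:
    method: str                  # "pcc" | "mi"
    pairwise: np.ndarray         # symmetric, zero diagonal
    mrs: float
    constant_flags: list[int]


def _binned(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin codes; binary columns keep their natural two bins."""
    uniq = np.unique(x)
    if uniq.size <= 2:
        return np.searchsorted(uniq, x)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in nats from the joint histogram of two code vectors."""
    joint = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(joint, (a, b), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mean_redundancy_score(
    X_selected: np.ndarray,
    method: str = "pcc",
    mi_bins: int = 10,
) -> RedundancyReport:
    """Mean pairwise similarity over the selected feature columns.

    ``pcc``: mean |Pearson correlation| over unordered pairs (in [0,1]).
    ``mi``: mean mutual information (nats) from ``mi_bins`` equal-width
    bins per variable.  A single feature scores 0 by convention; constant
    columns contribute 0 to their pairs and are flagged.
    """
    X = np.atleast_2d(np.asarray(X_selected, dtype=float))
    m = X.shape[1]
    if m < 1:
        raise ValueError("need at least one selected feature")
    if method not in ("pcc", "mi"):
        raise ValueError(f"unknown method {method!r}")
    pairwise = np.zeros((m, m))
    const = [j for j in range(m) if np.ptp(X[:, j]) == 0]
    if m == 1:
        return RedundancyReport(method=method, pairwise=pairwise, mrs=0.0, constant_flags=const)
    if method == "pcc":
        for j in range(m):
            for k in range(j + 1, m):
                v = abs(pearson_corr(X[:, j], X[:, k]))
                pairwise[j, k] = pairwise[k, j] = v
    else:
        codes = [_binned(X[:, j], mi_bins) for j in range(m)]
        for j in range(m):
            for k in range(j + 1, m):
                if j in const or k in const:
                    v = 0.0
                else:
                    v = _mutual_information(codes[j], codes[k])
                pairwise[j, k] = pairwise[k, j] = v
    iu = np.triu_indices(m, 1)
    return RedundancyReport(
        method=method,
        pairwise=pairwise,
        mrs=float(pairwise[iu].mean()),
        constant_flags=const,
    )


@dataclass
class PairedComparison:
    n_pairs: int
    mean_difference: float       # mean(a - b)
    t_statistic: float
    p_value: float
    differences: np.ndarray
    note: str = ""


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> PairedComparison:
    """Paired t-test on per-pair differences (a - b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length lists with at least 2 pairs")
    diff = a - b
    if np.all(diff == 0):
        return PairedComparison(a.size, 0.0, 0.0, 1.0, diff, note="no difference")
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(a.size, float(diff.mean()), float(t), float(p), diff)


def compare_mrs(
    models_a: list[SelectedModel],
    models_b: list[SelectedModel],
    X_values: np.ndarray | list[np.ndarray],
    method: str = "pcc",
) -> PairedComparison:
    """Paired t-test of redundancy between two matched model lists.

    Models are paired by position (same drug / same dataset); ``X_values``
    is either one shared design matrix or one matrix per pair.
    """
    if len(models_a) != len(models_b):
        raise ValueError("model lists must have equal length")
    if len(models_a) < 2:
        raise ValueError("need at least 2 pairs")
    mats = X_values if isinstance(X_values, list) else [X_values] * len(models_a)
    mrs_a = [mean_redundancy_score(m[:, ma.final_set], method).mrs for ma, m in zip(models_a, mats)]
    mrs_b = [mean_redundancy_score(m[:, mb.final_set], method).mrs for mb, m in zip(models_b, mats)]
    return paired_t(np.array(mrs_a), np.array(mrs_b))


REPORT_COLUMNS = (
    "feature_id",
    "class",
    "coef",
    "se",
    "t",
    "p",
    "marginal_r",
    "weak_marginal",
    "significant",
)


def write_model_report(model: SelectedModel, path: str) -> None:
    """TSV report: one row per selected feature, stable order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        if model.ols is None:
            return
        tests = coef_t_tests(model.ols, model.marginal_r, model.feature_ids)
        for cls, t in zip(model.feature_classes, tests):
            w.writerow(
                [
                    t.feature_id,
                    cls,
                    f"{t.coef:.10g}",
                    f"{t.se:.10g}",
                    f"{t.t_statistic:.10g}",
                    f"{t.p_value:.10g}",
                    f"{t.marginal_r:.10g}",
                    int(t.weak_marginal),
                    int(t.significant),
                ]
            )
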