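"""Marginal Pearson-correlation ranking (sure independence screening).

SIS ranks every feature by the absolute Pearson correlation of its column
with the response and keeps the top k.  It is the cheap first stage that
cuts an ultrahigh-dimensional feature space (p in the tens of thousands)
down to something a penalised regression can handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import FeatureMatrix


@dataclass
class ScreeningResult:
    recruited: list[int]          # indices ordered by decreasing |PCC|
    scores: np.ndarray            # |PCC| per recruited feature, non-increasing
    excluded: frozenset[int] = field(default_factory=frozenset)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; 0 for zero-variance input.

    Constant columns (e.g. an all-zero mutation gene inside a CV fold) are
    scored 0 rather than raising, so they simply never rank.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def marginal_correlations(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of ``values`` with ``y`` (vectorised)."""
    y = np.asarray(y, dtype=float)
    Xc = values - values.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    ss_y = yc @ yc
    denom = np.sqrt(ss_x * ss_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc.T @ yc) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def sis_screen(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    k: int,
    exclude: set[int] | frozenset[int] = frozenset(),
) -> ScreeningResult:
    """Recruit the k features with largest |PCC| against y.

    Ties break toward the lower feature index; excluded indices (already
    selected in earlier iterations) are masked out entirely.  Deterministic.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    p = values.shape[1]
    exclude = frozenset(exclude)
    avail = np.array([j for j in range(p) if j not in exclude])
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if avail.size == 0:
        raise ValueError("no features left after exclusion")
    r = marginal_correlations(values[:, avail], np.asarray(y, dtype=float))
    score = np.abs(r)
    if np.all(score == 0.0):
        raise ValueError("all remaining features are constant (or uncorrelated-degenerate)")
    k_eff = min(k, avail.size)
    # sort by (-score, index): stable lower-index-first tie-break
    order = np.lexsort((avail, -score))[:k_eff]
    recruited = avail[order]
    return ScreeningResult(
        recruited=[int(j) for j in recruited],
        scores=score[order],
        excluded=exclude,
    )
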