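"""Feature/response table handling and synthetic data generation.

Genomic features for a cell-line panel come in three blocks — gene
expression (continuous), mutation status (binary) and copy number
(continuous) — which are concatenated into a single samples x features
matrix with namespaced feature identifiers (``EXP:``, ``MUT:``, ``CNV:``).
The drug phenotype is the activity area (area under the 8-point
dose-response curve), one value per cell line per drug.

The synthetic generator emulates this structure and plants a sparse linear
signal that includes one *marginally weak* predictor: a feature whose
population covariance with the response is exactly zero by construction,
while its partial regression coefficient is substantial.  Marginal
screening cannot see such a feature; iterative screening on residuals can.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("expression", "mutation", "copynumber")
PREFIX = {"expression": "EXP:", "mutation": "MUT:", "copynumber": "CNV:"}

#: cell-line panel block proportions used to split p into (EXP, MUT, CNV)
_CCLE_BLOCK_COUNTS = (20069, 1667, 21217)

#: expression features are generated in equicorrelated sub-blocks this wide
EXPR_SUBBLOCK = 50


@dataclass
class FeatureBlock:
    """One genomic feature class: samples x features values with ids."""

    kind: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}; expected one of {KINDS}")
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.sample_ids, "sample_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.kind == "mutation":
            bad = ~np.isin(self.values, (0.0, 1.0))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"mutation value {self.values[i, j]!r} outside {{0,1}} at "
                    f"sample {self.sample_ids[i]!r}, gene {self.feature_ids[j]!r}"
                )


@dataclass
class FeatureMatrix:
    """Assembled n x p design matrix with globally unique namespaced ids."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.sample_ids, "sample_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match ids")
        if self.n < 2:
            raise ValueError(f"need at least 2 samples, got {self.n}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    def subset_samples(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx],
        )

    def column_index(self, feature_id: str) -> int:
        try:
            return self._id_index[feature_id]
        except AttributeError:
            self._id_index = {f: i for i, f in enumerate(self.feature_ids)}
            return self.column_index(feature_id)
        except KeyError:
            raise KeyError(f"feature id {feature_id!r} not present") from None

    def feature_class(self, j: int) -> str:
        fid = self.feature_ids[j]
        for kind, pre in PREFIX.items():
            if fid.startswith(pre):
                return kind
        return "unknown"


@dataclass
class ResponseVector:
    """Per-sample activity area for one drug."""

    drug_name: str
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample_ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("response length does not match sample_ids")
        if np.isnan(self.values).any():
            raise ValueError("response contains missing values after assembly")


@dataclass
class SyntheticTruth:
    """Planted signal for recovery scoring.

    ``weak_feature`` is a member of ``support`` whose population correlation
    with the response is zero by construction.
    """

    support: list[int]
    beta: dict[int, float]
    sigma: float
    weak_feature: int
    feature_ids: list[str] = field(default_factory=list)


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_feature_block(
    path: str,
    kind: str,
    orientation: str = "genes_by_samples",
    impute_mean: bool = False,
) -> FeatureBlock:
    """Read a delimited feature table and normalise to samples x features.

    Panel-style files are usually genes x cell-lines; ``orientation`` says
    which way the file on disk is laid out.  Missing cells are an error
    unless ``impute_mean`` is set, in which case each feature's mean fills
    the gaps (never for mutation blocks, whose values must be 0/1).
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for axis, what in ((df.index, "row ids"), (df.columns, "column ids")):
        dup = axis[axis.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate {what} in {path}: {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"non-numeric value {df[col].iloc[i]!r} at row "
                    f"{df.index[i]!r}, column {col!r} of {path}"
                ) from None
        raise
    if np.isnan(values).any():
        if impute_mean and kind != "mutation":
            if orientation == "genes_by_samples":
                means = np.nanmean(values, axis=1, keepdims=True)
                values = np.where(np.isnan(values), means, values)
            else:
                means = np.nanmean(values, axis=0, keepdims=True)
                values = np.where(np.isnan(values), means, values)
        else:
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at row {df.index[i]!r}, column {df.columns[j]!r} "
                f"of {path} (use impute_mean=True to mean-impute)"
            )
    if orientation == "genes_by_samples":
        feature_ids = df.index.tolist()
        sample_ids = df.columns.tolist()
        values = values.T
    else:
        feature_ids = df.columns.tolist()
        sample_ids = df.index.tolist()
    return FeatureBlock(kind=kind, feature_ids=feature_ids, sample_ids=sample_ids, values=values)


def write_feature_block(block: FeatureBlock, path: str, orientation: str = "genes_by_samples") -> None:
    """Write a block back to TSV/CSV; round-trips exactly through the loader."""
    df = pd.DataFrame(block.values, index=block.sample_ids, columns=block.feature_ids)
    if orientation == "genes_by_samples":
        df = df.T
    df.to_csv(path, sep=_sep_for(path))


def load_response_table(path: str) -> pd.DataFrame:
    """Read a cell-lines x drugs activity-area table."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate cell-line ids in {path}: {dup}")
    return df


def assemble(
    blocks: list[FeatureBlock],
    response: pd.DataFrame,
    drug: str,
) -> tuple[FeatureMatrix, ResponseVector]:
    """Join feature blocks and one drug's responses on the common samples.

    The sample set is the lexicographically sorted intersection of every
    block's samples and the response table's rows; samples lacking a
    response for ``drug`` are dropped (count logged).  Features are
    concatenated in expression, mutation, copynumber order with namespace
    prefixes.
    """
    if not blocks:
        raise ValueError("need at least one feature block")
    if drug not in response.columns:
        raise KeyError(
            f"drug {drug!r} not in response table; available: {list(response.columns)}"
        )
    common = set(response.index)
    for b in blocks:
        common &= set(b.sample_ids)
    if not common:
        raise ValueError("empty sample intersection across blocks and response table")
    resp = response.loc[sorted(common), drug]
    n_missing = int(resp.isna().sum())
    if n_missing:
        logger.warning("dropping %d samples with missing %s response", n_missing, drug)
        resp = resp.dropna()
    samples = sorted(resp.index)
    if len(samples) < 2:
        raise ValueError("fewer than 2 samples remain after intersection and response filter")

    ordered = sorted(blocks, key=lambda b: KINDS.index(b.kind))
    feature_ids: list[str] = []
    cols: list[np.ndarray] = []
    for b in ordered:
        row_of = {s: i for i, s in enumerate(b.sample_ids)}
        rows = np.array([row_of[s] for s in samples])
        feature_ids.extend(PREFIX[b.kind] + f for f in b.feature_ids)
        cols.append(b.values[rows])
    values = np.concatenate(cols, axis=1)
    if values.shape[1] == 0:
        raise ValueError("assembled matrix has zero features")
    X = FeatureMatrix(feature_ids=feature_ids, sample_ids=list(samples), values=values)
    y = ResponseVector(drug_name=drug, sample_ids=list(samples), values=resp.loc[samples].to_numpy())
    return X, y


def default_block_sizes(p: int) -> tuple[int, int, int]:
    """Split p into (expression, mutation, copynumber) at panel-like proportions."""
    total = sum(_CCLE_BLOCK_COUNTS)
    n_exp = max(1, round(p * _CCLE_BLOCK_COUNTS[0] / total))
    n_mut = max(1, round(p * _CCLE_BLOCK_COUNTS[1] / total))
    n_cnv = p - n_exp - n_mut
    if n_cnv < 1:
        raise ValueError(f"p={p} too small to split into three blocks")
    return n_exp, n_mut, n_cnv


def signal_variance(s_strong: int) -> float:
    """Population variance of the planted signal (strong + weak terms).

    With unit-variance independent strong predictors, unit coefficients,
    and the weak feature built as their sum plus unit-variance noise, the
    cancelling weak coefficient removes s^2/(s+1) of the raw signal
    variance s, leaving s/(s+1).
    """
    return s_strong / (s_strong + 1.0)


def sigma_for_r2(s_strong: int, r2: float) -> float:
    """Noise sd giving the requested population R^2 for the default construction."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0,1)")
    sv = signal_variance(s_strong)
    return float(np.sqrt(sv * (1.0 - r2) / r2))


def generate_synthetic(
    n: int = 400,
    p: int = 1000,
    s_strong: int = 3,
    rho: float = 0.5,
    sigma: float = 0.433,
    block_sizes: tuple[int, int, int] | None = None,
    seed: int = 0,
    mutation_rate: float = 0.1,
    expr_subblock: int = EXPR_SUBBLOCK,
) -> tuple[FeatureMatrix, ResponseVector, SyntheticTruth]:
    """Simulate a cell-line panel with a planted sparse signal.

    Expression-like features come in equicorrelated sub-blocks of width
    ``EXPR_SUBBLOCK`` with pairwise correlation ``rho``; mutation-like
    features are Bernoulli(``mutation_rate``); copy-number-like features
    are independent standard Gaussians.

    The ``s_strong`` strong predictors occupy the first column of distinct
    expression sub-blocks (so they are mutually independent in population
    for any ``rho``), each with coefficient 1.  One extra support member,
    the weak feature, is the sum of the strong predictors plus independent
    unit-variance noise; its coefficient is set to
    ``beta_w = -cov(x_w, sum_j x_j) / var(x_w) = -s/(s+1)`` so that
    ``cov(x_w, y) = 0`` exactly in population while its partial effect is
    far from zero.  The response is the linear signal plus
    Normal(0, sigma^2) noise.

    Same seed, same arguments -> bit-identical output.
    """
    if s_strong < 1:
        raise ValueError("s_strong must be >= 1")
    if p < s_strong + 1:
        raise ValueError("p must exceed s_strong")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if block_sizes is None:
        block_sizes = default_block_sizes(p)
    n_exp, n_mut, n_cnv = block_sizes
    if n_exp < 0 or n_mut < 0 or n_cnv < 0 or n_exp + n_mut + n_cnv != p:
        raise ValueError(f"block_sizes {block_sizes} must be non-negative and sum to p={p}")

    if expr_subblock < 1:
        raise ValueError("expr_subblock must be >= 1")
    n_sub = -(-n_exp // expr_subblock)  # ceil
    if s_strong + 1 > n_sub:
        raise ValueError(
            f"need {s_strong + 1} distinct expression sub-blocks for the support, "
            f"have {n_sub} (expression block of {n_exp} in widths of {expr_subblock})"
        )

    rng = np.random.default_rng(seed)

    # expression: equicorrelated sub-blocks, x = sqrt(rho) z_block + sqrt(1-rho) e
    expr = np.empty((n, n_exp))
    for b in range(n_sub):
        lo, hi = b * expr_subblock, min((b + 1) * expr_subblock, n_exp)
        z = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, hi - lo))
        expr[:, lo:hi] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * e
    mut = (rng.random((n, n_mut)) < mutation_rate).astype(float)
    cnv = rng.standard_normal((n, n_cnv))

    # strong predictors head distinct sub-blocks: exactly N(0,1), mutually
    # independent for any rho, yet each drags rho-correlated neighbours up
    # the marginal ranking — the redundancy a pure top-k list falls for
    strong_cols = [b * expr_subblock for b in range(s_strong)]
    weak_col = s_strong * expr_subblock

    g = expr[:, strong_cols].sum(axis=1)  # unit coefficients
    eta = rng.standard_normal(n)
    x_w = g + eta
    expr[:, weak_col] = x_w
    var_w = s_strong + 1.0  # population var of x_w
    beta_w = -s_strong / var_w  # kills cov(x_w, y) exactly

    eps = rng.standard_normal(n)
    y = g + beta_w * x_w + sigma * eps

    values = np.concatenate([expr, mut, cnv], axis=1)
    feature_ids = (
        [f"EXP:g{j + 1}" for j in range(n_exp)]
        + [f"MUT:g{j + 1}" for j in range(n_mut)]
        + [f"CNV:g{j + 1}" for j in range(n_cnv)]
    )
    sample_ids = [f"cell_{i + 1:04d}" for i in range(n)]
    X = FeatureMatrix(feature_ids=feature_ids, sample_ids=sample_ids, values=values)
    yv = ResponseVector(drug_name="synthetic_drug", sample_ids=list(sample_ids), values=y)
    beta = {c: 1.0 for c in strong_cols}
    beta[weak_col] = beta_w
    truth = SyntheticTruth(
        support=sorted(strong_cols + [weak_col]),
        beta=beta,
        sigma=float(sigma),
        weak_feature=weak_col,
        feature_ids=[feature_ids[j] for j in sorted(strong_cols + [weak_col])],
    )
    return X, yv, truth
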