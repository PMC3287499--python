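"""Phenotype-correlated gene-set selection and first-component projection.

Genes are ranked by the absolute Spearman correlation of their expression
with the binary endpoint; the gene set is then fixed by scanning prefixes of
that ranking and keeping the prefix whose first principal component carries
the largest share of the total variance (the variance-contribution rate,
lambda_1 / sum lambda).  Samples are finally projected onto that component.

`CorrelatedGeneSelector` wraps the procedure as a scikit-learn transformer
(X is samples x genes there); the module-level functions operate on the
genes x rows :class:`~condegree.containers.ExpressionMatrix` convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .containers import ExpressionMatrix
from .errors import DegenerateInputError, UndefinedCorrelationError, ValidationError

log = logging.getLogger("condegree.selection")

__all__ = [
    "RankedGeneList",
    "GeneSetSelection",
    "SampleScores",
    "spearman_rho",
    "rank_genes",
    "pc1_contribution",
    "select_geneset",
    "project_pc1",
    "CorrelatedGeneSelector",
]


@dataclass
class RankedGeneList:
    """Genes ordered by |rho| descending, ties broken by gene id."""

    gene_ids: list[str]
    rho: np.ndarray


@dataclass
class GeneSetSelection:
    """A prefix of the ranking together with its PC1 variance contribution."""

    gene_ids: list[str]
    prefix_size: int
    contribution: float
    scanned_sizes: np.ndarray
    contribution_curve: np.ndarray


@dataclass
class SampleScores:
    """First-principal-component coordinate per sample."""

    sample_ids: list[str]
    score: np.ndarray


def spearman_rho(x, y) -> float:
    """Midrank-based Spearman correlation (y may be binary)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(np.clip(((rx - rx.mean()) @ (ry - ry.mean())) / (x.size * sx * sy), -1, 1))


def _rank_rows(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised |rho| ranking helper: returns (rho per row, keep mask)."""
    keep = values.std(axis=1) > 0.0
    rx = rankdata(values, axis=1)
    ry = rankdata(y)
    sy = ry.std()
    if sy == 0.0:
        raise DegenerateInputError("labels are constant")
    rxc = rx - rx.mean(axis=1, keepdims=True)
    sx = rx.std(axis=1)
    sx[~keep] = 1.0  # avoid divide warnings; masked out below
    rho = (rxc @ (ry - ry.mean())) / (values.shape[1] * sx * sy)
    return np.clip(rho, -1.0, 1.0), keep


def rank_genes(expr: ExpressionMatrix, labels) -> RankedGeneList:
    """Order genes by |Spearman rho| with the endpoint, descending.

    Constant genes are dropped (logged); ties broken lexicographically on the
    gene identifier.
    """
    y = np.asarray(labels, dtype=float).ravel()
    if y.size != expr.n_samples:
        raise ValidationError("label vector length != number of samples")
    if y.size < 3:
        raise ValidationError("need at least 3 samples")
    rho, keep = _rank_rows(expr.values, y)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        log.info("dropping %d constant gene(s) from the ranking", n_dropped)
    if not keep.any():
        raise DegenerateInputError("all genes are constant")
    ids = np.asarray(expr.gene_ids, dtype=object)[keep]
    rho = rho[keep]
    order = np.lexsort((ids, -np.abs(rho)))
    return RankedGeneList([str(g) for g in ids[order]], rho[order])


def _median_sq_dist(X: np.ndarray) -> float:
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    tri = d2[np.triu_indices_from(d2, k=1)]
    tri = tri[tri > 0]
    if tri.size == 0:
        raise DegenerateInputError("all samples identical; RBF bandwidth undefined")
    return float(np.median(tri))


def pc1_contribution(
    sub: np.ndarray,
    kernel: str = "linear",
    scale: bool = False,
    gamma: float | None = None,
) -> float:
    """Variance-contribution rate of the first principal component.

    ``sub`` is samples x genes; columns are mean-centred internally (and
    optionally unit-scaled).  For the RBF kernel the rate is the leading
    eigenvalue share of the centred kernel matrix; the default bandwidth is
    the median-pairwise-squared-distance heuristic.
    """
    X = np.asarray(sub, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("need a samples x k matrix with k >= 2")
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 samples")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        sd[sd == 0.0] = 1.0
        Xc = Xc / sd
    if kernel == "linear":
        sv = np.linalg.svd(Xc, compute_uv=False)
        lam = sv**2
        total = lam.sum()
        if total <= 0.0:
            raise DegenerateInputError("zero total variance")
        return float(lam[0] / total)
    if kernel == "rbf":
        if gamma is None:
            gamma = 1.0 / (2.0 * _median_sq_dist(Xc))
        d2 = (
            np.sum(Xc**2, axis=1)[:, None]
            + np.sum(Xc**2, axis=1)[None, :]
            - 2.0 * Xc @ Xc.T
        )
        K = np.exp(-gamma * np.clip(d2, 0.0, None))
        m = K.shape[0]
        H = np.eye(m) - np.ones((m, m)) / m
        lam = np.linalg.eigvalsh(H @ K @ H)
        lam = np.clip(lam, 0.0, None)
        total = lam.sum()
        if total <= 0.0:
            raise DegenerateInputError("zero total variance in kernel space")
        return float(lam[-1] / total)
    raise ValidationError(f"unknown kernel {kernel!r}")


def select_geneset(
    expr: ExpressionMatrix,
    labels,
    k_min: int = 5,
    k_max: int | None = None,
    step: int = 1,
    kernel: str = "linear",
    scale: bool = False,
) -> GeneSetSelection:
    """Fix the correlated gene set by maximising the PC1 contribution over
    prefixes of the |rho| ranking.  Ties go to the smallest prefix."""
    ranked = rank_genes(expr, labels)
    n_ranked = len(ranked.gene_ids)
    if n_ranked < k_min:
        raise DegenerateInputError(
            f"only {n_ranked} usable genes, fewer than k_min={k_min}"
        )
    if k_max is None:
        k_max = min(500, n_ranked)
    k_max = min(k_max, n_ranked)
    if k_max < k_min:
        raise ValidationError("k_max < k_min")
    sub_all = expr.subset_genes(ranked.gene_ids).values.T  # samples x ranked genes
    sizes = np.arange(k_min, k_max + 1, step)
    curve = np.empty(sizes.size)
    for i, k in enumerate(sizes):
        curve[i] = pc1_contribution(sub_all[:, :k], kernel=kernel, scale=scale)
    best = int(np.argmax(curve))  # first occurrence -> smallest prefix on ties
    k_best = int(sizes[best])
    return GeneSetSelection(
        gene_ids=ranked.gene_ids[:k_best],
        prefix_size=k_best,
        contribution=float(curve[best]),
        scanned_sizes=sizes,
        contribution_curve=curve,
    )


def _project(X: np.ndarray, y: np.ndarray, scale: bool = False) -> np.ndarray:
    """PC1 scores of samples x genes ``X``, oriented so the class-1 mean
    score is >= the class-0 mean score."""
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        sd[sd == 0.0] = 1.0
        Xc = Xc / sd
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[0]
    m1 = scores[y == 1].mean()
    m0 = scores[y == 0].mean()
    if m1 < m0:
        scores = -scores
    elif m1 == m0 and scores[np.argmax(np.abs(scores))] < 0:
        # degenerate orientation: fall back to a fixed sign convention
        scores = -scores
    return scores


def project_pc1(
    expr: ExpressionMatrix,
    selection: GeneSetSelection,
    labels,
    scale: bool = False,
) -> SampleScores:
    """Per-sample coordinate on the first component of the selected genes."""
    y = np.asarray(labels, dtype=float).ravel()
    X = expr.subset_genes(selection.gene_ids).values.T
    return SampleScores(list(expr.sample_ids), _project(X, y, scale=scale))


class CorrelatedGeneSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer for the rank-and-scan gene selection.

    Parameters
    ----------
    k_min, k_max, step : prefix-scan bounds over the |rho| ranking
        (k_max=None means min(500, n usable genes)).
    kernel : {"linear", "rbf"}
        PCA flavour used for the variance-contribution rate.
    scale : bool
        Unit-scale columns before PCA (off by default: scaling distorts the
        contribution rate the scan maximises).

    Attributes
    ----------
    rho_ : |rho|-ranking correlation per kept feature (ranking order)
    order_ : column indices of X in ranking order
    prefix_size_, contribution_, contribution_curve_, scanned_sizes_
    support_mask_ : boolean mask over input features
    """

    def __init__(self, k_min=5, k_max=None, step=1, kernel="linear", scale=False):
        self.k_min = k_min
        self.k_max = k_max
        self.step = step
        self.kernel = kernel
        self.scale = scale

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        yb = np.asarray(y, dtype=float)
        rho, keep = _rank_rows(X.T, yb)
        if not keep.any():
            raise DegenerateInputError("all features are constant")
        idx = np.flatnonzero(keep)
        order = idx[np.lexsort((idx, -np.abs(rho[keep])))]
        n_ranked = order.size
        if n_ranked < self.k_min:
            raise DegenerateInputError(
                f"only {n_ranked} usable features, fewer than k_min={self.k_min}"
            )
        k_max = min(500, n_ranked) if self.k_max is None else min(self.k_max, n_ranked)
        sizes = np.arange(self.k_min, k_max + 1, self.step)
        curve = np.empty(sizes.size)
        for i, k in enumerate(sizes):
            curve[i] = pc1_contribution(
                X[:, order[:k]], kernel=self.kernel, scale=self.scale
            )
        best = int(np.argmax(curve))
        self.order_ = order
        self.rho_ = rho[order]
        self.prefix_size_ = int(sizes[best])
        self.contribution_ = float(curve[best])
        self.scanned_sizes_ = sizes
        self.contribution_curve_ = curve
        self.selected_idx_ = order[: self.prefix_size_]
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[self.selected_idx_] = True
        self.support_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def project(self, X, y):
        """PC1 scores on the selected features (class-1 mean oriented up)."""
        check_is_fitted(self, "support_mask_")
        X = np.asarray(X, dtype=float)
        return _project(X[:, self.selected_idx_], np.asarray(y), scale=self.scale)
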