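"""The consistency degree of a binary endpoint.

Pipeline: select the endpoint-correlated gene set, project samples onto the
first principal component, arrange the scores as the class-0 block followed
by the class-1 block, and bootstrap within classes: each replicate resamples
scores with replacement inside each class (class sizes preserved), randomly
orders them within the blocks, runs the change-point sampler, and records
the posterior change probability at the class boundary.  The consistency
degree is the median of those boundary posteriors — a probability in [0, 1]
measuring how coherently the endpoint partitions the expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_X_y

from . import _bh_kernel as _k
from .changepoint import BHParams, ChangePointPosterior
from .containers import ExpressionMatrix
from .errors import DegenerateInputError, ValidationError
from .selection import CorrelatedGeneSelector, GeneSetSelection

__all__ = ["ConsistencyConfig", "ConsistencyResult", "ConsistencyScorer", "consistency_degree"]


@dataclass
class ConsistencyConfig:
    """Configuration for :func:`consistency_degree`."""

    bootstrap_reps: int = 10_000
    engine: BHParams = field(default_factory=BHParams)
    k_min: int = 5
    k_max: int | None = None
    step: int = 1
    kernel: str = "linear"
    scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")


@dataclass
class ConsistencyResult:
    """The consistency degree with its bootstrap distribution."""

    degree: float
    bootstrap_values: np.ndarray
    selection: GeneSetSelection
    boundary: int
    scores: np.ndarray
    sample_ids: list[str]
    posterior: ChangePointPosterior
    ordering: np.ndarray  # sample positions of the class-ordered series


class ConsistencyScorer(BaseEstimator):
    """scikit-learn estimator computing the consistency degree.

    ``fit(X, y)`` takes a samples x genes matrix and binary labels; the
    statistic ends up in ``degree_``.

    Parameters mirror :class:`ConsistencyConfig`; ``random_state`` seeds the
    bootstrap resampling and every sampler chain (counter-based per-replicate
    streams, so runs are reproducible and replicate-order independent).

    Attributes
    ----------
    degree_ : float
        Median bootstrap boundary posterior — the consistency degree.
    bootstrap_values_ : ndarray of shape (bootstrap_reps,)
    boundary_ : int
        1-based boundary position (= class-0 count) in the ordered series.
    prefix_size_, contribution_, contribution_curve_, selected_idx_
        Gene-selection results (see :class:`CorrelatedGeneSelector`).
    scores_ : ndarray
        PC1 scores in input sample order.
    posterior_ : ChangePointPosterior
        Single-chain posterior on the class-ordered (non-resampled) series,
        for reporting and unpredictable-sample placement.
    ordering_ : ndarray
        Input-sample positions forming the class-ordered series.
    """

    def __init__(
        self,
        k_min=5,
        k_max=None,
        step=1,
        kernel="linear",
        scale=False,
        bootstrap_reps=10_000,
        p0=0.2,
        w0=0.2,
        burnin=50,
        sweeps=500,
        random_state=None,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.step = step
        self.kernel = kernel
        self.scale = scale
        self.bootstrap_reps = bootstrap_reps
        self.p0 = p0
        self.w0 = w0
        self.burnin = burnin
        self.sweeps = sweeps
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if not np.all(np.isin(classes, [0, 1])) or classes.size != 2:
            raise ValidationError("labels must contain both classes, coded 0/1")
        n0 = int(np.sum(y == 0))
        n1 = int(np.sum(y == 1))
        if n0 < 2 or n1 < 2:
            raise DegenerateInputError(
                f"need >= 2 samples per class (got {n0} / {n1})"
            )
        if self.bootstrap_reps < 1:
            raise ValidationError("bootstrap_reps must be >= 1")

        selector = CorrelatedGeneSelector(
            k_min=self.k_min,
            k_max=self.k_max,
            step=self.step,
            kernel=self.kernel,
            scale=self.scale,
        ).fit(X, y)
        scores = selector.project(X, y)

        idx0 = np.flatnonzero(y == 0)
        idx1 = np.flatnonzero(y == 1)
        ordering = np.concatenate([idx0, idx1])
        s0 = scores[idx0]
        s1 = scores[idx1]
        n = n0 + n1
        boundary = n0

        seed = 0 if self.random_state is None else int(self.random_state)
        ss = np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss.spawn(1)[0])
        reps = int(self.bootstrap_reps)

        # replicate series: within-class resampling, then random within-block order
        draw0 = rng.integers(0, n0, size=(reps, n0))
        draw1 = rng.integers(0, n1, size=(reps, n1))
        series = np.empty((reps, n))
        series[:, :n0] = rng.permuted(s0[draw0], axis=1)
        series[:, n0:] = rng.permuted(s1[draw1], axis=1)

        chain_seeds = ss.generate_state(reps + 1).astype(np.int64) % (2**31)
        tab = _k.engine_tables(n, float(self.p0), float(self.w0))
        boots = _k.gibbs_boundary_batch(
            series, chain_seeds[:reps], boundary, tab, int(self.burnin), int(self.sweeps)
        )

        full_series = np.concatenate([s0, s1])
        cp, pm = _k.gibbs_run(
            full_series, int(chain_seeds[reps]), tab, int(self.burnin), int(self.sweeps)
        )

        self.selector_ = selector
        self.prefix_size_ = selector.prefix_size_
        self.contribution_ = selector.contribution_
        self.contribution_curve_ = selector.contribution_curve_
        self.scanned_sizes_ = selector.scanned_sizes_
        self.selected_idx_ = selector.selected_idx_
        self.scores_ = scores
        self.ordering_ = ordering
        self.boundary_ = boundary
        self.bootstrap_values_ = boots
        self.degree_ = float(np.median(boots))
        self.posterior_ = ChangePointPosterior(cp, pm)
        self.n_features_in_ = X.shape[1]
        return self

    def score(self, X=None, y=None):
        """The fitted consistency degree (refitting is the caller's job)."""
        check_is_fitted(self, "degree_")
        return self.degree_


def consistency_degree(
    expr: ExpressionMatrix, labels, cfg: ConsistencyConfig | None = None
) -> ConsistencyResult:
    """Consistency degree of a binary endpoint on an expression matrix.

    ``labels`` must be aligned with ``expr.sample_ids`` (see
    :func:`condegree.containers.align`).
    """
    cfg = cfg or ConsistencyConfig()
    scorer = ConsistencyScorer(
        k_min=cfg.k_min,
        k_max=cfg.k_max,
        step=cfg.step,
        kernel=cfg.kernel,
        scale=cfg.scale,
        bootstrap_reps=cfg.bootstrap_reps,
        p0=cfg.engine.p0,
        w0=cfg.engine.w0,
        burnin=cfg.engine.burnin,
        sweeps=cfg.engine.sweeps,
        random_state=cfg.seed,
    ).fit(expr.values.T, np.asarray(labels))
    sel = GeneSetSelection(
        gene_ids=[expr.gene_ids[i] for i in scorer.selected_idx_],
        prefix_size=scorer.prefix_size_,
        contribution=scorer.contribution_,
        scanned_sizes=scorer.scanned_sizes_,
        contribution_curve=scorer.contribution_curve_,
    )
    return ConsistencyResult(
        degree=scorer.degree_,
        bootstrap_values=scorer.bootstrap_values_,
        selection=sel,
        boundary=scorer.boundary_,
        scores=scorer.scores_,
        sample_ids=list(expr.sample_ids),
        posterior=scorer.posterior_,
        ordering=scorer.ordering_,
    )
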