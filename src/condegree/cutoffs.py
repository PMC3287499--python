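"""Survival milestone redefinition by consistency-degree maximisation.

A milestone endpoint dichotomises survival at a day cutoff: positive = event
by the cutoff, negative = event-free with follow-up at least the cutoff;
samples censored before the cutoff are excluded.  Any observed time is a
candidate cutoff; each candidate's consistency degree is computed and the
argmax redefines the endpoint.  Significance comes from an upper-tail
binomial enrichment test on how often the chosen cutoff recurs among
bootstrap re-definitions (null success probability 1/N over the N candidate
cutoffs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .changepoint import BHParams
from .consistency import ConsistencyConfig, ConsistencyScorer
from .containers import ClinicalTable, ExpressionMatrix
from .errors import DegenerateInputError, ValidationError

log = logging.getLogger("condegree.cutoffs")

__all__ = [
    "MilestoneLabeling",
    "CutoffScan",
    "EnrichmentResult",
    "milestone_labels",
    "candidate_cutoffs",
    "scan_cutoffs",
    "bootstrap_cutoff_recurrence",
    "enrichment_pvalue",
    "MilestoneCutoffScanner",
]


@dataclass
class MilestoneLabeling:
    """Binary milestone labels at one cutoff (NaN = excluded)."""

    cutoff: float
    labels: pd.Series  # 1.0 / 0.0 / NaN, indexed by sample id
    excluded_ids: list[str]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)


@dataclass
class CutoffScan:
    """Consistency degree per candidate cutoff, with the argmax."""

    candidates: np.ndarray
    degree_at: np.ndarray
    best_cutoff: float
    best_degree: float
    n_labeled: np.ndarray

    @property
    def n_candidates(self) -> int:
        return self.candidates.size


@dataclass
class EnrichmentResult:
    """Upper-tail binomial enrichment of the chosen cutoff's recurrence."""

    k: int
    n: int
    N: int
    pvalue: float

    @property
    def p_null(self) -> float:
        return 1.0 / self.N

    @property
    def s(self) -> float:
        """The significance level scaled by the null probability (the tail
        probability equals s x p_null in the construction)."""
        return self.pvalue / self.p_null


def _survival_arrays(
    times, events
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if np.isnan(t).any() or np.isnan(e).any():
        raise ValidationError("survival times/events contain missing values")
    if (t < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(e, [0, 1]).all():
        raise ValidationError("event indicator outside {0, 1}")
    return t, e.astype(int)


def _milestone_vector(t: np.ndarray, e: np.ndarray, cutoff: float) -> np.ndarray:
    """1 = event by cutoff, 0 = follow-up past cutoff, NaN = censored early.

    A death exactly at the cutoff counts as an event by the milestone.
    """
    lab = np.full(t.size, np.nan)
    lab[(e == 1) & (t <= cutoff)] = 1.0
    lab[np.isnan(lab) & (t >= cutoff)] = 0.0
    return lab


def milestone_labels(clin: ClinicalTable, cutoff: float) -> MilestoneLabeling:
    """Milestone endpoint labels at ``cutoff`` days."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    times, events = clin.survival()
    t, e = _survival_arrays(times.to_numpy(), events.to_numpy())
    lab = _milestone_vector(t, e, cutoff)
    series = pd.Series(lab, index=times.index)
    excluded = [str(s) for s in series.index[series.isna()]]
    return MilestoneLabeling(cutoff=float(cutoff), labels=series, excluded_ids=excluded)


def candidate_cutoffs(
    clin: ClinicalTable, min_per_class: int = 10, max_candidates: int | None = None
) -> np.ndarray:
    """Distinct observed times yielding at least ``min_per_class`` samples in
    each milestone class, ascending; optionally thinned to an evenly spaced
    subset of ``max_candidates`` (the degree-vs-cutoff curve is smooth)."""
    times, events = clin.survival()
    t, e = _survival_arrays(times.to_numpy(), events.to_numpy())
    cands = []
    for c in np.unique(t):
        if c <= 0:
            continue
        lab = _milestone_vector(t, e, c)
        if np.nansum(lab == 1) >= min_per_class and np.nansum(lab == 0) >= min_per_class:
            cands.append(c)
    if not cands:
        raise DegenerateInputError(
            f"no cutoff yields >= {min_per_class} samples per milestone class"
        )
    cands = np.asarray(cands, dtype=float)
    if max_candidates is not None and cands.size > max_candidates:
        idx = np.unique(np.linspace(0, cands.size - 1, max_candidates).round().astype(int))
        cands = cands[idx]
    return cands


def _scan_arrays(
    X: np.ndarray,
    t: np.ndarray,
    e: np.ndarray,
    cands: np.ndarray,
    scorer_kwargs: dict,
    seed: int,
) -> CutoffScan:
    """Core scan on samples x genes arrays; shared seed across candidates."""
    degrees = np.empty(cands.size)
    n_labeled = np.empty(cands.size, dtype=int)
    for i, c in enumerate(cands):
        lab = _milestone_vector(t, e, c)
        keep = ~np.isnan(lab)
        y = lab[keep].astype(int)
        scorer = ConsistencyScorer(random_state=seed, **scorer_kwargs)
        scorer.fit(X[keep], y)
        degrees[i] = scorer.degree_
        n_labeled[i] = int(keep.sum())
    best = int(np.argmax(degrees))  # first max -> smallest cutoff on ties
    return CutoffScan(
        candidates=cands,
        degree_at=degrees,
        best_cutoff=float(cands[best]),
        best_degree=float(degrees[best]),
        n_labeled=n_labeled,
    )


@dataclass
class ScanConfig:
    """Cutoff-scan configuration (reduced engine settings for throughput;
    the final chosen cutoff should be re-scored at full settings)."""

    min_per_class: int = 10
    max_candidates: int | None = 25
    scan_reps: int = 200
    final_reps: int = 10_000
    sweeps: int = 150
    burnin: int = 30
    p0: float = 0.2
    w0: float = 0.2
    k_min: int = 5
    k_max: int | None = None
    step: int = 1
    kernel: str = "linear"
    scale: bool = False
    match_window: float = 0.0
    seed: int = 0

    def scorer_kwargs(self, reps: int | None = None) -> dict:
        return dict(
            k_min=self.k_min,
            k_max=self.k_max,
            step=self.step,
            kernel=self.kernel,
            scale=self.scale,
            bootstrap_reps=self.scan_reps if reps is None else reps,
            p0=self.p0,
            w0=self.w0,
            burnin=self.burnin,
            sweeps=self.sweeps,
        )


def scan_cutoffs(
    expr: ExpressionMatrix, clin: ClinicalTable, cfg: ScanConfig | None = None
) -> CutoffScan:
    """Consistency degree for every candidate cutoff; argmax redefines the
    endpoint (ties go to the smallest cutoff)."""
    cfg = cfg or ScanConfig()
    times, events = clin.survival()
    shared = [s for s in expr.sample_ids if s in set(times.index)]
    if not shared:
        raise DegenerateInputError("no samples shared between matrix and clinical table")
    sub = expr.subset_samples(shared)
    t, e = _survival_arrays(times.loc[shared].to_numpy(), events.loc[shared].to_numpy())
    sub_clin = ClinicalTable(
        pd.DataFrame({"days": t, "event": e}, index=shared),
        time_col="days",
        event_col="event",
    )
    cands = candidate_cutoffs(sub_clin, cfg.min_per_class, cfg.max_candidates)
    return _scan_arrays(sub.values.T, t, e, cands, cfg.scorer_kwargs(), cfg.seed)


def rescore_cutoff(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    cutoff: float,
    cfg: ScanConfig | None = None,
) -> float:
    """Consistency degree of one milestone cutoff at full bootstrap reps."""
    cfg = cfg or ScanConfig()
    times, events = clin.survival()
    shared = [s for s in expr.sample_ids if s in set(times.index)]
    sub = expr.subset_samples(shared)
    t, e = _survival_arrays(times.loc[shared].to_numpy(), events.loc[shared].to_numpy())
    lab = _milestone_vector(t, e, cutoff)
    keep = ~np.isnan(lab)
    scorer = ConsistencyScorer(
        random_state=cfg.seed, **cfg.scorer_kwargs(reps=cfg.final_reps)
    ).fit(sub.values.T[keep], lab[keep].astype(int))
    return scorer.degree_


def bootstrap_cutoff_recurrence(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    cfg: ScanConfig | None = None,
    n: int = 1000,
    best_cutoff: float | None = None,
) -> EnrichmentResult:
    """Re-derive the cutoff on ``n`` sample bootstraps and count recurrences.

    ``k`` counts resamples whose redefined cutoff matches the original best
    (within ``cfg.match_window`` days; 0 = exact).  N is the original number
    of candidate cutoffs, so the enrichment null adapts to the grid.
    """
    cfg = cfg or ScanConfig()
    if n < 1:
        raise ValidationError("n must be >= 1")
    times, events = clin.survival()
    shared = [s for s in expr.sample_ids if s in set(times.index)]
    sub = expr.subset_samples(shared)
    t, e = _survival_arrays(times.loc[shared].to_numpy(), events.loc[shared].to_numpy())
    X = sub.values.T
    m = len(shared)

    def _cands(tt, ee):
        c = []
        for cut in np.unique(tt):
            if cut <= 0:
                continue
            lab = _milestone_vector(tt, ee, cut)
            if (
                np.nansum(lab == 1) >= cfg.min_per_class
                and np.nansum(lab == 0) >= cfg.min_per_class
            ):
                c.append(cut)
        c = np.asarray(c, dtype=float)
        if cfg.max_candidates is not None and c.size > cfg.max_candidates:
            idx = np.unique(
                np.linspace(0, c.size - 1, cfg.max_candidates).round().astype(int)
            )
            c = c[idx]
        return c

    base_cands = _cands(t, e)
    if base_cands.size == 0:
        raise DegenerateInputError("empty candidate set")
    if best_cutoff is None:
        base = _scan_arrays(X, t, e, base_cands, cfg.scorer_kwargs(), cfg.seed)
        best_cutoff = base.best_cutoff

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2**20]))
    k = 0
    skipped = 0
    for r in range(n):
        take = rng.integers(0, m, size=m)
        tt, ee = t[take], e[take]
        cands_r = _cands(tt, ee)
        if cands_r.size == 0:
            skipped += 1
            continue
        scan_r = _scan_arrays(
            X[take], tt, ee, cands_r, cfg.scorer_kwargs(), int(rng.integers(2**31))
        )
        if abs(scan_r.best_cutoff - best_cutoff) <= cfg.match_window:
            k += 1
    if skipped:
        log.info("%d bootstrap resamples had no admissible cutoff", skipped)
    return EnrichmentResult(
        k=k, n=n, N=int(base_cands.size), pvalue=enrichment_pvalue(k, n, base_cands.size)
    )


def enrichment_pvalue(k: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Binomial(n, 1/N): the probability that a uniformly
    drawn cutoff recurs at least k times in n re-definitions."""
    k, n, N = int(k), int(n), int(N)
    if N < 1 or n < 0 or not (0 <= k <= n):
        raise ValidationError(f"invalid counts k={k}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, 1.0 / N))


class MilestoneCutoffScanner(BaseEstimator):
    """scikit-learn estimator redefining a survival milestone endpoint.

    ``fit(X, y)`` takes samples x genes expression and survival outcomes
    (``y`` either a structured array with 'time'/'days' and 'event' fields,
    a (time, event) tuple of arrays, or a 2-column array).

    Attributes
    ----------
    candidates_, degrees_, n_labeled_ : the scan curve
    best_cutoff_, best_degree_ : the argmax (smallest cutoff on ties)
    final_degree_ : best cutoff re-scored at ``final_reps`` bootstrap reps
    """

    def __init__(
        self,
        min_per_class=10,
        max_candidates=25,
        scan_reps=200,
        final_reps=10_000,
        sweeps=150,
        burnin=30,
        p0=0.2,
        w0=0.2,
        k_min=5,
        k_max=None,
        step=1,
        kernel="linear",
        scale=False,
        match_window=0.0,
        random_state=None,
    ):
        self.min_per_class = min_per_class
        self.max_candidates = max_candidates
        self.scan_reps = scan_reps
        self.final_reps = final_reps
        self.sweeps = sweeps
        self.burnin = burnin
        self.p0 = p0
        self.w0 = w0
        self.k_min = k_min
        self.k_max = k_max
        self.step = step
        self.kernel = kernel
        self.scale = scale
        self.match_window = match_window
        self.random_state = random_state

    def _cfg(self) -> ScanConfig:
        return ScanConfig(
            min_per_class=self.min_per_class,
            max_candidates=self.max_candidates,
            scan_reps=self.scan_reps,
            final_reps=self.final_reps,
            sweeps=self.sweeps,
            burnin=self.burnin,
            p0=self.p0,
            w0=self.w0,
            k_min=self.k_min,
            k_max=self.k_max,
            step=self.step,
            kernel=self.kernel,
            scale=self.scale,
            match_window=self.match_window,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    @staticmethod
    def _unpack_y(y) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(y, tuple) and len(y) == 2:
            return _survival_arrays(y[0], y[1])
        arr = np.asarray(y)
        if arr.dtype.names:
            names = {n.lower(): n for n in arr.dtype.names}
            tname = names.get("time") or names.get("days")
            ename = names.get("event")
            if not tname or not ename:
                raise ValidationError("structured y needs 'time'/'days' and 'event'")
            return _survival_arrays(
                arr[tname].astype(float), arr[ename].astype(float)
            )
        if arr.ndim == 2 and arr.shape[1] == 2:
            return _survival_arrays(arr[:, 0], arr[:, 1])
        raise ValidationError("y must carry survival time and event status")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        t, e = self._unpack_y(y)
        if X.shape[0] != t.size:
            raise ValidationError("X rows and survival records must match")
        cfg = self._cfg()
        clin = ClinicalTable(
            pd.DataFrame(
                {"days": t, "event": e},
                index=[f"r{i}" for i in range(t.size)],
            ),
            time_col="days",
            event_col="event",
        )
        cands = candidate_cutoffs(clin, cfg.min_per_class, cfg.max_candidates)
        scan = _scan_arrays(X, t, e, cands, cfg.scorer_kwargs(), cfg.seed)
        self.candidates_ = scan.candidates
        self.degrees_ = scan.degree_at
        self.n_labeled_ = scan.n_labeled
        self.best_cutoff_ = scan.best_cutoff
        self.best_degree_ = scan.best_degree
        # re-score the winner at full precision
        lab = _milestone_vector(t, e, scan.best_cutoff)
        keep = ~np.isnan(lab)
        final = ConsistencyScorer(
            random_state=cfg.seed, **cfg.scorer_kwargs(reps=cfg.final_reps)
        ).fit(X[keep], lab[keep].astype(int))
        self.final_degree_ = final.degree_
        self._Xte = (X, t, e)
        return self

    def bootstrap_recurrence(self, n: int = 1000) -> EnrichmentResult:
        """Enrichment of the fitted cutoff over ``n`` bootstrap redefinitions."""
        check_is_fitted(self, "best_cutoff_")
        X, t, e = self._Xte
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(X.shape[1])],
            [f"r{i}" for i in range(X.shape[0])],
            X.T,
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {"days": t, "event": e}, index=[f"r{i}" for i in range(t.size)]
            ),
            time_col="days",
            event_col="event",
        )
        return bootstrap_cutoff_recurrence(
            expr, clin, self._cfg(), n=n, best_cutoff=self.best_cutoff_
        )
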