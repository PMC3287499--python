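"""Validity and unpredictability analyses.

Checks that the consistency degree tracks independent model performance
(one-sided rank correlations against top-k MCC summaries), identifies
consistently mispredicted ("unpredictable") samples from per-sample error
rates, tests whether their OS-EFS gap is smaller than the rest (one-sided
rank-sum), and provides Kaplan-Meier milestone quantiles plus the numeric
table behind score-vs-posterior-mean placement of unpredictable samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import kendalltau, mannwhitneyu, rankdata, spearmanr

from .changepoint import ChangePointPosterior
from .containers import ErrorRateTable, PerformanceTable
from .errors import DegenerateInputError, ValidationError
from .selection import SampleScores

__all__ = [
    "ValidityReport",
    "UnpredictableSet",
    "validity_test",
    "impute_low_coverage",
    "select_unpredictable",
    "os_efs_gap_test",
    "km_quantile",
    "score_position_report",
]

_EXACT_MAX = 25  # exact rank-sum enumeration bound per group


@dataclass
class ValidityReport:
    """One-sided (greater) rank-correlation tests of degrees vs performance."""

    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float
    endpoints: list[str]
    degrees: np.ndarray
    summaries: np.ndarray


@dataclass
class UnpredictableSet:
    """Samples whose prediction error rate reaches the cutoff."""

    sample_ids: list[str]
    error_rate: np.ndarray
    cutoff: float

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in set(self.sample_ids)


def validity_test(
    degrees: dict[str, float], perf: PerformanceTable, top_k: int = 10
) -> ValidityReport:
    """Correlate consistency degrees with mean top-``top_k`` MCC per endpoint.

    Alternative hypothesis: positive association ("greater") for both the
    Spearman and the Kendall test.
    """
    common = sorted(set(degrees) & set(perf.endpoints))
    if len(common) < 3:
        raise DegenerateInputError(
            f"need >= 3 endpoints shared between degrees and performance "
            f"(got {len(common)})"
        )
    d = np.array([float(degrees[ep]) for ep in common])
    s = np.array([perf.top_mean(ep, top_k) for ep in common])
    rho, p_rho = spearmanr(d, s, alternative="greater")
    tau, p_tau = kendalltau(d, s, alternative="greater")
    return ValidityReport(
        spearman_rho=float(rho),
        spearman_p=float(p_rho),
        kendall_tau=float(tau),
        kendall_p=float(p_tau),
        endpoints=common,
        degrees=d,
        summaries=s,
    )


def impute_low_coverage(errors: ErrorRateTable, min_models: int = 50) -> ErrorRateTable:
    """Set the error rate to 0.5 for samples predicted by fewer than
    ``min_models`` classifiers (their observed rate is unreliable)."""
    df = errors.data.copy()
    df.loc[df["n_models"] < min_models, "error_rate"] = 0.5
    return ErrorRateTable(df)


def select_unpredictable(
    errors: ErrorRateTable,
    cutoff: float,
    top_k: int | None = None,
    max_models: int | None = None,
) -> UnpredictableSet:
    """Samples with error rate >= ``cutoff``, sorted by error rate descending.

    Optional conjunctive filters: keep only the ``top_k`` highest error rates
    and/or only samples predicted by at most ``max_models`` classifiers.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError("cutoff must lie in [0, 1]")
    df = errors.data.copy()
    if max_models is not None:
        df = df[df["n_models"] <= max_models]
    df = df[df["error_rate"] >= cutoff]
    # error rate descending, sample id as the deterministic tie-break
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df["error_rate"].to_numpy()))]
    if top_k is not None:
        df = df.iloc[:top_k]
    return UnpredictableSet(
        sample_ids=list(df.index),
        error_rate=df["error_rate"].to_numpy(),
        cutoff=float(cutoff),
    )


def _exact_ranksum_p_less(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation tail P(rank-sum of group A <= observed), midranks."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = a.size
    obs = ranks[:na].sum()
    total = comb(pooled.size, na)
    hits = 0
    idx = range(pooled.size)
    for pick in combinations(idx, na):
        if ranks[list(pick)].sum() <= obs + 1e-9:
            hits += 1
    return hits / total


def os_efs_gap_test(os_days, efs_days, unpredictable_mask) -> float:
    """One-sided test that OS-EFS gaps are smaller in unpredictable samples.

    Exact permutation enumeration when both groups are small (<= 25 each and
    the enumeration is tractable); otherwise the normal approximation with
    tie correction (rank-sum / Mann-Whitney).
    """
    os_days = np.asarray(os_days, dtype=float)
    efs_days = np.asarray(efs_days, dtype=float)
    mask = np.asarray(unpredictable_mask, dtype=bool)
    if not (os_days.size == efs_days.size == mask.size):
        raise ValidationError("inputs must have equal length")
    gaps = os_days - efs_days
    g_un = gaps[mask]
    g_other = gaps[~mask]
    if g_un.size == 0 or g_other.size == 0:
        raise DegenerateInputError("both groups must be non-empty")
    n, m = g_un.size, g_other.size
    if n <= _EXACT_MAX and m <= _EXACT_MAX and comb(n + m, n) <= 400_000:
        return float(_exact_ranksum_p_less(g_un, g_other))
    _, p = mannwhitneyu(g_un, g_other, alternative="less", method="asymptotic")
    return float(p)


def km_quantile(times, events, q: float) -> float:
    """Smallest observed time where the Kaplan-Meier survival estimate drops
    to ``q`` or below; NaN when the curve never reaches ``q``."""
    if not (0.0 < q < 1.0):
        raise ValidationError("q must lie in (0, 1)")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValidationError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_.iloc[:, 0]
    below = sf[sf <= q + 1e-12]
    below = below[below.index > 0]
    if below.empty:
        return float("nan")
    return float(below.index[0])


def score_position_report(
    scores: SampleScores,
    labels,
    posterior: ChangePointPosterior,
    ordering,
    unpredictable: UnpredictableSet,
) -> pd.DataFrame:
    """Where do unpredictable samples sit relative to the class posterior
    means?  One row per unpredictable sample: its PC1 score, the posterior
    mean of each class block, and which side of each mean it falls on.
    """
    y = np.asarray(labels)
    ordering = np.asarray(ordering, dtype=int)
    n0 = int(np.sum(y == 0))
    pm = posterior.posterior_mean
    mean0 = float(pm[:n0].mean())
    mean1 = float(pm[n0:].mean())
    pos = {s: i for i, s in enumerate(scores.sample_ids)}
    rows = []
    for sid in unpredictable.sample_ids:
        if sid not in pos:
            raise ValidationError(f"unknown sample id {sid!r}")
        sc = float(scores.score[pos[sid]])
        rows.append(
            {
                "sample_id": sid,
                "score": sc,
                "label": int(y[pos[sid]]),
                "class0_posterior_mean": mean0,
                "class1_posterior_mean": mean1,
                "above_class0_mean": sc > mean0,
                "above_class1_mean": sc > mean1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "score",
            "label",
            "class0_posterior_mean",
            "class1_posterior_mean",
            "above_class0_mean",
            "above_class1_mean",
        ],
    )
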