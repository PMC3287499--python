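"""Synthetic expression + clinical data with controlled consistency structure.

Two generators:

* :func:`simulate_two_class` — a binary endpoint shifts a shared latent
  trait L = effect*y + N(0,1) (unit within-class biological variance, as in
  a co-expressed signature module); each of the ``n_informative`` genes is
  loading*L plus idiosyncratic noise, with random loading sign and |loading|
  uniform in [correlation, 1], so informative genes correlate pairwise by
  a_i*a_j and a full-loading gene's between-class shift is ``effect`` in
  per-gene SD units.  The remaining genes are pure noise and effect=0 is an
  exact null.
* :func:`simulate_survival` — a latent milestone class (event by
  ``true_cutoff`` vs survival past it) drives the informative genes; event
  times are exponential per latent class (truncated below the cutoff for the
  event class, shifted beyond it for the survivor class) and censoring is
  applied uniformly at a configurable rate.

Both are deterministic under their seed (PCG64 streams) and write-ready via
the standard TSV pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix
from .errors import DegenerateSimulationError, ValidationError
from .io import write_clinical_table, write_expression_matrix

__all__ = ["SimConfig", "SurvSimConfig", "simulate_two_class", "simulate_survival"]


@dataclass
class SimConfig:
    """Two-class expression simulation settings.

    Defaults emulate a positive-control endpoint on a small training cohort:
    30 + 30 samples, 150 genes of which 20 carry a 3-SD class shift.
    """

    n0: int = 30
    n1: int = 30
    n_genes: int = 150
    n_informative: int = 20
    effect: float = 3.0
    noise_sd: float = 1.0
    correlation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValidationError("n_informative cannot exceed n_genes")
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not (0.0 <= self.correlation <= 1.0):
            raise ValidationError("correlation must lie in [0, 1]")
        if self.n0 < 0 or self.n1 < 0:
            raise ValidationError("class sizes must be non-negative")


@dataclass
class SurvSimConfig(SimConfig):
    """Survival simulation settings (latent milestone class drives genes)."""

    true_cutoff: float = 900.0
    censoring_rate: float = 0.1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.true_cutoff <= 0:
            raise ValidationError("true_cutoff must be > 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValidationError("censoring_rate must lie in [0, 1)")


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _expression_from_classes(
    y: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    n = y.size
    values = rng.normal(0.0, 1.0, size=(cfg.n_genes, n))
    if cfg.n_informative and cfg.effect > 0:
        mag = rng.uniform(cfg.correlation, 1.0, size=cfg.n_informative)
        sign = rng.choice([-1.0, 1.0], size=cfg.n_informative)
        loading = mag * sign
        latent = cfg.effect * y + rng.normal(0.0, 1.0, size=n)
        k = cfg.n_informative
        # unit per-gene variance: loading^2 from the latent, rest idiosyncratic
        values[:k] = np.outer(loading, latent) + np.sqrt(
            1.0 - loading[:, None] ** 2
        ) * values[:k]
    return values * cfg.noise_sd


def simulate_two_class(cfg: SimConfig) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Simulate a binary endpoint with a controllable expression signal."""
    if cfg.n0 < 2 or cfg.n1 < 2:
        raise DegenerateSimulationError(
            "need at least 2 samples per class; increase n0/n1"
        )
    rng = np.random.default_rng(cfg.seed)
    y = np.concatenate([np.zeros(cfg.n0, dtype=int), np.ones(cfg.n1, dtype=int)])
    values = _expression_from_classes(y, cfg, rng)
    samples = _ids("s", y.size)
    genes = _ids("ginf", cfg.n_informative) + _ids("gnoise", cfg.n_genes - cfg.n_informative)
    expr = ExpressionMatrix(genes, samples, values)
    clin = ClinicalTable(
        pd.DataFrame({"class": y}, index=samples), endpoint_cols=("class",)
    )
    return expr, clin


def simulate_survival(cfg: SurvSimConfig) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Simulate survival data whose latent milestone class drives the genes.

    Latent class 1 (event by ``true_cutoff``): times truncated-exponential on
    (0, cutoff] with rate 0.5/cutoff, i.e. events spread through the whole
    window rather than piling up early — the planted milestone is only
    identifiable if late events exist on both sides of it.  Latent class 0:
    times cutoff + exponential with mean cutoff/2.  Censoring replaces a
    sample's record with a uniform time before its event, at rate
    ``censoring_rate``.
    """
    if cfg.n0 < 2 or cfg.n1 < 2:
        raise DegenerateSimulationError(
            "each latent milestone class needs >= 2 samples; with these "
            "settings one side of true_cutoff would be (near) empty — "
            "increase n0/n1 or move true_cutoff inside the time range"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n0 + cfg.n1
    c = np.concatenate([np.zeros(cfg.n0, dtype=int), np.ones(cfg.n1, dtype=int)])
    rng.shuffle(c)

    times = np.empty(n)
    rate1 = 0.5 / cfg.true_cutoff
    u = rng.uniform(size=n)
    mask1 = c == 1
    # inverse-CDF of an exponential truncated to (0, cutoff]
    times[mask1] = -np.log1p(-u[mask1] * (1.0 - np.exp(-rate1 * cfg.true_cutoff))) / rate1
    times[~mask1] = cfg.true_cutoff + rng.exponential(cfg.true_cutoff / 2.0, size=cfg.n0)

    events = np.ones(n, dtype=int)
    censor = rng.uniform(size=n) < cfg.censoring_rate
    times = np.where(censor, rng.uniform(0.0, 1.0, size=n) * times, times)
    events[censor] = 0

    if not ((events == 1) & (times <= cfg.true_cutoff)).any() or not (
        times > cfg.true_cutoff
    ).any():
        raise DegenerateSimulationError(
            "all samples landed on one side of true_cutoff; move the cutoff "
            "inside the simulated time range"
        )

    values = _expression_from_classes(c, cfg, rng)
    samples = _ids("s", n)
    genes = _ids("ginf", cfg.n_informative) + _ids("gnoise", cfg.n_genes - cfg.n_informative)
    expr = ExpressionMatrix(genes, samples, values)
    clin = ClinicalTable(
        pd.DataFrame(
            {"latent_class": c, "days": np.round(times, 6), "event": events},
            index=samples,
        ),
        endpoint_cols=("latent_class",),
        time_col="days",
        event_col="event",
    )
    return expr, clin


def write_fixture(
    expr: ExpressionMatrix, clin: ClinicalTable, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the standard TSV pair (expression.tsv, clinical.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    e = out / "expression.tsv"
    c = out / "clinical.tsv"
    write_expression_matrix(expr, e)
    write_clinical_table(clin, c)
    return e, c
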