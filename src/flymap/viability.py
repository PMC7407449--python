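"""Stage-survival, fertility and rescue-cross accounting.

Balancer intercrosses segregate 1 homozygous mutant : 2 balanced
heterozygote : 1 balancer homozygote; the balancer-homozygous class dies as
embryos, so among hatched larvae the Mendelian expectation is 1/3 mutant
(non-Tubby) : 2/3 balanced (Tubby).  This module computes observed stage
proportions, model-based expectations with lethal classes, goodness-of-fit
tests of observed vs expected class counts, the arcsine square-root
variance-stabilising transform for proportions, and exact binomial summaries
of fertility assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GofResult",
    "RatioModel",
    "StageCounts",
    "arcsine_sqrt",
    "expected_classes",
    "fertility_summary",
    "goodness_of_fit",
    "stage_proportion",
]


@dataclass(frozen=True)
class StageCounts:
    """Per-class counts along an ordered sequence of developmental stages."""

    counts: pd.DataFrame  # index: class, columns: stages in order

    def __post_init__(self) -> None:
        df = self.counts
        if (df.values < 0).any():
            raise ValueError("counts must be non-negative")
        diffs = df.diff(axis=1).iloc[:, 1:]
        if (diffs.values > 0).any():
            raise ValueError("per-class counts must be non-increasing across stages")

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def stages(self) -> list[str]:
        return list(self.counts.columns)

    def at_stage(self, stage: str) -> pd.Series:
        return self.counts[stage]


@dataclass(frozen=True)
class RatioModel:
    """Mendelian class proportions plus per-class, per-stage survival.

    ``survival[c][j]`` is the probability that a class-``c`` individual alive
    at stage ``j-1`` survives to stage ``j``; zero encodes a lethal class.
    """

    proportions: dict[str, float]
    survival: dict[str, list[float]]
    stages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if set(self.survival) != set(self.proportions):
            raise ValueError("survival classes must match proportion classes")
        lengths = {len(v) for v in self.survival.values()}
        if len(lengths) != 1:
            raise ValueError("all classes need the same number of stages")
        for c, probs in self.survival.items():
            if any(not (0.0 <= p <= 1.0) for p in probs):
                raise ValueError(f"class {c}: survival probabilities must be in [0, 1]")
        if self.stages and len(self.stages) != lengths.pop():
            raise ValueError("stage names must match survival length")

    @property
    def n_stages(self) -> int:
        return len(next(iter(self.survival.values())))

    def cumulative_survival(self, stage_index: int) -> dict[str, float]:
        """P(alive at stage ``stage_index``), counting fertilization as -1."""
        out = {}
        for c in self.proportions:
            s = 1.0
            for j in range(stage_index + 1):
                s *= self.survival[c][j]
            out[c] = s
        return out

    def _stage_index(self, stage: int | str) -> int:
        if isinstance(stage, str):
            if not self.stages:
                raise ValueError("model has no stage names; use an integer index")
            return self.stages.index(stage)
        return stage


def stage_proportion(numerator: int, denominator: int) -> float:
    """Observed stage percentage, 100·numerator/denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must be between 0 and denominator")
    return 100.0 * numerator / denominator


def expected_classes(
    model: RatioModel,
    n: int,
    stage: int | str,
    renormalize: bool = True,
) -> dict[str, float]:
    """Expected per-class counts at a stage.

    With ``renormalize`` (the usual case: ``n`` is the number of individuals
    actually observed at that stage) expectations are conditional on survival
    to the stage; otherwise they are unconditional projections
    n · proportion · cumulative survival.
    """
    j = model._stage_index(stage)
    cum = model.cumulative_survival(j)
    raw = {c: model.proportions[c] * cum[c] for c in model.proportions}
    if renormalize:
        total = sum(raw.values())
        if total == 0:
            raise ValueError("no class survives to this stage")
        return {c: n * v / total for c, v in raw.items()}
    return {c: n * v for c, v in raw.items()}


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    pvalue: float
    method: str


def goodness_of_fit(
    observed: dict[str, int] | pd.Series,
    expected: dict[str, float] | pd.Series,
    method: str = "auto",
) -> GofResult:
    """Observed vs expected class counts.

    ``auto`` uses the Pearson chi-square for ≥3 classes and the exact binomial
    for 2 classes; ``chi_square`` / ``exact_binomial`` force the route (the
    exact route requires exactly 2 classes).
    """
    obs = pd.Series(observed, dtype=float)
    exp = pd.Series(expected, dtype=float).reindex(obs.index)
    if exp.isna().any():
        raise ValueError("expected counts missing for some classes")
    if (exp <= 0).any():
        raise ValueError("expected counts must be positive for included classes")
    if len(obs) < 2:
        raise ValueError("need at least 2 classes")
    if method == "auto":
        method = "exact_binomial" if len(obs) == 2 else "chi_square"
    if method == "exact_binomial":
        if len(obs) != 2:
            raise ValueError("exact binomial test requires exactly 2 classes")
        n = int(obs.sum())
        p = float(exp.iloc[0] / exp.sum())
        res = stats.binomtest(int(obs.iloc[0]), n, p)
        return GofResult(float(obs.iloc[0]), 1, float(res.pvalue), "exact_binomial")
    if method != "chi_square":
        raise ValueError(f"unknown goodness-of-fit method {method!r}")
    # rescale expected to the observed total (proportions may come unnormalised)
    exp = exp * obs.sum() / exp.sum()
    stat, p = stats.chisquare(obs.values, exp.values)
    return GofResult(float(stat), len(obs) - 1, float(p), "chi_square")


def arcsine_sqrt(p):
    """Variance-stabilising transform asin(√p), in radians, for p ∈ [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must be in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass(frozen=True)
class FertilitySummary:
    percent: float
    ci_low: float
    ci_high: float
    fertile: int
    total: int


def fertility_summary(
    pairs_fertile: int, pairs_total: int, ci_level: float = 0.95
) -> FertilitySummary:
    """Percent fertile pair matings with an exact Clopper–Pearson CI."""
    if pairs_total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= pairs_fertile <= pairs_total):
        raise ValueError("fertile count must be between 0 and total")
    pct = 100.0 * pairs_fertile / pairs_total
    alpha = 1.0 - ci_level
    k, n = pairs_fertile, pairs_total
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return FertilitySummary(pct, 100.0 * lo, 100.0 * hi, k, n)
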