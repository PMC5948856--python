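"""Replicate batches and the strategy-comparison statistics harness.

Because a single run is stochastic (appearance times, placements and
movement), strategies are compared over independent replicate runs of
the same scenario.  For each strategy a batch of final metric records is
collected and the comparison proceeds in the standard robust-ANOVA
style: Levene's test for homogeneity of variances, then Welch's and the
Brown-Forsythe heteroscedasticity-robust tests of equality of means
(both asymptotically F distributed), and pooled-SD Cohen's d effect
sizes for the focal pair of strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import STRATEGY_NAMES, SimConfig
from .engine import run_simulation

__all__ = [
    "BatchResult",
    "ComparisonReport",
    "STRATEGY_SEED_STRIDE",
    "run_batch",
    "run_all_batches",
    "summarize",
    "levene_test",
    "welch_anova",
    "brown_forsythe_anova",
    "cohens_d",
    "compare_strategies",
]

#: Metric labels in batch tables, in fixed order.
METRICS = ("power", "crop_health", "alive_bugs", "pesticide")

#: Offset between the base seeds of consecutive strategy batches, so
#: that replicate seeds of different strategies never collide.
STRATEGY_SEED_STRIDE = 1_000_000


@dataclass
class BatchResult:
    """Final metrics of ``n`` replicate runs of one strategy."""

    strategy: str
    table: pd.DataFrame  # columns: replicate, seed, power, crop_health, alive_bugs, pesticide

    @property
    def n(self) -> int:
        return len(self.table)

    def metric(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "strategy", self.strategy)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BatchResult":
        df = pd.read_csv(path, float_precision="round_trip")
        strategy = str(df["strategy"].iloc[0])
        return cls(strategy, df.drop(columns=["strategy"]))


def run_batch(
    config: SimConfig, strategy: str, n_reps: int, base_seed: int
) -> BatchResult:
    """Run ``n_reps`` independent replicates; replicate ``i`` seeds with
    ``base_seed + i``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for i in range(n_reps):
        seed = base_seed + i
        cfg = config.replace(strategy=strategy, seed=seed)
        final = run_simulation(cfg).final
        rows.append(
            {
                "replicate": i,
                "seed": seed,
                "power": final.avg_power,
                "crop_health": final.crop_health_pct,
                "alive_bugs": final.alive_bugs_pct,
                "pesticide": final.pesticide_per_station,
            }
        )
    return BatchResult(strategy, pd.DataFrame(rows))


def run_all_batches(
    config: SimConfig,
    n_reps: int,
    base_seed: int,
    strategies: Sequence[str] = STRATEGY_NAMES,
) -> dict[str, BatchResult]:
    """One batch per strategy, same scenario parameters for fairness.

    Strategy ``k`` uses base seed ``base_seed + k * STRATEGY_SEED_STRIDE``.
    """
    return {
        name: run_batch(config, name, n_reps, base_seed + k * STRATEGY_SEED_STRIDE)
        for k, name in enumerate(strategies)
    }


def summarize(batch: BatchResult) -> pd.DataFrame:
    """Per-metric mean and sample SD (n-1 denominator) of a batch."""
    if batch.n < 2:
        raise ValueError("at least 2 replicates are needed for a sample SD")
    rows = [
        {
            "metric": m,
            "mean": float(np.mean(batch.metric(m))),
            "sd": float(np.std(batch.metric(m), ddof=1)),
        }
        for m in METRICS
    ]
    return pd.DataFrame(rows)


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("at least two groups are required")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    return arrays


def levene_test(
    groups: Sequence[Sequence[float]], center: str = "mean"
) -> tuple[float, float]:
    """Levene's test of homogeneity of variances (classical mean-centred
    form by default; ``center='median'`` for the robust variant)."""
    arrays = _as_groups(groups)
    if all(np.ptp(g) == 0 for g in arrays):
        raise ValueError("all observations equal within every group; "
                         "Levene's statistic is undefined")
    stat, p = stats.levene(*arrays, center=center)
    return float(stat), float(p)


def welch_anova(
    groups: Sequence[Sequence[float]],
) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way test of equality of means.

    Returns ``(F, df1, df2, p)``.  Group ``i`` is weighted by
    ``w_i = n_i / s_i^2``; with ``k`` groups the statistic is

        F = [sum_i w_i (m_i - m*)^2 / (k - 1)]
            / [1 + 2(k - 2)/(k^2 - 1) * A]

    where ``m* = sum w_i m_i / sum w_i``,
    ``A = sum_i (1 - w_i/W)^2 / (n_i - 1)`` and
    ``df2 = (k^2 - 1) / (3 A)``.  For two groups the statistic equals
    the squared Welch t and ``df2`` is the Welch-Satterthwaite df.
    """
    arrays = _as_groups(groups)
    k = len(arrays)
    n = np.array([len(g) for g in arrays], dtype=float)
    m = np.array([g.mean() for g in arrays])
    v = np.array([g.var(ddof=1) for g in arrays])
    if np.any(v <= 0):
        raise ValueError("every group needs positive within-group variance")
    w = n / v
    w_total = w.sum()
    m_star = (w * m).sum() / w_total
    a = (((1 - w / w_total) ** 2) / (n - 1)).sum()
    numerator = (w * (m - m_star) ** 2).sum() / (k - 1)
    denominator = 1 + 2 * (k - 2) / (k**2 - 1) * a
    f = numerator / denominator
    df1 = float(k - 1)
    df2 = (k**2 - 1) / (3 * a)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, float(df2), p


def brown_forsythe_anova(
    groups: Sequence[Sequence[float]],
) -> tuple[float, float, float, float]:
    """Brown-Forsythe robust test of equality of means.

    Returns ``(F*, df1, df2, p)`` with

        F* = sum_i n_i (m_i - m)^2 / sum_i (1 - n_i/N) s_i^2

    where ``m`` is the grand mean of all observations, and the
    denominator df follow Satterthwaite:
    ``1/df2 = sum_i c_i^2 / (n_i - 1)`` with
    ``c_i = (1 - n_i/N) s_i^2 / sum_j (1 - n_j/N) s_j^2``.

    (Distinct from the Brown-Forsythe *variance* test, which is Levene's
    test centred at the median.)
    """
    arrays = _as_groups(groups)
    k = len(arrays)
    n = np.array([len(g) for g in arrays], dtype=float)
    big_n = n.sum()
    m = np.array([g.mean() for g in arrays])
    v = np.array([g.var(ddof=1) for g in arrays])
    if np.any(v <= 0):
        raise ValueError("every group needs positive within-group variance")
    grand = np.concatenate(arrays).mean()
    denom_terms = (1 - n / big_n) * v
    denom = denom_terms.sum()
    f = (n * (m - grand) ** 2).sum() / denom
    c = denom_terms / denom
    df2 = 1.0 / ((c**2 / (n - 1)).sum())
    df1 = float(k - 1)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, float(df2), p


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Pooled-SD standardized mean difference ``(mean(a) - mean(b)) / s_p``.

    Pooled variance weights each group's sample variance by ``n - 1``.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var <= 0:
        raise ValueError("pooled SD is zero; Cohen's d is undefined")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def _stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.01:
        return "*"
    return ""


@dataclass
class ComparisonReport:
    """Summary, robust-test and effect-size tables for a set of batches.

    ``robust_tests`` holds one Welch row and one Brown-Forsythe row per
    metric for the all-strategies comparison and for each requested
    pair.  ``effects`` holds the raw mean difference and Cohen's d per
    metric for each pair, computed as (first - second) of the pair.
    Significance stars follow the usual convention: ``*`` for p < 0.01,
    ``**`` for p < 0.001.
    """

    summary: pd.DataFrame
    robust_tests: pd.DataFrame
    effects: pd.DataFrame

    def to_text(self) -> str:
        lines = ["== Summary (mean (SD)) ==", self.summary.to_string(index=False), ""]
        lines += ["== Robust tests of equality of means ==",
                  self.robust_tests.to_string(index=False), ""]
        if len(self.effects):
            lines += ["== Effect sizes ==", self.effects.to_string(index=False), ""]
        return "\n".join(lines)


def compare_strategies(
    batches: Mapping[str, BatchResult],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> ComparisonReport:
    """Full statistical comparison of strategy batches.

    ``pairs`` defaults to ``[("lowcost_neighbor", "neighbor")]`` when both
    are present: the focal low-cost-vs-neighbor contrast, with the mean
    difference and Cohen's d signed as (low-cost - neighbor).
    """
    if len(batches) < 2:
        raise ValueError("at least two batches are required")
    names = list(batches)
    if pairs is None:
        pairs = (
            [("lowcost_neighbor", "neighbor")]
            if {"lowcost_neighbor", "neighbor"} <= set(names)
            else []
        )

    summary_rows = []
    for name in names:
        s = summarize(batches[name]).set_index("metric")
        row: dict[str, object] = {"strategy": name}
        for metric in METRICS:
            row[f"{metric}_mean"] = s.loc[metric, "mean"]
            row[f"{metric}_sd"] = s.loc[metric, "sd"]
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    test_rows = []
    comparisons: list[tuple[str, list[str]]] = [("all", names)]
    comparisons += [(f"{a} vs {b}", [a, b]) for a, b in pairs]
    for label, group_names in comparisons:
        for metric in METRICS:
            groups = [batches[g].metric(metric) for g in group_names]
            for test_name, fn in (
                ("welch", welch_anova),
                ("brown_forsythe", brown_forsythe_anova),
            ):
                try:
                    f, df1, df2, p = fn(groups)
                except ValueError:
                    # degenerate sample (e.g. zero within-group variance):
                    # report an undefined row rather than aborting the report
                    f = df1 = df2 = p = float("nan")
                test_rows.append(
                    {
                        "comparison": label,
                        "metric": metric,
                        "test": test_name,
                        "statistic": f,
                        "df1": df1,
                        "df2": df2,
                        "p": p,
                        "sig": _stars(p),
                    }
                )
    robust_tests = pd.DataFrame(test_rows)

    effect_rows = []
    for a, b in pairs:
        for metric in METRICS:
            xa, xb = batches[a].metric(metric), batches[b].metric(metric)
            try:
                d = cohens_d(xa, xb)
            except ValueError:
                d = float("nan")
            effect_rows.append(
                {
                    "pair": f"{a} - {b}",
                    "metric": metric,
                    "mean_difference": float(np.mean(xa) - np.mean(xb)),
                    "cohens_d": d,
                }
            )
    effects = pd.DataFrame(
        effect_rows, columns=["pair", "metric", "mean_difference", "cohens_d"]
    )
    return ComparisonReport(summary, robust_tests, effects)
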