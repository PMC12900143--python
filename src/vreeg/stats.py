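"""Non-parametric group comparisons and survey aggregation.

The study's statistical toolkit: Shapiro–Wilk normality screening that
motivates non-parametric tests, the Mann–Whitney U (Wilcoxon rank-sum)
test with midranks for ties, a seeded two-sample permutation test on the
standardized difference of group means, descriptive performance-metric
summaries with pooled epochs, and 7-point Likert sentiment aggregation.

Conventions: all tests are two-sided; the reported ``W`` follows the
common R convention (the U statistic of the first sample); no
multiple-testing correction is applied by default, with Holm adjustment
available as an explicit helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ParameterError, SampleError

__all__ = [
    "GroupComparison",
    "SentimentSummary",
    "normality_check",
    "mann_whitney",
    "permutation_test",
    "summarize_pm",
    "likert_sentiment",
    "holm_adjust",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group comparison, Tables-style."""

    test: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    missing_x: int = 0
    missing_y: int = 0
    summary: dict = field(default_factory=dict)  # per group: mean, sd
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value out of range: {self.p_value}")


def _clean(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1:
        raise SampleError("samples must be one-dimensional")
    return arr[~np.isnan(arr)]


def normality_check(sample, alpha: float = 0.05) -> tuple:
    """Shapiro–Wilk test with a normal/non-normal verdict.

    Returns ``(W, p, verdict)`` where the verdict is ``"non-normal"``
    when p < ``alpha``; this drives the automatic choice of
    non-parametric tests downstream. Requires n ≥ 3 and a non-constant
    sample.
    """
    arr = _clean(sample)
    if arr.size < 3:
        raise SampleError(f"normality check requires n >= 3, got {arr.size}")
    if np.ptp(arr) == 0.0:
        raise SampleError("constant sample: normality is undefined")
    w, p = sstats.shapiro(arr)
    return float(w), float(p), ("non-normal" if p < alpha else "normal")


def mann_whitney(x, y, alternative: str = "two-sided") -> GroupComparison:
    """Mann–Whitney U test with midranks for ties.

    Uses exact null enumeration when ``n_x · n_y ≤ 64`` and the pooled
    sample is tie-free, otherwise the normal approximation with tie and
    continuity corrections. ``W`` is the U statistic of ``x`` (the value
    R's ``wilcox.test`` prints as W).
    """
    xa, ya = _clean(x), _clean(y)
    if xa.size < 1 or ya.size < 1:
        raise SampleError("both samples must be non-empty")
    ties = np.unique(np.concatenate([xa, ya])).size < xa.size + ya.size
    method = "exact" if (xa.size * ya.size <= 64 and not ties) else "asymptotic"
    res = sstats.mannwhitneyu(
        xa, ya, alternative=alternative, method=method, use_continuity=True
    )
    return GroupComparison(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_x=xa.size,
        n_y=ya.size,
        summary={
            "x": {"mean": float(xa.mean()), "sd": float(xa.std(ddof=1)) if xa.size > 1 else 0.0},
            "y": {"mean": float(ya.mean()), "sd": float(ya.std(ddof=1)) if ya.size > 1 else 0.0},
        },
        meta={"method": method, "alternative": alternative, "statistic_convention": "U of x (R wilcox.test W)"},
    )


def _standardized_mean_diff(xa: np.ndarray, ya: np.ndarray) -> float:
    nx, ny = xa.size, ya.size
    pooled = ((nx - 1) * xa.var(ddof=1) + (ny - 1) * ya.var(ddof=1)) / (nx + ny - 2)
    if pooled <= 0.0:
        raise SampleError("degenerate pooled variance: statistic undefined")
    return float((xa.mean() - ya.mean()) / np.sqrt(pooled * (1.0 / nx + 1.0 / ny)))


def permutation_test(x, y, n_perm: int = 10_000, seed: int = 0) -> GroupComparison:
    """Seeded two-sample permutation test.

    The statistic is the standardized difference of group means (a
    two-sample Z). The two-sided p-value uses the add-one estimator
    ``(1 + #{|Z_perm| ≥ |Z_obs|}) / (n_perm + 1)``, so it can never fall
    below ``1/(n_perm + 1)``. Group labels are shuffled with a seeded
    generator; results are reproducible for a fixed seed.
    """
    if n_perm < 99:
        raise ParameterError(f"n_perm must be >= 99, got {n_perm}")
    xa, ya = _clean(x), _clean(y)
    if xa.size < 2 or ya.size < 2:
        raise SampleError("permutation test needs n >= 2 per group")
    z_obs = _standardized_mean_diff(xa, ya)
    pooled = np.concatenate([xa, ya])
    rng = np.random.default_rng(seed)
    nx = xa.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        try:
            z = _standardized_mean_diff(perm[:nx], perm[nx:])
        except SampleError:
            z = 0.0  # constant permutation of a non-constant pool cannot occur
        if abs(z) >= abs(z_obs) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return GroupComparison(
        test="permutation",
        statistic=z_obs,
        p_value=p,
        n_x=xa.size,
        n_y=ya.size,
        summary={
            "x": {"mean": float(xa.mean()), "sd": float(xa.std(ddof=1))},
            "y": {"mean": float(ya.mean()), "sd": float(ya.std(ddof=1))},
        },
        meta={"n_perm": n_perm, "seed": seed, "estimator": "add-one"},
    )


def summarize_pm(
    pm: pd.DataFrame, metric: str, event: int, groups: Sequence[str] = ("experimental", "control")
) -> dict:
    """Descriptive summary plus Mann–Whitney comparison of pooled epochs.

    Pools every epoch value of ``metric`` during ``event`` across the
    participants of each group (n = participants × epochs, the pooling
    used in the study's summary tables), reports mean ± SD and missing
    counts per group, and attaches the Mann–Whitney comparison of the
    pooled values.
    """
    if metric not in pm.columns:
        raise KeyError(f"unknown metric {metric!r}")
    if pm.empty:
        raise SampleError("empty PM table")
    sub = pm[pm["event"] == event]
    pooled, out = {}, {"metric": metric, "event": event, "groups": {}}
    for group in groups:
        values = sub.loc[sub["group"] == group, metric].to_numpy(dtype=float)
        missing = int(np.isnan(values).sum())
        observed = values[~np.isnan(values)]
        pooled[group] = observed
        out["groups"][group] = {
            "n_pooled": int(values.size),
            "n_observed": int(observed.size),
            "missing": missing,
            "mean": float(observed.mean()) if observed.size else float("nan"),
            "sd": float(observed.std(ddof=1)) if observed.size > 1 else 0.0,
        }
    ga, gb = groups
    out["comparison"] = mann_whitney(pooled[ga], pooled[gb])
    return out


@dataclass(frozen=True)
class SentimentSummary:
    """Per-question negative/neutral/positive percentages."""

    table: pd.DataFrame  # columns: question [, group], pct_negative, pct_neutral, pct_positive


def likert_sentiment(
    responses: pd.DataFrame,
    questions: Sequence[str] | None = None,
    by_group: bool = True,
) -> SentimentSummary:
    """Aggregate 7-point Likert responses into sentiment percentages.

    Mapping: 1-3 negative, 4 neutral, 5-7 positive. Percentages are per
    question (and per group when ``by_group``), and always sum to 100.
    """
    if questions is None:
        questions = [
            c for c in responses.columns if c not in ("participant", "group")
        ]
    rows = []
    keys = ["group"] if (by_group and "group" in responses.columns) else []
    grouped = responses.groupby(keys) if keys else [((), responses)]
    for key, frame in grouped:
        for question in questions:
            values = frame[question].to_numpy()
            if not np.isin(values, np.arange(1, 8)).all():
                raise ParameterError(f"question {question!r} has responses outside 1-7")
            n = values.size
            row = {
                "question": question,
                "pct_negative": 100.0 * np.isin(values, (1, 2, 3)).sum() / n,
                "pct_neutral": 100.0 * (values == 4).sum() / n,
                "pct_positive": 100.0 * np.isin(values, (5, 6, 7)).sum() / n,
            }
            if keys:
                row["group"] = key[0] if isinstance(key, tuple) else key
            rows.append(row)
    return SentimentSummary(table=pd.DataFrame(rows))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (optional; raw p-values are the default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
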