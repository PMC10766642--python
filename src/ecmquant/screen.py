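"""Ordinal fluorescence scoring and RNAi screen hit calling.

Reporter fluorescence per animal group is graded visually on an ordinal grid
(0-3 in 0.5 steps for whole-worm reporter intensity; 0-5 in unit steps for
hemidesmosome-structure categories).  A screen condition is a hit when the
mean of its replicates differs from the matched control mean by at least the
lowest visible difference (0.5 grade) — positive deltas are enhancers,
negative deltas suppressors (the relevant direction against long-lived
backgrounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_GRID = tuple(x / 2 for x in range(0, 7))  # 0, 0.5, ..., 3.0
HEMIDESMOSOME_GRID = tuple(float(x) for x in range(6))  # 0..5 categories


@dataclass
class ScoreRecord:
    well_id: str
    condition: str
    day: float
    replicate: str
    score: float


@dataclass
class HitCall:
    condition: str
    mean_score: float
    control_mean: float
    delta: float
    is_hit: bool
    direction: str  # enhancer / suppressor / none


def validate_scores(records, grid=DEFAULT_GRID) -> list:
    """Reject off-grid scores; returns the validated list.

    Raises naming the offending well and condition.  Warns when a condition
    has fewer than 3 replicates (the screen expects 3-4).
    """
    grid_set = set(float(g) for g in grid)
    out = []
    counts: dict = {}
    for rec in records:
        if float(rec.score) not in grid_set:
            raise ValueError(
                f"off-grid score {rec.score} in well {rec.well_id!r} "
                f"(condition {rec.condition!r}); grid={sorted(grid_set)}"
            )
        counts[rec.condition] = counts.get(rec.condition, 0) + 1
        out.append(rec)
    for cond, n in counts.items():
        if n < 3:
            warnings.warn(
                f"condition {cond!r} has only {n} replicate(s); 3-4 expected",
                stacklevel=2,
            )
    return out


def call_hits(records, control_name: str, threshold: float = 0.5) -> list:
    """Per-condition hit call against the matched control mean.

    is_hit when |mean - control_mean| >= threshold (inclusive, "at least" the
    lowest visible difference); delta >= threshold is an enhancer, delta <=
    -threshold a suppressor.
    """
    by_cond: dict = {}
    for rec in records:
        by_cond.setdefault(rec.condition, []).append(float(rec.score))
    if control_name not in by_cond:
        raise ValueError(f"control condition {control_name!r} not present")
    control_mean = float(np.mean(by_cond[control_name]))
    calls = []
    for cond in sorted(by_cond):
        if cond == control_name:
            continue
        mean = float(np.mean(by_cond[cond]))
        delta = mean - control_mean
        if delta >= threshold:
            direction, hit = "enhancer", True
        elif delta <= -threshold:
            direction, hit = "suppressor", True
        else:
            direction, hit = "none", False
        calls.append(
            HitCall(
                condition=cond,
                mean_score=mean,
                control_mean=control_mean,
                delta=delta,
                is_hit=hit,
                direction=direction,
            )
        )
    return calls


def timecourse_score_summary(records) -> tuple:
    """Day x condition mean +- SEM table plus a two-way factorial ANOVA.

    Returns (summary DataFrame, anova DataFrame).  The ANOVA (score ~ day *
    condition, both categorical) is routine plumbing over an ordinary linear
    model.
    """
    df = pd.DataFrame(
        [
            {
                "condition": r.condition,
                "day": r.day,
                "replicate": r.replicate,
                "score": float(r.score),
            }
            for r in records
        ]
    )
    if df.empty or df["day"].nunique() < 2:
        raise ValueError("time-course summary needs scores on at least 2 days")
    if df["condition"].nunique() < 2:
        raise ValueError("time-course summary needs at least 2 conditions")
    cell_counts = df.groupby(["day", "condition"]).size().unstack()
    if cell_counts.isna().any().any():
        raise ValueError("every day x condition cell needs at least one score")
    summary = (
        df.groupby(["day", "condition"])["score"]
        .agg(mean="mean", sem=lambda v: v.sem() if len(v) > 1 else 0.0, n="size")
        .reset_index()
    )
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("score ~ C(day) * C(condition)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate (noise-free) designs
        anova = sm.stats.anova_lm(model, typ=2)
    return summary, anova
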