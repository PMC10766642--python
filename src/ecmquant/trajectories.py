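"""Aging-trajectory classification of matrisome molecules.

Each molecule carries time courses on up to four levels — mRNA abundance,
whole-proteome protein level, de-novo synthesis rate, and in-vivo ECM-reporter
intensity.  A time course is called down-, un-, or up-regulated during aging
when the Pearson and Spearman correlation coefficients of value versus age
agree in sign and both exceed a magnitude threshold tau.  Synthesis rates are
instead compared to the grand mean production rate across all molecules.
Collagens are then assigned to three dynamic patterns:

* Pattern I   — mRNA, protein, and ECM abundance all decline;
* Pattern II  — mRNA declines but the protein persists (unchanged or up) in
  the matrix;
* Pattern III — mRNA unchanged (or only mildly declining) while matrix protein
  accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LEVELS = ("mRNA", "protein", "synthesis", "reporter")
CALLS = ("down", "unchanged", "up")


@dataclass
class TrajectorySeries:
    """One molecule's time course on one level.

    points: list of (age_days, replicate_id, value) tuples; replicates are
    treated as individual samples when correlating against age.
    """

    molecule_id: str
    level: str
    points: list

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if not all(np.isfinite(p[2]) for p in self.points):
            raise ValueError(f"non-finite value in series {self.molecule_id}")

    @property
    def ages(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([p[2] for p in self.points], dtype=float)


@dataclass
class TrendCall:
    molecule_id: str
    level: str
    pearson_r: float
    spearman_rho: float
    call: str


@dataclass
class PatternCall:
    molecule_id: str
    mrna_call: str | None = None
    protein_call: str | None = None
    reporter_call: str | None = None
    mrna_mild_decline: bool = False
    pattern: str = "unclassified"


def classify_trend(
    series: TrajectorySeries,
    tau: float = 0.5,
    use_pvalue: bool = False,
    alpha: float = 0.05,
) -> TrendCall:
    """Call a time course down/unchanged/up from the agreement of Pearson and
    Spearman correlations of value versus age.

    down if r <= -tau and rho <= -tau; up if r >= tau and rho >= tau; else
    unchanged.  A constant series is unchanged by convention.  With
    ``use_pvalue`` the rule is instead agreement in sign with both
    correlations significant at ``alpha``.
    """
    ages, values = series.ages, series.values
    if len(np.unique(ages)) < 3:
        raise ValueError(
            f"series {series.molecule_id} needs >=3 distinct ages for classification"
        )
    if np.all(values == values[0]):
        return TrendCall(series.molecule_id, series.level, 0.0, 0.0, "unchanged")
    pearson = stats.pearsonr(ages, values)
    spearman = stats.spearmanr(ages, values)  # average ranks for ties
    r, rho = float(pearson.statistic), float(spearman.statistic)
    if use_pvalue:
        agree = (
            np.sign(r) == np.sign(rho)
            and pearson.pvalue < alpha
            and spearman.pvalue < alpha
        )
        if agree:
            call = "down" if r < 0 else "up"
        else:
            call = "unchanged"
    else:
        if r <= -tau and rho <= -tau:
            call = "down"
        elif r >= tau and rho >= tau:
            call = "up"
        else:
            call = "unchanged"
    return TrendCall(series.molecule_id, series.level, r, rho, call)


def classify_synthesis(
    series: TrajectorySeries, all_series, k: float = 1.0
) -> TrendCall:
    """Call a de-novo synthesis rate lower/unchanged/elevated relative to the
    overall mean protein production across molecules (+- k standard
    deviations of the per-molecule means)."""
    all_series = list(all_series)
    if len(all_series) < 2:
        raise ValueError("synthesis classification needs >=2 molecules")
    per_molecule = np.array([s.values.mean() for s in all_series])
    grand_mean = per_molecule.mean()
    sd = per_molecule.std(ddof=1)
    own = series.values.mean()
    if own < grand_mean - k * sd:
        call = "down"
    elif own > grand_mean + k * sd:
        call = "up"
    else:
        call = "unchanged"
    # report the standardized offset in the correlation slots' place: not a
    # correlation, so record NaN correlations and the call only
    return TrendCall(series.molecule_id, "synthesis", float("nan"), float("nan"), call)


def assign_pattern(
    molecule_id: str,
    mrna_call: str | None,
    protein_call: str | None = None,
    reporter_call: str | None = None,
    mrna_mild_decline: bool = False,
) -> PatternCall:
    """Assign a collagen to dynamic pattern I, II, or III from its level calls.

    Requires an mRNA call and at least one of protein/reporter; otherwise the
    molecule stays unclassified.  ``mrna_mild_decline`` marks a down-called
    mRNA whose decline is only mild (down at a relaxed threshold but not the
    strict one), which routes an accumulating protein to pattern III.
    """
    pc = PatternCall(
        molecule_id=molecule_id,
        mrna_call=mrna_call,
        protein_call=protein_call,
        reporter_call=reporter_call,
        mrna_mild_decline=mrna_mild_decline,
    )
    present = [c for c in (protein_call, reporter_call) if c is not None]
    if mrna_call is None or not present:
        return pc
    any_up = any(c == "up" for c in present)
    if mrna_call == "unchanged" and any_up:
        pc.pattern = "III"
    elif mrna_call == "down" and mrna_mild_decline and any_up:
        pc.pattern = "III"
    elif mrna_call == "down":
        if all(c == "down" for c in present):
            pc.pattern = "I"
        else:  # any protein/reporter unchanged or up
            pc.pattern = "II"
    return pc


# ---------------------------------------------------------------------------
# Table-level drivers


def classify_table(
    table: pd.DataFrame,
    tau: float = 0.5,
    tau_mild: float = 0.25,
    k: float = 1.0,
    use_pvalue: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every (molecule, level) series in a long-format table.

    Expects columns molecule_id, level, age_days, replicate, value.  Synthesis
    series are classified against the grand mean; all other levels by the
    correlation-agreement rule.  Returns one row per series with r, rho, call,
    and for mRNA series whether the decline is only mild.
    """
    required = {"molecule_id", "level", "age_days", "replicate", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    series_by_level: dict = {}
    for (mol, level), grp in table.groupby(["molecule_id", "level"], sort=True):
        pts = list(zip(grp["age_days"], grp["replicate"], grp["value"]))
        series_by_level.setdefault(level, []).append(
            TrajectorySeries(molecule_id=mol, level=level, points=pts)
        )
    rows = []
    for level, series_list in series_by_level.items():
        for s in series_list:
            if level == "synthesis":
                call = classify_synthesis(s, series_list, k=k)
                mild = False
            else:
                call = classify_trend(s, tau=tau, use_pvalue=use_pvalue, alpha=alpha)
                # mild decline: down at the relaxed threshold but not the strict
                mild = (
                    level == "mRNA"
                    and call.call != "down"
                    and call.pearson_r <= -tau_mild
                    and call.spearman_rho <= -tau_mild
                )
            rows.append(
                {
                    "molecule_id": s.molecule_id,
                    "level": level,
                    "pearson_r": call.pearson_r,
                    "spearman_rho": call.spearman_rho,
                    "call": call.call,
                    "mild_decline": mild,
                }
            )
    return pd.DataFrame(rows)


def pattern_table(
    calls: pd.DataFrame, tau: float = 0.5, tau_mild: float = 0.25
) -> pd.DataFrame:
    """Assign patterns per molecule from a calls table (output of
    ``classify_table``).

    A down-called mRNA is additionally tested at the relaxed threshold
    ``tau_mild``: an mRNA that is down at tau_mild but *not* at tau counts as
    a mild decline, eligible for pattern III when the protein accumulates.
    """
    out = []
    for mol, grp in calls.groupby("molecule_id", sort=True):
        by_level = {row["level"]: row for _, row in grp.iterrows()}

        def _call(level):
            row = by_level.get(level)
            return None if row is None else row["call"]

        mrna = by_level.get("mRNA")
        mild = False
        if mrna is not None and np.isfinite(mrna["pearson_r"]):
            r, rho = mrna["pearson_r"], mrna["spearman_rho"]
            down_strict = r <= -tau and rho <= -tau
            down_mild = r <= -tau_mild and rho <= -tau_mild
            mild = down_mild and not down_strict
        mrna_call = _call("mRNA")
        if mild and mrna_call == "unchanged":
            # mildly declining mRNA: treat as down with the mild flag so the
            # pattern rule can route it to III
            mrna_call = "down"
        pc = assign_pattern(
            molecule_id=mol,
            mrna_call=mrna_call,
            protein_call=_call("protein"),
            reporter_call=_call("reporter"),
            mrna_mild_decline=mild,
        )
        out.append(
            {
                "molecule_id": mol,
                "mrna_call": pc.mrna_call,
                "protein_call": pc.protein_call,
                "reporter_call": pc.reporter_call,
                "mrna_mild_decline": pc.mrna_mild_decline,
                "pattern": pc.pattern,
            }
        )
    return pd.DataFrame(out)


def pattern_counts(patterns: pd.DataFrame) -> dict:
    """Summary counts per pattern (I, II, III, unclassified)."""
    counts = patterns["pattern"].value_counts().to_dict()
    return {p: int(counts.get(p, 0)) for p in ("I", "II", "III", "unclassified")}
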