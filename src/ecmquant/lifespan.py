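"""Lifespan statistics: mean-lifespan extension, within-batch epistasis, and
diagonal-plot preparation, plus the applied-pressure computation.

Lifespan extension is expressed as a percentage of the control mean,
100 * (mean_treated - mean_control) / mean_control.  Epistasis between a
matrisome mutant and a longevity treatment is the difference, in percentage
points, between the mutant's extension and the wild-type extension measured
within the same experimental batch: a full suppressor drags the delta down to
minus the wild-type extension.  Censored animals (lost, bagged) are excluded
from mean lifespans, the standard worm-lifespan convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass
class SurvivalRecord:
    animal_id: str
    genotype: str
    treatment: str
    batch: str
    event_day: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.event_day <= 0:
            raise ValueError(f"event_day must be > 0 (animal {self.animal_id})")


@dataclass
class ExtensionResult:
    genotype: str
    batch: str
    mean_ctrl: float
    mean_trt: float
    extension_pct: float


@dataclass
class PressureSpec:
    mass: float
    area: float
    g: float = STANDARD_GRAVITY

    @property
    def pressure(self) -> float:
        return self.mass * self.g / self.area


def mean_lifespan(records) -> float:
    """Arithmetic mean adult day of death over uncensored animals."""
    days = [r.event_day for r in records if not r.censored]
    if not days:
        raise ValueError("no uncensored animals: mean lifespan undefined")
    return float(np.mean(days))


def extension_pct(
    ctrl_records, trt_records, genotype: str = "", batch: str = ""
) -> ExtensionResult:
    """Percent mean-lifespan extension of the treated arm over control."""
    mean_ctrl = mean_lifespan(ctrl_records)
    mean_trt = mean_lifespan(trt_records)
    pct = 100.0 * (mean_trt - mean_ctrl) / mean_ctrl
    return ExtensionResult(
        genotype=genotype,
        batch=batch,
        mean_ctrl=mean_ctrl,
        mean_trt=mean_trt,
        extension_pct=pct,
    )


def epistasis_delta(mutant: ExtensionResult, wildtype: ExtensionResult) -> float:
    """Mutant extension minus wild-type extension, in percentage points,
    within one batch.  Cross-batch input is an error, never silently pooled."""
    if mutant.batch != wildtype.batch:
        raise ValueError(
            f"epistasis delta requires matching batches "
            f"({mutant.batch!r} vs {wildtype.batch!r})"
        )
    return mutant.extension_pct - wildtype.extension_pct


def diagonal_table(extensions, wildtype_genotype: str = "N2") -> pd.DataFrame:
    """One row per genotype x batch with control and treated mean lifespans,
    for plotting treated against control means along the diagonal."""
    rows = [
        {
            "genotype": e.genotype,
            "batch": e.batch,
            "mean_ctrl": e.mean_ctrl,
            "mean_trt": e.mean_trt,
            "extension_pct": e.extension_pct,
            "is_wildtype": e.genotype == wildtype_genotype,
        }
        for e in extensions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "batch",
            "mean_ctrl",
            "mean_trt",
            "extension_pct",
            "is_wildtype",
        ],
    )


def applied_pressure(mass: float, area: float, g: float = STANDARD_GRAVITY) -> float:
    """Pressure in pascals from a resting mass on a contact area: m*g/A."""
    if mass < 0:
        raise ValueError("mass must be >= 0")
    if area <= 0:
        raise ValueError("area must be > 0")
    return PressureSpec(mass=mass, area=area, g=g).pressure


def format_pressure(pa: float) -> str:
    return f"{pa:.1f} Pa"


# ---------------------------------------------------------------------------
# Routine survival-curve plumbing


def logrank_pvalue(records_a, records_b) -> float:
    """Two-group log-rank test p-value (censoring respected)."""
    from lifelines.statistics import logrank_test

    a_days = [r.event_day for r in records_a]
    a_obs = [not r.censored for r in records_a]
    b_days = [r.event_day for r in records_b]
    b_obs = [not r.censored for r in records_b]
    res = logrank_test(a_days, b_days, event_observed_A=a_obs, event_observed_B=b_obs)
    return float(res.p_value)


def kaplan_meier(records):
    """Fitted Kaplan-Meier estimator for one arm."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(
        [r.event_day for r in records],
        event_observed=[not r.censored for r in records],
    )
    return km


def records_from_table(df: pd.DataFrame) -> list:
    """Build survival records from a table with columns animal_id, genotype,
    treatment, batch, event_day, censored."""
    return [
        SurvivalRecord(
            animal_id=str(row["animal_id"]),
            genotype=str(row["genotype"]),
            treatment=str(row["treatment"]),
            batch=str(row["batch"]),
            event_day=float(row["event_day"]),
            censored=bool(row["censored"]),
        )
        for _, row in df.iterrows()
    ]
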