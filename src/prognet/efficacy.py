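"""Tumor response classification and efficacy summaries.

Response categories follow the RECIST reading used throughout the package:
CR when all target lesions are undetectable for at least four weeks, PD on
any new lesion or a ≥ 20% increase of the summed target-lesion long
diameters over baseline, PR on a reduction of *more than* 30% (the strict
boundary; standard RECIST 1.1 uses ≥ 30% and is available via
``recist_dialect="recist11"``), otherwise SD.  Group-level efficacy is
summarized by the objective response rate ORR = (CR+PR)/n and the disease
control rate DCR = (CR+PR+SD)/n, both in percent.  Progression-free
survival uses the Kaplan–Meier product-limit estimator with the median at
the earliest time the curve reaches 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

__all__ = [
    "LesionAssessment",
    "EfficacySummary",
    "KMEstimate",
    "classify_response",
    "efficacy_rates",
    "km_curve",
    "chi2_compare",
]

CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class LesionAssessment:
    """Summed target-lesion long diameters at baseline and follow-up (mm)."""

    patient_id: str
    baseline_sum_mm: float
    followup_sum_mm: float
    undetectable: bool = False
    new_lesion: bool = False

    def __post_init__(self) -> None:
        if self.baseline_sum_mm < 0 or self.followup_sum_mm < 0:
            raise ValueError("diameter sums must be non-negative")
        if self.undetectable and self.followup_sum_mm != 0:
            raise ValueError("undetectable lesions imply a zero follow-up sum")


def classify_response(a: LesionAssessment, duration_ok: bool = True,
                      recist_dialect: str = "strict") -> str:
    """Classify one assessment as CR, PR, SD or PD.

    Precedence: CR (all lesions undetectable, sustained ≥ 4 weeks), then PD
    (new lesion, or follow-up ≥ 1.20 × baseline), then PR (follow-up below
    0.70 × baseline under the default strict dialect; ≤ 0.70 × baseline
    under ``recist11``), else SD.
    """
    if a.baseline_sum_mm <= 0:
        raise ValueError("baseline sum must be positive")
    if recist_dialect not in ("strict", "recist11"):
        raise ValueError("recist_dialect must be 'strict' or 'recist11'")
    if a.undetectable and duration_ok:
        return "CR"
    if a.new_lesion or a.followup_sum_mm >= 1.20 * a.baseline_sum_mm:
        return "PD"
    pr_cut = 0.70 * a.baseline_sum_mm
    if (a.followup_sum_mm < pr_cut if recist_dialect == "strict"
            else a.followup_sum_mm <= pr_cut):
        return "PR"
    return "SD"


@dataclass(frozen=True)
class EfficacySummary:
    """Per-category counts with the derived ORR and DCR (percent)."""

    cr: int
    pr: int
    sd: int
    pd: int
    orr_pct: float
    dcr_pct: float
    group: str = ""

    @property
    def n(self) -> int:
        return self.cr + self.pr + self.sd + self.pd

    def __post_init__(self) -> None:
        if min(self.cr, self.pr, self.sd, self.pd) < 0:
            raise ValueError("counts must be non-negative")
        if not self.orr_pct <= self.dcr_pct <= 100.0:
            raise ValueError("requires ORR ≤ DCR ≤ 100")


def efficacy_rates(cr: int, pr: int, sd: int, pd_: int,
                   group: str = "") -> EfficacySummary:
    """ORR = 100·(CR+PR)/n and DCR = 100·(CR+PR+SD)/n, to 0.1%."""
    total = cr + pr + sd + pd_
    if total <= 0:
        raise ValueError("total cases must be positive")
    orr = round(100.0 * (cr + pr) / total, 1)
    dcr = round(100.0 * (cr + pr + sd) / total, 1)
    return EfficacySummary(cr, pr, sd, pd_, orr, dcr, group)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve with its median."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    median_defined: bool

    def step(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> KMEstimate:
    """Kaplan–Meier product-limit estimate of progression-free survival.

    ``events`` flags observed progressions; censored records leave the
    risk set without contributing an event factor.  The median is the
    earliest time at which the estimate is ≤ 0.5 and is flagged undefined
    when the curve never reaches it.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("at least one record required")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    defined = bool(np.isfinite(median))
    if not defined:
        logger.warning("survival curve never reaches 0.5; median undefined")
        median = float("nan")
    return KMEstimate(grid, surv, at_risk, median, defined)


def chi2_compare(successes: tuple[int, int], totals: tuple[int, int],
                 correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square comparison of two proportions (df = 1).

    ``correction`` applies the Yates continuity correction.  Degenerate
    margins (an empty group, or an all-success / all-failure pooled column)
    raise an error.
    """
    s1, s2 = successes
    n1, n2 = totals
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= s1 <= n1 and 0 <= s2 <= n2):
        raise ValueError("successes must lie within totals")
    table = np.array([[s1, n1 - s1], [s2, n2 - s2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate margin in 2×2 table")
    stat, p, _, _ = chi2_contingency(table, correction=correction)
    return float(stat), float(p)
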