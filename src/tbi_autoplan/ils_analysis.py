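"""Incident-learning-system analytics for TBI planning reports.

Descriptive statistics over departmental incident reports: zero-filled
per-quarter series, half-up percentage proportions, the overrepresentation
factor of one treatment type among planning reports, and pre/post-intervention
summaries around the quarter in which automation went live.

A bundled example audit (:data:`DEPARTMENT_AUDIT`, :func:`example_tbi_reports`)
carries the headline counts of a 6.5-year single-institution audit: 9108
distinct patients of whom 411 received TBI, 1566 incident reports of which 470
were planning-related and 24 concerned TBI planning, and 35 TBI reports in
total across 25 pre-automation quarters.  The per-quarter spread of those 35
reports is not part of the published tallies, so the example dataset
distributes them deterministically; totals, marginals and the mean rate are
the fixed quantities.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("treatment", "documentation", "field_issue", "other")
CLASSIFICATIONS = ("operational_workflow", "unsafe_condition", "near_miss", "other")
TREATMENT_TYPES = ("TBI", "other")


class IlsError(Exception):
    pass


@dataclass(frozen=True)
class IncidentReport:
    """One incident-learning-system entry."""

    report_date: _dt.date
    treatment_type: str
    category: str
    classification: str
    planning_related: bool

    def __post_init__(self) -> None:
        if self.treatment_type not in TREATMENT_TYPES:
            raise IlsError(f"treatment_type {self.treatment_type!r} not in {TREATMENT_TYPES}")
        if self.category not in CATEGORIES:
            raise IlsError(f"category {self.category!r} not in {CATEGORIES}")
        if self.classification not in CLASSIFICATIONS:
            raise IlsError(f"classification {self.classification!r} not in {CLASSIFICATIONS}")


CSV_COLUMNS = ["report_date", "treatment_type", "category", "classification",
               "planning_related"]


def load_reports(path: str | Path, strict: bool = False) -> list[IncidentReport]:
    """Read incident reports from CSV (header: ``report_date,treatment_type,
    category,classification,planning_related``).

    Malformed rows are logged and skipped, or raise in strict mode.
    """
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != CSV_COLUMNS:
        raise IlsError(f"CSV header must be {','.join(CSV_COLUMNS)}")
    reports: list[IncidentReport] = []
    for i, row in df.iterrows():
        try:
            reports.append(IncidentReport(
                report_date=_dt.date.fromisoformat(row["report_date"]),
                treatment_type=row["treatment_type"],
                category=row["category"],
                classification=row["classification"],
                planning_related=str(row["planning_related"]).lower() in ("true", "1", "yes"),
            ))
        except (IlsError, ValueError, TypeError) as exc:
            if strict:
                raise IlsError(f"row {i}: {exc}") from exc
            logger.warning("skipping malformed row %d: %s", i, exc)
    return reports


def save_reports(reports: list[IncidentReport], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "report_date": r.report_date.isoformat(),
                "treatment_type": r.treatment_type,
                "category": r.category,
                "classification": r.classification,
                "planning_related": r.planning_related,
            }
            for r in reports
        ],
        columns=CSV_COLUMNS,
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# core statistics

def proportion(numerator: int, denominator: int) -> float:
    """Percentage, rounded half-up to one decimal."""
    if denominator <= 0:
        raise IlsError("denominator must be > 0")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def overrepresentation_factor(share_a: float, share_b: float) -> float:
    """Ratio of two shares, rounded half-up to one decimal."""
    if share_b == 0:
        raise IlsError("reference share must be non-zero")
    ratio = Decimal(repr(share_a)) / Decimal(repr(share_b))
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def quarterly_series(
    reports: list[IncidentReport],
    window_start: _dt.date,
    window_end: _dt.date,
) -> pd.Series:
    """Zero-filled counts per calendar quarter over [window_start, window_end].

    Reports outside the window are excluded with a logged notice.
    """
    if window_end < window_start:
        raise IlsError("window_end before window_start")
    quarters = pd.period_range(window_start, window_end, freq="Q")
    counts = pd.Series(0, index=quarters, dtype=int)
    for r in reports:
        q = pd.Period(r.report_date, freq="Q")
        if q in counts.index:
            counts[q] += 1
        else:
            logger.info("report on %s outside window, excluded", r.report_date)
    return counts


@dataclass
class IlsSummary:
    """Descriptive summary of a set of reports over a quarter window."""

    total: int
    n_quarters: int
    per_quarter: list[int]
    mean_per_quarter: float
    sd_per_quarter: float
    counts_by_category: dict[str, int] = field(default_factory=dict)
    counts_by_classification: dict[str, int] = field(default_factory=dict)
    proportions_by_category: dict[str, float] = field(default_factory=dict)
    proportions_by_classification: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "n_quarters": self.n_quarters,
            "per_quarter": self.per_quarter,
            "mean_per_quarter": self.mean_per_quarter,
            "sd_per_quarter": self.sd_per_quarter,
            "counts_by_category": self.counts_by_category,
            "counts_by_classification": self.counts_by_classification,
            "proportions_by_category": self.proportions_by_category,
            "proportions_by_classification": self.proportions_by_classification,
        }


def summarize(
    reports: list[IncidentReport],
    window_start: _dt.date,
    window_end: _dt.date,
) -> IlsSummary:
    series = quarterly_series(reports, window_start, window_end)
    in_window = [r for r in reports
                 if pd.Period(r.report_date, freq="Q") in series.index]
    cat = {c: sum(r.category == c for r in in_window) for c in CATEGORIES}
    cls = {c: sum(r.classification == c for r in in_window) for c in CLASSIFICATIONS}
    total = int(series.sum())
    return IlsSummary(
        total=total,
        n_quarters=len(series),
        per_quarter=series.tolist(),
        mean_per_quarter=float(series.mean()),
        sd_per_quarter=float(series.std(ddof=1)) if len(series) > 1 else 0.0,
        counts_by_category=cat,
        counts_by_classification=cls,
        proportions_by_category={c: proportion(n, total) for c, n in cat.items() if total},
        proportions_by_classification={c: proportion(n, total) for c, n in cls.items() if total},
    )


def pre_post_summary(
    reports: list[IncidentReport],
    window_start: _dt.date,
    window_end: _dt.date,
    intervention_date: _dt.date,
) -> tuple[IlsSummary, IlsSummary]:
    """Summaries before and after an intervention.

    The quarter containing ``intervention_date`` belongs to the *pre* period
    (the change took effect at that quarter's end).
    """
    iq = pd.Period(intervention_date, freq="Q")
    pre_end = min(iq.end_time.date(), window_end)
    if not window_start <= intervention_date <= window_end:
        raise IlsError("intervention date outside window")
    pre = summarize(reports, window_start, pre_end)
    if pre_end >= window_end:
        post = IlsSummary(0, 0, [], 0.0, 0.0)
    else:
        post_start = (iq + 1).start_time.date()
        post = summarize(reports, post_start, window_end)
    return pre, post


# ---------------------------------------------------------------------------
# synthetic generator

def generate_reports(
    seed: int,
    rate_per_quarter: float = 1.4,
    window_start: _dt.date = _dt.date(2013, 1, 1),
    window_end: _dt.date = _dt.date(2019, 3, 31),
    treatment_type: str = "TBI",
) -> list[IncidentReport]:
    """Seeded Poisson report stream: Poisson(rate) reports in each quarter,
    uniform dates within the quarter, categories/classifications sampled from
    the example audit's empirical mix."""
    rng = np.random.default_rng(seed)
    quarters = pd.period_range(window_start, window_end, freq="Q")
    cat_p = np.array([11, 12, 12, 0], dtype=float)
    cls_p = np.array([17, 11, 7, 0], dtype=float)
    cat_p /= cat_p.sum()
    cls_p /= cls_p.sum()
    reports: list[IncidentReport] = []
    for q in quarters:
        n = rng.poisson(rate_per_quarter)
        days = (q.end_time.date() - q.start_time.date()).days
        for _ in range(n):
            reports.append(IncidentReport(
                report_date=q.start_time.date() + _dt.timedelta(days=int(rng.integers(0, days + 1))),
                treatment_type=treatment_type,
                category=str(rng.choice(CATEGORIES, p=cat_p)),
                classification=str(rng.choice(CLASSIFICATIONS, p=cls_p)),
                planning_related=bool(rng.random() < 24 / 35),
            ))
    return reports


# ---------------------------------------------------------------------------
# bundled example audit

#: Headline counts of the bundled 6.5-year departmental audit
#: (January 2013 – June 2019; automation went live at the end of 2019 Q1).
DEPARTMENT_AUDIT = {
    "patients_total": 9108,
    "patients_tbi": 411,
    "reports_total": 1566,
    "reports_planning_related": 470,
    "reports_tbi": 35,
    "reports_tbi_planning_related": 24,
    "tbi_classification": {"operational_workflow": 17, "unsafe_condition": 11,
                           "near_miss": 7},
    "tbi_category": {"treatment": 11, "documentation": 12, "field_issue": 12},
    "window_start": _dt.date(2013, 1, 1),
    "window_end": _dt.date(2019, 6, 30),
    "pre_automation_end": _dt.date(2019, 3, 31),  # 25 quarters from 2013 Q1
    "automation_date": _dt.date(2019, 3, 31),
}


def example_tbi_reports() -> list[IncidentReport]:
    """The audit's 35 TBI reports as report objects.

    Marginals (category 11/12/12, classification 17/11/7, 24 planning-related)
    match the audit exactly; dates spread the reports deterministically over
    the 25 pre-automation quarters, since the audit publishes only the totals.
    """
    cats = (["treatment"] * 11 + ["documentation"] * 12 + ["field_issue"] * 12)
    clss = (["operational_workflow"] * 17 + ["unsafe_condition"] * 11 +
            ["near_miss"] * 7)
    planning = [True] * 24 + [False] * 11
    quarters = pd.period_range(DEPARTMENT_AUDIT["window_start"],
                               DEPARTMENT_AUDIT["pre_automation_end"], freq="Q")
    reports = []
    for i in range(35):
        q = quarters[(i * 7) % len(quarters)]  # deterministic spread
        reports.append(IncidentReport(
            report_date=q.start_time.date() + _dt.timedelta(days=14),
            treatment_type="TBI",
            category=cats[i],
            classification=clss[i],
            planning_related=planning[i],
        ))
    return reports


def plot_quarterly(series: pd.Series, path: str | Path,
                   intervention: _dt.date | None = None) -> Path:
    """Bar chart of reports per quarter, optionally marking the intervention."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    labels = [str(p) for p in series.index]
    ax.bar(range(len(series)), series.values, color="steelblue")
    ax.set_xticks(range(len(series)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("TBI planning reports")
    ax.set_xlabel("quarter")
    if intervention is not None:
        iq = pd.Period(intervention, freq="Q")
        if iq in series.index:
            pos = list(series.index).index(iq)
            ax.axvline(pos + 0.5, color="firebrick", linestyle="--",
                       label="automation go-live")
            ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
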