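"""Comparison, trend, and gap outputs for quality monitoring.

All functions are pure: the same reports always yield byte-identical tables.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .scoring import ScoreReport, Verdict

__all__ = ["compare", "trend", "gap_summary"]


def _check_same_version(reports: Sequence[ScoreReport]) -> None:
    versions = sorted({r.registry_version for r in reports})
    if len(versions) > 1:
        raise ValueError(
            f"reports scored against mixed registry versions: {versions}"
        )


def compare(reports: Sequence[ScoreReport]) -> pd.DataFrame:
    """Rank ICU visits by percentage of maximum (ties broken by icu_id).

    One row per (icu_id, visit_date) with total, maximum, percentage, and one
    ``<domain>_earned`` / ``<domain>_max`` column pair per domain.
    """
    if not reports:
        raise ValueError("no reports to compare")
    _check_same_version(reports)
    rows = []
    for r in reports:
        row = {
            "icu_id": r.icu_id,
            "visit_date": r.visit_date,
            "total_points": r.total_points,
            "max_points": r.max_points,
            "percentage": r.percentage,
        }
        for dom, (earned, mx) in r.domain_subscores.items():
            row[f"{dom}_earned"] = earned
            row[f"{dom}_max"] = mx
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["percentage", "icu_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def trend(reports: Sequence[ScoreReport]) -> pd.DataFrame:
    """Per-visit series for one ICU with deltas versus the previous visit.

    Reports are ordered by visit date; the first visit has no delta (NA).
    Deltas are exact integer differences of totals and of per-domain earned
    points.
    """
    if not reports:
        raise ValueError("no reports")
    icus = sorted({r.icu_id for r in reports})
    if len(icus) > 1:
        raise ValueError(f"trend expects a single ICU, got {icus}")
    _check_same_version(reports)
    ordered = sorted(reports, key=lambda r: r.visit_date)
    rows = []
    prev: ScoreReport | None = None
    for r in ordered:
        row = {
            "icu_id": r.icu_id,
            "visit_date": r.visit_date,
            "total_points": r.total_points,
            "percentage": r.percentage,
            "delta_total": (r.total_points - prev.total_points) if prev else pd.NA,
        }
        for dom, (earned, _) in r.domain_subscores.items():
            row[f"{dom}_earned"] = earned
            if prev is not None:
                row[f"delta_{dom}"] = earned - prev.domain_subscores[dom][0]
            else:
                row[f"delta_{dom}"] = pd.NA
        rows.append(row)
        prev = r
    return pd.DataFrame(rows)


def gap_summary(report: ScoreReport) -> pd.DataFrame:
    """Items that earned no point, grouped by domain, with member verdicts.

    The ``reason`` column distinguishes genuine failures from missing-data
    penalties — the actionable "quality gap list" for targeted support.
    """
    rows = []
    for s in report.item_scores:
        if s.excluded or s.points == 1:
            continue
        rows.append(
            {
                "domain": s.domain.value,
                "item_id": s.item_id,
                "reason": "missing data" if s.penalty else "failed",
                "penalty": s.penalty,
                "verdicts": ";".join(
                    f"{c}={v.value}" for c, v in s.member_verdicts.items()
                ),
                "failing_codes": ";".join(
                    c
                    for c, v in s.member_verdicts.items()
                    if v in (Verdict.failed, Verdict.missing)
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["domain", "item_id", "reason", "penalty", "verdicts", "failing_codes"],
    )
    return df.sort_values(["domain", "item_id"], kind="mergesort").reset_index(
        drop=True
    )
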