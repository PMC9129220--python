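"""The 26-point scoring engine.

Each score item is worth one point.  A grouped item earns its point only if
every member indicator passes its dichotomization rule ("1p if all true, 0p
if at least one false").  An item containing a missing response earns zero
points AND deducts one penalty point from the total sum; the total is floored
at zero so the percentage of maximum stays in [0, 100].

Two behaviours are configurable:

* ``penalty``: ``per_item`` (default; one deduction per item with any missing
  member) or ``per_indicator`` (one deduction per missing member indicator,
  for sensitivity analysis).
* ``na``: how not-applicable responses score — ``vacuous`` (default; absence
  of eligible patients cannot demonstrate substandard care, so the member
  counts as passing and is flagged) or ``exclude`` (an item whose members are
  all not-applicable is dropped and the maximum is reduced accordingly).
"""

from __future__ import annotations

import enum
import logging
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .assessment import Assessment, IndicatorResponse, ResponseStatus
from .registry import Comparator, Domain, PassRule, Registry, ScoreItem

__all__ = [
    "Verdict",
    "ScoringConfig",
    "ItemScore",
    "ScoreReport",
    "evaluate_rule",
    "score_item",
    "score_assessment",
]

logger = logging.getLogger(__name__)


class Verdict(str, enum.Enum):
    passed = "pass"
    failed = "fail"
    missing = "missing"
    not_applicable = "not_applicable"


class ScoringConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    penalty: Literal["per_item", "per_indicator"] = "per_item"
    na: Literal["vacuous", "exclude"] = "vacuous"


def evaluate_rule(rule: PassRule, resp: IndicatorResponse) -> Verdict:
    """Dichotomize one response against its rule.

    Boundary inclusivity is exactly as the protocol prints it: ``>= 0.5``
    passes at 0.5, ``<= 15`` passes at 15, ``> 12`` fails at 12.  Missing and
    not-applicable statuses propagate unchanged.
    """
    if resp.indicator_code != rule.indicator_code:
        raise ValueError(
            f"rule for {rule.indicator_code} applied to response "
            f"{resp.indicator_code}"
        )
    if resp.status is ResponseStatus.missing:
        return Verdict.missing
    if resp.status is ResponseStatus.not_applicable:
        return Verdict.not_applicable

    value = resp.value
    comp = rule.comparator
    if comp in (Comparator.is_yes, Comparator.is_no):
        if not isinstance(value, bool):
            raise TypeError(
                f"{rule.indicator_code}: yes/no rule needs a boolean, got {value!r}"
            )
        want = comp is Comparator.is_yes
        return Verdict.passed if value is want else Verdict.failed
    if comp is Comparator.count_eq_zero:
        if isinstance(value, bool) or not isinstance(value, int):
            raise TypeError(
                f"{rule.indicator_code}: count rule needs an integer, got {value!r}"
            )
        return Verdict.passed if value == 0 else Verdict.failed
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise TypeError(
            f"{rule.indicator_code}: numeric rule needs a number, got {value!r}"
        )
    t = rule.threshold
    ok = {
        Comparator.ge: value >= t,
        Comparator.le: value <= t,
        Comparator.gt: value > t,
    }[comp]
    return Verdict.passed if ok else Verdict.failed


class ItemScore(BaseModel):
    """Outcome of one score item for one assessment."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    domain: Domain
    points: int  # 0 or 1
    penalty: int  # missing-data deductions attributable to this item
    excluded: bool = False  # dropped from the denominator (na="exclude" only)
    member_verdicts: dict[str, Verdict]

    @property
    def has_missing(self) -> bool:
        return Verdict.missing in self.member_verdicts.values()


def score_item(
    item: ScoreItem, a: Assessment, config: Optional[ScoringConfig] = None
) -> ItemScore:
    """Score one item: all-must-pass conjunction plus the missing-data rule."""
    config = config or ScoringConfig()
    verdicts = {
        r.indicator_code: evaluate_rule(r, a.response(r.indicator_code))
        for r in item.rules
    }
    for code, v in verdicts.items():
        logger.debug("item %s: %s -> %s", item.item_id, code, v.value)

    n_missing = sum(v is Verdict.missing for v in verdicts.values())
    n_na = sum(v is Verdict.not_applicable for v in verdicts.values())
    n_fail = sum(v is Verdict.failed for v in verdicts.values())

    if n_missing:
        penalty = 1 if config.penalty == "per_item" else n_missing
        return ItemScore(
            item_id=item.item_id,
            domain=item.domain,
            points=0,
            penalty=penalty,
            member_verdicts=verdicts,
        )
    if config.na == "exclude" and n_na == len(verdicts):
        return ItemScore(
            item_id=item.item_id,
            domain=item.domain,
            points=0,
            penalty=0,
            excluded=True,
            member_verdicts=verdicts,
        )
    # under "vacuous" a not-applicable member counts as passing (flagged via
    # the verdict map); under "exclude" remaining NA members are ignored in
    # the conjunction
    points = item.points if n_fail == 0 else 0
    return ItemScore(
        item_id=item.item_id,
        domain=item.domain,
        points=points,
        penalty=0,
        member_verdicts=verdicts,
    )


class ScoreReport(BaseModel):
    """Full scoring result for one ICU visit."""

    model_config = ConfigDict(frozen=True)

    icu_id: str
    visit_date: str  # ISO date, kept as text for stable serialization
    registry_version: str
    config: ScoringConfig
    item_scores: tuple[ItemScore, ...]
    domain_subscores: dict[str, tuple[int, int]]  # domain -> (earned, max)
    total_points: int
    max_points: int
    percentage: float
    gap_list: tuple[str, ...]  # item_ids with zero points (failed or penalized)

    def to_frame(self) -> pd.DataFrame:
        """One row per item: item_id, domain, points, penalty, verdicts."""
        return pd.DataFrame(
            [
                {
                    "item_id": s.item_id,
                    "domain": s.domain.value,
                    "points": s.points,
                    "penalty": s.penalty,
                    "excluded": s.excluded,
                    "verdicts": ";".join(
                        f"{c}={v.value}" for c, v in s.member_verdicts.items()
                    ),
                }
                for s in self.item_scores
            ]
        )


def score_assessment(
    a: Assessment, reg: Registry, config: Optional[ScoringConfig] = None
) -> ScoreReport:
    """Score a full assessment: totals, domain subscores, percentage, gaps.

    ``total = max(0, sum(points) - sum(penalties))``;
    ``percentage = 100 * total / max`` reported to one decimal.
    """
    config = config or ScoringConfig()
    scores = tuple(score_item(item, a, config) for item in reg.items)

    included = [s for s in scores if not s.excluded]
    earned = sum(s.points for s in included)
    penalties = sum(s.penalty for s in included)
    total = max(0, earned - penalties)
    max_points = sum(
        item.points
        for item, s in zip(reg.items, scores)
        if not s.excluded
    )
    percentage = round(100.0 * total / max_points, 1) if max_points else 0.0

    domains: dict[str, tuple[int, int]] = {}
    for item, s in zip(reg.items, scores):
        if s.excluded:
            continue
        e, m = domains.get(item.domain.value, (0, 0))
        domains[item.domain.value] = (e + s.points, m + item.points)

    gaps = tuple(s.item_id for s in included if s.points == 0)
    logger.debug(
        "scored %s@%s: total=%d/%d (%.1f%%), penalties=%d",
        a.icu_id, a.visit_date, total, max_points, percentage, penalties,
    )
    return ScoreReport(
        icu_id=a.icu_id,
        visit_date=a.visit_date.isoformat(),
        registry_version=reg.version,
        config=config,
        item_scores=scores,
        domain_subscores=domains,
        total_points=total,
        max_points=max_points,
        percentage=percentage,
        gap_list=gaps,
    )
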