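"""Inter-rater concordance between duplicate collections of one ICU visit.

Two trained collectors fill the checklist independently at the same visit;
agreement is compared at the *classification* level: scored indicators are
compared on their dichotomized pass/fail verdict (a 14- vs 15-minute blood-gas
turnaround both pass and therefore agree), descriptive indicators on their
raw value.  Indicators not answered by both collectors are excluded from the
comparison and listed separately.

Cohen's kappa over the dichotomized verdicts is reported as a supplementary
chance-corrected statistic alongside raw percent agreement.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .assessment import Assessment, ResponseStatus
from .registry import Registry
from .scoring import ScoringConfig, Verdict, evaluate_rule, score_item

__all__ = ["AgreementReport", "concordance", "cohen_kappa"]


def cohen_kappa(x: Sequence[bool], y: Sequence[bool]) -> float:
    """Cohen's kappa for two paired binary ratings.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the marginal rates.  Degenerate tables where both
    raters are constant and identical (p_e = 1) have perfect observed
    agreement and are defined here as kappa = 1.0.
    """
    if len(x) != len(y):
        raise ValueError("rating vectors differ in length")
    n = len(x)
    if n == 0:
        return float("nan")
    po = sum(a == b for a, b in zip(x, y)) / n
    px, py = sum(x) / n, sum(y) / n
    pe = px * py + (1 - px) * (1 - py)
    if math.isclose(pe, 1.0):
        return 1.0
    return (po - pe) / (1 - pe)


class AgreementReport(BaseModel):
    """Indicator- and item-level concordance between two collections."""

    model_config = ConfigDict(frozen=True)

    icu_id: str
    visit_date: str
    collectors: tuple[str, str]
    # all-indicator framing (scored compared on verdict, descriptive on value)
    n_compared: int
    n_discordant: int
    percent_agreement: float
    discordant_codes: tuple[str, ...]
    excluded_codes: tuple[str, ...]  # not answered by both collectors
    # scored-only framing
    n_compared_scored: int
    n_discordant_scored: int
    percent_agreement_scored: float
    # item-level framing over the 26 score items
    n_items_compared: int
    n_items_discordant: int
    percent_agreement_items: float
    discordant_items: tuple[str, ...]
    kappa: float  # chance-corrected agreement on dichotomized verdicts


def _pct(n_agree: int, n_total: int) -> float:
    # nothing compared -> vacuous full agreement, kept in [0, 100]
    return round(100.0 * n_agree / n_total, 1) if n_total else 100.0


def concordance(
    a1: Assessment,
    a2: Assessment,
    reg: Registry,
    config: Optional[ScoringConfig] = None,
) -> AgreementReport:
    """Compare two collections of the same visit; symmetric in (a1, a2)."""
    if (a1.icu_id, a1.visit_date) != (a2.icu_id, a2.visit_date):
        raise ValueError(
            f"assessments describe different visits: "
            f"({a1.icu_id}, {a1.visit_date}) vs ({a2.icu_id}, {a2.visit_date})"
        )
    config = config or ScoringConfig()

    discordant: list[str] = []
    excluded: list[str] = []
    n_compared = 0
    n_compared_scored = 0
    n_discordant_scored = 0
    pairs: list[tuple[bool, bool]] = []  # dichotomized verdict pairs for kappa

    for ind in reg.indicators:
        r1, r2 = a1.response(ind.code), a2.response(ind.code)
        if (
            r1.status is not ResponseStatus.answered
            or r2.status is not ResponseStatus.answered
        ):
            excluded.append(ind.code)
            continue
        n_compared += 1
        rule = reg.rule_for(ind.code)
        if rule is not None:
            v1, v2 = evaluate_rule(rule, r1), evaluate_rule(rule, r2)
            pairs.append((v1 is Verdict.passed, v2 is Verdict.passed))
            n_compared_scored += 1
            agree = v1 is v2
            if not agree:
                n_discordant_scored += 1
        else:
            agree = r1.value == r2.value
        if not agree:
            discordant.append(ind.code)

    # item-level: compare earned points over items unaffected by missing data
    # in either collection
    item_discordant: list[str] = []
    n_items = 0
    for item in reg.items:
        s1 = score_item(item, a1, config)
        s2 = score_item(item, a2, config)
        if s1.has_missing or s2.has_missing or s1.excluded or s2.excluded:
            continue
        n_items += 1
        if s1.points != s2.points:
            item_discordant.append(item.item_id)

    kappa = cohen_kappa([p[0] for p in pairs], [p[1] for p in pairs])
    return AgreementReport(
        icu_id=a1.icu_id,
        visit_date=a1.visit_date.isoformat(),
        collectors=(a1.collector_id, a2.collector_id),
        n_compared=n_compared,
        n_discordant=len(discordant),
        percent_agreement=_pct(n_compared - len(discordant), n_compared),
        discordant_codes=tuple(discordant),
        excluded_codes=tuple(excluded),
        n_compared_scored=n_compared_scored,
        n_discordant_scored=n_discordant_scored,
        percent_agreement_scored=_pct(
            n_compared_scored - n_discordant_scored, n_compared_scored
        ),
        n_items_compared=n_items,
        n_items_discordant=len(item_discordant),
        percent_agreement_items=_pct(n_items - len(item_discordant), n_items),
        discordant_items=tuple(item_discordant),
        kappa=kappa,
    )
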