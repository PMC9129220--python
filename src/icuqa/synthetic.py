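"""Seeded generation of assessment records with controlled structure.

No ICU's raw checklist responses are published, so every downstream module is
exercised on synthetic visits.  A :class:`SyntheticProfile` controls, per
indicator, the probability that the response passes its dichotomization rule,
the probability it is missing or not applicable, and (for duplicate-collector
pairs) the probability that the second collector's classification flips.

Numeric responses are drawn from documented intervals around each rule's
threshold so that the dichotomized verdict always reproduces the Bernoulli
draw that produced it:

===================  =========================  =========================
rule                 passing draw               failing draw
===================  =========================  =========================
ratio >= t           U[t, 1.0]                  U[0.4*t, t)
percentage >= t      U[t, 100]                  U[0, t)
duration <= t        integer U[t/3, t]          integer U[t+1, 4*t]
count > t            integer U[t+1, t+12]       integer U[0, t]
count >= t (t >= 1)  integer U[t, t+3]          integer U[0, t-1]
count == 0           0                          integer U[1, 5]
yes/no               the passing category       the failing category
===================  =========================  =========================

Descriptive (unscored) indicators draw from fixed plausible ranges; flips for
these perturb the raw value, since concordance compares them at raw level.
"""

from __future__ import annotations

import datetime
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import IO, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .assessment import Assessment, IndicatorResponse, ResponseStatus
from .registry import Comparator, PassRule, Registry, ResponseType

__all__ = [
    "SyntheticProfile",
    "load_profile",
    "shipped_archetypes",
    "generate_assessment",
    "generate_rater_pair",
]

_Prob = Field(ge=0.0, le=1.0)

DEFAULT_VISIT_DATE = datetime.date(2021, 3, 1)

#: Compound text payloads for the two-part interview indicators.
_TEXT_CHOICES = (
    "no",
    "yes: CT pulmonary angiography",
    "yes: ultrasound",
    "yes: chest X-ray",
)


class SyntheticProfile(BaseModel):
    """Per-indicator response-generating probabilities for one archetype."""

    model_config = ConfigDict(frozen=True)

    name: str
    default_pass_prob: float = _Prob
    pass_prob: dict[str, float] = Field(default_factory=dict)
    default_missing_prob: float = 0.0
    missing_prob: dict[str, float] = Field(default_factory=dict)
    default_na_prob: float = 0.0
    na_prob: dict[str, float] = Field(default_factory=dict)
    rater_flip_prob: float = 0.0

    def pass_prob_for(self, code: str) -> float:
        return self.pass_prob.get(code, self.default_pass_prob)

    def missing_prob_for(self, code: str) -> float:
        return self.missing_prob.get(code, self.default_missing_prob)

    def na_prob_for(self, code: str) -> float:
        return self.na_prob.get(code, self.default_na_prob)


def load_profile(source: Union[str, Path, IO[str]]) -> SyntheticProfile:
    """Load a profile from a YAML file path or stream."""
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    return SyntheticProfile.model_validate(yaml.safe_load(text))


@lru_cache(maxsize=1)
def shipped_archetypes() -> dict[str, SyntheticProfile]:
    """The two shipped archetypes: ``low_resource`` and ``high_resource``.

    Calibrated so the low-resource mean total sits near half of the maximum
    and the high-resource mean near 85-90% of it, mirroring the spread the
    instrument is meant to resolve between under-resourced public units and
    protocolized university units.
    """
    out = {}
    root = resources.files("icuqa.data").joinpath("profiles")
    for name in ("low_resource", "high_resource"):
        with root.joinpath(f"{name}.yaml").open("r", encoding="utf-8") as fh:
            out[name] = load_profile(fh)
    return out


def _draw_scored_value(
    rule: PassRule, rtype: ResponseType, passing: bool, rng: np.random.Generator
):
    comp, t = rule.comparator, rule.threshold
    if comp is Comparator.is_yes:
        return bool(passing)
    if comp is Comparator.is_no:
        return not passing
    if comp is Comparator.count_eq_zero:
        return 0 if passing else int(rng.integers(1, 6))
    if comp is Comparator.gt:  # counts of charted values
        return (
            int(rng.integers(int(t) + 1, int(t) + 13))
            if passing
            else int(rng.integers(0, int(t) + 1))
        )
    if comp is Comparator.ge:
        if rtype is ResponseType.count:
            return (
                int(rng.integers(int(t), int(t) + 4))
                if passing
                else int(rng.integers(0, int(t)))
            )
        if rtype is ResponseType.percentage:
            return float(rng.uniform(t, 100.0)) if passing else float(rng.uniform(0.0, t))
        # ratio
        return (
            float(rng.uniform(t, 1.0)) if passing else float(rng.uniform(0.4 * t, t))
        )
    if comp is Comparator.le:  # turnaround durations
        return (
            int(rng.integers(max(1, int(t) // 3), int(t) + 1))
            if passing
            else int(rng.integers(int(t) + 1, 4 * int(t) + 1))
        )
    raise AssertionError(f"unhandled comparator {comp}")


def _draw_descriptive_value(rtype: ResponseType, rng: np.random.Generator):
    if rtype is ResponseType.boolean:
        return bool(rng.random() < 0.5)
    if rtype is ResponseType.count:
        return int(rng.integers(0, 11))
    if rtype is ResponseType.duration_minutes:
        return int(rng.integers(0, 121))
    if rtype is ResponseType.ratio:
        return float(rng.uniform(0.2, 1.0))
    if rtype is ResponseType.percentage:
        return float(rng.uniform(0.0, 100.0))
    return _TEXT_CHOICES[int(rng.integers(0, len(_TEXT_CHOICES)))]


def _perturb_descriptive_value(value, rtype: ResponseType, rng: np.random.Generator):
    """A guaranteed-different raw value, standing in for collector disagreement."""
    if rtype is ResponseType.boolean:
        return not value
    if rtype in (ResponseType.count, ResponseType.duration_minutes):
        return int(value) + 1
    if rtype is ResponseType.ratio:
        return float(value) + 0.1
    if rtype is ResponseType.percentage:
        return float(value) - 1.0 if value >= 1.0 else float(value) + 1.0
    choices = [c for c in _TEXT_CHOICES if c != value]
    return choices[int(rng.integers(0, len(choices)))]


def generate_assessment(
    profile: SyntheticProfile,
    reg: Registry,
    seed: int,
    icu_id: Optional[str] = None,
    visit_date: datetime.date = DEFAULT_VISIT_DATE,
    collector_id: str = "sim-1",
) -> Assessment:
    """One seeded synthetic visit; deterministic given (profile, seed)."""
    rng = np.random.default_rng(seed)
    responses = _generate_responses(profile, reg, rng)
    return Assessment(
        icu_id=icu_id or f"icu-{profile.name}",
        visit_date=visit_date,
        collector_id=collector_id,
        responses=responses,
    )


def _generate_responses(
    profile: SyntheticProfile, reg: Registry, rng: np.random.Generator
) -> dict[str, IndicatorResponse]:
    responses: dict[str, IndicatorResponse] = {}
    for ind in reg.indicators:
        u = rng.random()
        m, na = profile.missing_prob_for(ind.code), profile.na_prob_for(ind.code)
        if u < m:
            responses[ind.code] = IndicatorResponse(
                indicator_code=ind.code, status=ResponseStatus.missing
            )
            continue
        if u < m + na:
            responses[ind.code] = IndicatorResponse(
                indicator_code=ind.code, status=ResponseStatus.not_applicable
            )
            continue
        rule = reg.rule_for(ind.code)
        if rule is not None:
            passing = rng.random() < profile.pass_prob_for(ind.code)
            value = _draw_scored_value(rule, ind.response_type, passing, rng)
        else:
            value = _draw_descriptive_value(ind.response_type, rng)
        responses[ind.code] = IndicatorResponse(
            indicator_code=ind.code, status=ResponseStatus.answered, value=value
        )
    return responses


def generate_rater_pair(
    profile: SyntheticProfile,
    reg: Registry,
    seed: int,
    icu_id: Optional[str] = None,
    visit_date: datetime.date = DEFAULT_VISIT_DATE,
) -> tuple[Assessment, Assessment]:
    """Two independent collections of the same visit.

    The second collector re-records each answered indicator; with probability
    ``rater_flip_prob`` its classification flips (scored indicators move to
    the other side of their threshold, descriptive indicators get a different
    raw value).  Non-flipped responses are copied verbatim — disagreement
    within the same verdict class is invisible to classification-level
    concordance, so it is not modelled.
    """
    rng = np.random.default_rng(seed)
    responses1 = _generate_responses(profile, reg, rng)

    responses2: dict[str, IndicatorResponse] = {}
    for ind in reg.indicators:
        r1 = responses1[ind.code]
        if r1.status is not ResponseStatus.answered:
            responses2[ind.code] = r1
            continue
        if rng.random() >= profile.rater_flip_prob:
            responses2[ind.code] = r1
            continue
        rule = reg.rule_for(ind.code)
        if rule is not None:
            from .scoring import Verdict, evaluate_rule  # local to avoid cycle

            was_passing = evaluate_rule(rule, r1) is Verdict.passed
            value = _draw_scored_value(rule, ind.response_type, not was_passing, rng)
        else:
            value = _perturb_descriptive_value(r1.value, ind.response_type, rng)
        responses2[ind.code] = IndicatorResponse(
            indicator_code=ind.code, status=ResponseStatus.answered, value=value
        )

    ident = dict(
        icu_id=icu_id or f"icu-{profile.name}", visit_date=visit_date
    )
    a1 = Assessment(collector_id="sim-1", responses=responses1, **ident)
    a2 = Assessment(collector_id="sim-2", responses=responses2, **ident)
    return a1, a2
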