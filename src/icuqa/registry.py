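"""Instrument definition: the checklist indicators and the scoring protocol.

The instrument is data, not code: it ships as a versioned YAML file (see
``icuqa/data/registry_v1.yaml``) describing 44 checklist indicators collected
by three methods during a one-hour ICU visit, and the 26 one-point score items
built from the 33 indicators that can be dichotomized against a minimum
standard.  This module loads, saves, and integrity-checks that file.
"""

from __future__ import annotations

import enum
import io
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "Domain",
    "Method",
    "ResponseType",
    "Comparator",
    "IndicatorDefinition",
    "PassRule",
    "ScoreItem",
    "Registry",
    "RegistryError",
    "RegistryIntegrityError",
    "load_registry",
    "save_registry",
    "validate_registry",
    "max_score",
    "default_registry",
    "data_dictionary",
]


class RegistryError(ValueError):
    """Malformed registry file (parse/schema failure)."""


class RegistryIntegrityError(RegistryError):
    """Structurally valid file whose cross-references are inconsistent."""


class Domain(str, enum.Enum):
    """Quality-of-care domains (structure and process only)."""

    staffing = "staffing"
    infrastructure = "infrastructure"
    equipment_drugs = "equipment_drugs"
    clinical_management = "clinical_management"
    protocols = "protocols"
    training_development = "training_development"


class Method(str, enum.Enum):
    """How an indicator is collected during the visit."""

    observation = "observation"
    chart_review = "chart_review"
    interview = "interview"


#: Indicator codes are prefixed by their collection-method section letter.
METHOD_PREFIX: dict[str, Method] = {
    "A": Method.observation,
    "B": Method.chart_review,
    "C": Method.interview,
}


class ResponseType(str, enum.Enum):
    boolean = "boolean"
    count = "count"
    ratio = "ratio"
    duration_minutes = "duration_minutes"
    percentage = "percentage"
    text = "text"


NUMERIC_TYPES = {
    ResponseType.count,
    ResponseType.ratio,
    ResponseType.duration_minutes,
    ResponseType.percentage,
}


class Comparator(str, enum.Enum):
    is_yes = "is_yes"
    is_no = "is_no"
    ge = "ge"
    le = "le"
    gt = "gt"
    count_eq_zero = "count_eq_zero"


THRESHOLD_COMPARATORS = {Comparator.ge, Comparator.le, Comparator.gt}


class IndicatorDefinition(BaseModel):
    """One checklist indicator (a row of the instrument's indicator table)."""

    model_config = ConfigDict(frozen=True)

    code: str
    label: str
    domain: Domain
    method: Method
    response_type: ResponseType
    scored: bool

    @field_validator("code")
    @classmethod
    def _code_shape(cls, v: str) -> str:
        if len(v) < 2 or v[0] not in METHOD_PREFIX or not v[1:].isdigit():
            raise ValueError(f"indicator code {v!r} must look like A01/B07/C14")
        return v


class PassRule(BaseModel):
    """Dichotomization rule: maps one indicator's response to pass/fail."""

    model_config = ConfigDict(frozen=True)

    indicator_code: str
    comparator: Comparator
    threshold: Optional[float] = None

    @field_validator("threshold")
    @classmethod
    def _finite(cls, v):
        if v is not None and not (v == v and abs(v) != float("inf")):
            raise ValueError("threshold must be finite")
        return v


class ScoreItem(BaseModel):
    """One point-bearing unit: a singleton rule or an all-must-pass group."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    domain: Domain
    rules: tuple[PassRule, ...] = Field(min_length=1)
    points: int = 1

    @property
    def is_group(self) -> bool:
        return len(self.rules) > 1

    @property
    def member_codes(self) -> tuple[str, ...]:
        return tuple(r.indicator_code for r in self.rules)


class Registry(BaseModel):
    """The full instrument: indicators, score items, version, provenance."""

    model_config = ConfigDict(frozen=True)

    version: str
    provenance: dict = Field(default_factory=dict)
    indicators: tuple[IndicatorDefinition, ...]
    items: tuple[ScoreItem, ...]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(i.code for i in self.indicators)

    def indicator(self, code: str) -> IndicatorDefinition:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown indicator code {code!r}") from None

    @property
    def _by_code(self) -> dict[str, IndicatorDefinition]:
        # frozen model: cache on the instance's __dict__ via object.__setattr__
        cached = self.__dict__.get("_code_index")
        if cached is None:
            cached = {i.code: i for i in self.indicators}
            object.__setattr__(self, "_code_index", cached)
        return cached

    def rule_for(self, code: str) -> Optional[PassRule]:
        """The dichotomization rule of a scored indicator (None if unscored)."""
        cached = self.__dict__.get("_rule_index")
        if cached is None:
            cached = {
                r.indicator_code: r for item in self.items for r in item.rules
            }
            object.__setattr__(self, "_rule_index", cached)
        return cached.get(code)

    def item_for(self, code: str) -> Optional[ScoreItem]:
        cached = self.__dict__.get("_item_index")
        if cached is None:
            cached = {
                c: item for item in self.items for c in item.member_codes
            }
            object.__setattr__(self, "_item_index", cached)
        return cached.get(code)


# Printed counts the shipped instrument must reproduce.
EXPECTED_COUNTS = {
    "indicators": 44,
    "scored": 33,
    "items": 26,
    "groups": 4,
    "grouped_indicators": 11,
}
EXPECTED_DOMAIN_MAXIMA = {
    Domain.staffing: 3,
    Domain.infrastructure: 5,
    Domain.equipment_drugs: 2,
    Domain.clinical_management: 12,
    Domain.training_development: 2,
    Domain.protocols: 2,
}

Source = Union[str, Path, IO[str]]


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text(encoding="utf-8")


def load_registry(source: Source) -> Registry:
    """Load a registry from a YAML file path or text stream.

    Raises
    ------
    RegistryError
        If the document does not parse or a field fails schema validation.
    RegistryIntegrityError
        If a score item references an indicator code that does not exist.
    """
    text = _read_text(source)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RegistryError(f"registry is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise RegistryError("registry document must be a mapping")
    try:
        reg = Registry.model_validate(doc)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise RegistryError(f"registry schema error: {exc}") from exc

    known = set(reg.codes)
    dangling = [
        r.indicator_code
        for item in reg.items
        for r in item.rules
        if r.indicator_code not in known
    ]
    if dangling:
        raise RegistryIntegrityError(
            f"score items reference unknown indicator codes: {sorted(set(dangling))}"
        )
    return reg


def save_registry(reg: Registry, target: Union[str, Path, IO[str]]) -> None:
    """Write a registry back to YAML losslessly (``load(save(reg)) == reg``)."""
    doc = reg.model_dump(mode="json")
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text, encoding="utf-8")


def dumps_registry(reg: Registry) -> str:
    buf = io.StringIO()
    save_registry(reg, buf)
    return buf.getvalue()


def validate_registry(
    reg: Registry, expected: Optional[dict] = EXPECTED_COUNTS
) -> list[str]:
    """Integrity-check a registry; returns findings (empty iff valid).

    Structural invariants (unique codes, method-letter prefixes, comparator /
    response-type compatibility, one score item per scored indicator) are
    always checked.  Shipped-instrument count invariants (44 indicators, 33
    scored, 26 items, 4 groups of 11 indicators, domain point maxima) are
    checked against ``expected``; pass ``expected=None`` for ad-hoc registries.
    """
    findings: list[str] = []

    codes = [i.code for i in reg.indicators]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        findings.append(f"duplicate indicator codes: {sorted(dupes)}")
    for ind in reg.indicators:
        want = METHOD_PREFIX[ind.code[0]]
        if ind.method is not want:
            findings.append(
                f"{ind.code}: method {ind.method.value} inconsistent with "
                f"section letter (expected {want.value})"
            )

    by_code = {i.code: i for i in reg.indicators}
    seen_in: dict[str, str] = {}
    for item in reg.items:
        if item.points != 1:
            findings.append(f"{item.item_id}: points {item.points} != 1")
        for rule in item.rules:
            ind = by_code.get(rule.indicator_code)
            if ind is None:
                findings.append(
                    f"{item.item_id}: dangling indicator reference "
                    f"{rule.indicator_code}"
                )
                continue
            if rule.indicator_code in seen_in:
                findings.append(
                    f"{rule.indicator_code}: appears in both "
                    f"{seen_in[rule.indicator_code]} and {item.item_id}"
                )
            seen_in[rule.indicator_code] = item.item_id
            if not ind.scored:
                findings.append(
                    f"{item.item_id}: member {ind.code} is not a scored indicator"
                )
            if rule.comparator in THRESHOLD_COMPARATORS:
                if rule.threshold is None:
                    findings.append(
                        f"{item.item_id}/{ind.code}: comparator "
                        f"{rule.comparator.value} requires a threshold"
                    )
                if ind.response_type not in NUMERIC_TYPES:
                    findings.append(
                        f"{item.item_id}/{ind.code}: numeric comparator on "
                        f"{ind.response_type.value} response"
                    )
            elif rule.threshold is not None:
                findings.append(
                    f"{item.item_id}/{ind.code}: comparator "
                    f"{rule.comparator.value} takes no threshold"
                )
            if rule.comparator in (Comparator.is_yes, Comparator.is_no):
                if ind.response_type is not ResponseType.boolean:
                    findings.append(
                        f"{item.item_id}/{ind.code}: yes/no comparator on "
                        f"{ind.response_type.value} response"
                    )
            if (
                rule.comparator is Comparator.count_eq_zero
                and ind.response_type is not ResponseType.count
            ):
                findings.append(
                    f"{item.item_id}/{ind.code}: count_eq_zero on "
                    f"{ind.response_type.value} response"
                )

    for ind in reg.indicators:
        if ind.scored and ind.code not in seen_in:
            findings.append(f"{ind.code}: scored indicator missing from all items")

    if expected is not None:
        n_ind = len(reg.indicators)
        if n_ind != expected["indicators"]:
            findings.append(f"indicator count {n_ind} != {expected['indicators']}")
        n_scored = sum(i.scored for i in reg.indicators)
        if n_scored != expected["scored"]:
            findings.append(f"scored indicator count {n_scored} != {expected['scored']}")
        n_items = len(reg.items)
        if n_items != expected["items"]:
            findings.append(f"score item count {n_items} != {expected['items']}")
        groups = [it for it in reg.items if it.is_group]
        if len(groups) != expected["groups"]:
            findings.append(f"grouped item count {len(groups)} != {expected['groups']}")
        n_grouped = sum(len(it.rules) for it in groups)
        if n_grouped != expected["grouped_indicators"]:
            findings.append(
                f"grouped indicator count {n_grouped} != "
                f"{expected['grouped_indicators']}"
            )
        for dom, mx in EXPECTED_DOMAIN_MAXIMA.items():
            have = sum(it.points for it in reg.items if it.domain is dom)
            if have != mx:
                findings.append(
                    f"domain {dom.value}: max points {have} != {mx}"
                )
    return findings


def max_score(reg: Registry) -> int:
    """Maximum attainable total: one point per score item (26 as shipped)."""
    return sum(item.points for item in reg.items)


def data_dictionary(reg: Registry) -> pd.DataFrame:
    """One-row-per-indicator data dictionary (CSV-exportable).

    Columns: code, label, domain, method, response_type, scored, item_id,
    comparator, threshold.  Unscored indicators have empty scoring columns.
    """
    rows = []
    for ind in reg.indicators:
        rule = reg.rule_for(ind.code)
        item = reg.item_for(ind.code)
        rows.append(
            {
                "code": ind.code,
                "label": ind.label,
                "domain": ind.domain.value,
                "method": ind.method.value,
                "response_type": ind.response_type.value,
                "scored": ind.scored,
                "item_id": item.item_id if item else "",
                "comparator": rule.comparator.value if rule else "",
                "threshold": rule.threshold if rule and rule.threshold is not None else "",
            }
        )
    return pd.DataFrame(rows)


DEFAULT_REGISTRY_RESOURCE = "registry_v1.yaml"


@lru_cache(maxsize=1)
def default_registry() -> Registry:
    """The shipped instrument (44 indicators, 26 score items)."""
    ref = resources.files("icuqa.data").joinpath(DEFAULT_REGISTRY_RESOURCE)
    with ref.open("r", encoding="utf-8") as fh:
        return load_registry(fh)
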