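"""One ICU visit's collected responses: representation, I/O, validation.

Two documented interchange formats:

* CSV "long" format, one row per indicator::

      icu_id,visit_date,collector_id,indicator_code,value,status

  ``status`` may be left blank (inferred: ``answered`` if a value is present,
  else ``missing``); the literal value token ``NA`` marks ``not_applicable``.
  Indicator codes absent from the file are recorded as ``missing`` — the
  scoring protocol penalizes missing data, so absence must be representable.

* JSON, mirroring :class:`Assessment` field-for-field.

Boolean responses accept yes/no/true/false/y/n/1/0 (case-insensitive) on
input and are normalized to yes/no on write.  Ratios are decimals (0.5 = one
nurse per two patients), durations are integer minutes, dates ISO 8601.
"""

from __future__ import annotations

import csv
import datetime
import enum
import io
import json
from pathlib import Path
from typing import IO, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .registry import Domain, Method, Registry, ResponseType

__all__ = [
    "ResponseStatus",
    "IndicatorResponse",
    "Assessment",
    "AssessmentError",
    "CompletenessSummary",
    "read_assessment",
    "write_assessment",
    "completeness",
    "parse_value",
    "format_value",
]

Value = Union[bool, int, float, str]

CSV_HEADER = ["icu_id", "visit_date", "collector_id", "indicator_code", "value", "status"]

NA_TOKEN = "NA"

_TRUE_TOKENS = {"yes", "true", "y", "1"}
_FALSE_TOKENS = {"no", "false", "n", "0"}


class AssessmentError(ValueError):
    """Invalid assessment data (bad value, duplicate code, bad date...)."""


class ResponseStatus(str, enum.Enum):
    answered = "answered"
    missing = "missing"
    not_applicable = "not_applicable"


def parse_value(raw: str, rtype: ResponseType) -> Value:
    """Parse a raw text token into the typed payload for ``rtype``.

    Raises :class:`AssessmentError` on type or range violations.
    """
    raw = raw.strip()
    if rtype is ResponseType.boolean:
        low = raw.lower()
        if low in _TRUE_TOKENS:
            return True
        if low in _FALSE_TOKENS:
            return False
        raise AssessmentError(f"expected yes/no, got {raw!r}")
    if rtype is ResponseType.count:
        try:
            n = int(raw)
        except ValueError:
            raise AssessmentError(f"expected a non-negative integer count, got {raw!r}")
        if n < 0:
            raise AssessmentError(f"count cannot be negative: {n}")
        return n
    if rtype is ResponseType.duration_minutes:
        try:
            n = int(float(raw)) if float(raw).is_integer() else None
        except ValueError:
            n = None
        if n is None or n < 0:
            raise AssessmentError(
                f"expected a non-negative whole number of minutes, got {raw!r}"
            )
        return n
    if rtype is ResponseType.ratio:
        try:
            x = float(raw)
        except ValueError:
            raise AssessmentError(f"expected a decimal ratio, got {raw!r}")
        if x < 0:
            raise AssessmentError(f"ratio cannot be negative: {x}")
        return x
    if rtype is ResponseType.percentage:
        try:
            x = float(raw.rstrip("%"))
        except ValueError:
            raise AssessmentError(f"expected a percentage, got {raw!r}")
        if not 0 <= x <= 100:
            raise AssessmentError(f"percentage out of [0, 100]: {x}")
        return x
    return raw  # text (compound payloads like "yes: CT angiography")


def format_value(value: Value, rtype: ResponseType) -> str:
    if rtype is ResponseType.boolean:
        return "yes" if value else "no"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def check_value_type(value: Value, rtype: ResponseType) -> None:
    ok = {
        ResponseType.boolean: lambda v: isinstance(v, bool),
        ResponseType.count: lambda v: isinstance(v, int) and not isinstance(v, bool) and v >= 0,
        ResponseType.duration_minutes: lambda v: isinstance(v, int) and not isinstance(v, bool) and v >= 0,
        ResponseType.ratio: lambda v: isinstance(v, (int, float)) and not isinstance(v, bool) and v >= 0,
        ResponseType.percentage: lambda v: isinstance(v, (int, float)) and not isinstance(v, bool) and 0 <= v <= 100,
        ResponseType.text: lambda v: isinstance(v, str),
    }[rtype]
    if not ok(value):
        raise AssessmentError(
            f"value {value!r} incompatible with response type {rtype.value}"
        )


class IndicatorResponse(BaseModel):
    """One indicator's recorded response (or its absence)."""

    model_config = ConfigDict(frozen=True)

    indicator_code: str
    status: ResponseStatus = ResponseStatus.answered
    value: Optional[Value] = None

    @model_validator(mode="after")
    def _value_matches_status(self) -> "IndicatorResponse":
        if self.status is ResponseStatus.answered and self.value is None:
            raise ValueError(
                f"{self.indicator_code}: answered response requires a value"
            )
        if self.status is not ResponseStatus.answered and self.value is not None:
            raise ValueError(
                f"{self.indicator_code}: {self.status.value} response carries no value"
            )
        return self


class Assessment(BaseModel):
    """One ICU visit's responses keyed by indicator code, plus identity."""

    model_config = ConfigDict(frozen=True)

    icu_id: str
    visit_date: datetime.date
    collector_id: str = ""
    responses: dict[str, IndicatorResponse] = Field(default_factory=dict)
    notes: str = ""

    @model_validator(mode="after")
    def _keys_match(self) -> "Assessment":
        for code, resp in self.responses.items():
            if resp.indicator_code != code:
                raise ValueError(
                    f"response keyed {code!r} carries code {resp.indicator_code!r}"
                )
        return self

    def response(self, code: str) -> IndicatorResponse:
        """The response for ``code``; absent entries read as missing."""
        return self.responses.get(
            code, IndicatorResponse(indicator_code=code, status=ResponseStatus.missing)
        )

    def is_complete(self, reg: Registry) -> bool:
        return all(
            self.response(c).status is ResponseStatus.answered for c in reg.codes
        )


def validate_against_registry(a: Assessment, reg: Registry) -> None:
    """Reject unknown codes and type-incompatible values."""
    known = set(reg.codes)
    for code, resp in a.responses.items():
        if code not in known:
            raise AssessmentError(f"unknown indicator code {code!r}")
        if resp.status is ResponseStatus.answered:
            check_value_type(resp.value, reg.indicator(code).response_type)


Source = Union[str, Path, IO[str]]


def _read_text(source: Source) -> tuple[str, str]:
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "<stream>")
    p = Path(source)
    return p.read_text(encoding="utf-8"), str(p)


def _parse_date(raw: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(raw.strip())
    except ValueError:
        raise AssessmentError(f"unparseable visit date {raw!r} (expected ISO 8601)")


def read_assessment(source: Source, reg: Registry) -> Assessment:
    """Read an assessment from CSV-long or JSON (auto-detected).

    All registry codes absent from the file come back with status
    ``missing``, so a returned assessment always covers the full checklist.
    """
    text, name = _read_text(source)
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _read_json(text, reg)
    return _read_csv(text, reg, name)


def _read_json(text: str, reg: Registry) -> Assessment:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise AssessmentError(f"invalid JSON assessment: {exc}") from exc
    try:
        a = Assessment.model_validate(doc)
    except Exception as exc:
        raise AssessmentError(f"assessment schema error: {exc}") from exc
    validate_against_registry(a, reg)
    return _fill_missing(a, reg)


def _read_csv(text: str, reg: Registry, name: str) -> Assessment:
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != CSV_HEADER:
        raise AssessmentError(
            f"{name}: expected header {','.join(CSV_HEADER)}, "
            f"got {reader.fieldnames}"
        )
    known = set(reg.codes)
    responses: dict[str, IndicatorResponse] = {}
    icu_id = visit_date = collector_id = None
    for lineno, row in enumerate(reader, start=2):
        code = (row.get("indicator_code") or "").strip()
        if code not in known:
            raise AssessmentError(f"{name}:{lineno}: unknown indicator code {code!r}")
        if code in responses:
            raise AssessmentError(f"{name}:{lineno}: duplicate indicator code {code}")
        if icu_id is None:
            icu_id = (row.get("icu_id") or "").strip()
            visit_date = _parse_date(row.get("visit_date") or "")
            collector_id = (row.get("collector_id") or "").strip()
        raw_value = (row.get("value") or "").strip()
        raw_status = (row.get("status") or "").strip().lower()
        rtype = reg.indicator(code).response_type
        try:
            responses[code] = _row_to_response(code, raw_value, raw_status, rtype)
        except AssessmentError as exc:
            raise AssessmentError(f"{name}:{lineno}: {code}: {exc}") from None
    if icu_id is None:
        raise AssessmentError(f"{name}: no data rows")
    a = Assessment(
        icu_id=icu_id,
        visit_date=visit_date,
        collector_id=collector_id,
        responses=responses,
    )
    return _fill_missing(a, reg)


def _row_to_response(
    code: str, raw_value: str, raw_status: str, rtype: ResponseType
) -> IndicatorResponse:
    if raw_status in ("missing",):
        if raw_value:
            raise AssessmentError("missing response must not carry a value")
        return IndicatorResponse(indicator_code=code, status=ResponseStatus.missing)
    if raw_status in ("not_applicable", "na") or (
        not raw_status and raw_value == NA_TOKEN
    ):
        return IndicatorResponse(
            indicator_code=code, status=ResponseStatus.not_applicable
        )
    if raw_status in ("answered", ""):
        if not raw_value:
            return IndicatorResponse(indicator_code=code, status=ResponseStatus.missing)
        return IndicatorResponse(
            indicator_code=code,
            status=ResponseStatus.answered,
            value=parse_value(raw_value, rtype),
        )
    raise AssessmentError(f"unknown status token {raw_status!r}")


def _fill_missing(a: Assessment, reg: Registry) -> Assessment:
    responses = dict(a.responses)
    for code in reg.codes:
        responses.setdefault(
            code, IndicatorResponse(indicator_code=code, status=ResponseStatus.missing)
        )
    # keep registry order for deterministic serialization
    ordered = {c: responses[c] for c in reg.codes}
    ordered.update({c: r for c, r in responses.items() if c not in ordered})
    return a.model_copy(update={"responses": ordered})


def write_assessment(
    a: Assessment,
    target: Union[str, Path, IO[str]],
    reg: Registry,
    fmt: str = "csv",
) -> None:
    """Write an assessment as CSV-long (default) or JSON."""
    if fmt == "json":
        text = a.model_dump_json(indent=2)
    elif fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for code, resp in a.responses.items():
            if resp.status is ResponseStatus.answered:
                rtype = reg.indicator(code).response_type
                value, status = format_value(resp.value, rtype), "answered"
            elif resp.status is ResponseStatus.not_applicable:
                value, status = "", "not_applicable"
            else:
                value, status = "", "missing"
            writer.writerow(
                [a.icu_id, a.visit_date.isoformat(), a.collector_id, code, value, status]
            )
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown format {fmt!r} (csv or json)")
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text, encoding="utf-8")


class CompletenessSummary(BaseModel):
    """Counts of answered / missing / not-applicable responses."""

    answered: int
    missing: int
    not_applicable: int
    by_method: dict[str, dict[str, int]]
    by_domain: dict[str, dict[str, int]]

    @property
    def total(self) -> int:
        return self.answered + self.missing + self.not_applicable


def completeness(a: Assessment, reg: Registry) -> CompletenessSummary:
    """Tally response statuses over the full checklist (counts sum to 44)."""
    overall = {s: 0 for s in ResponseStatus}
    by_method: dict[str, dict[str, int]] = {
        m.value: {s.value: 0 for s in ResponseStatus} for m in Method
    }
    by_domain: dict[str, dict[str, int]] = {
        d.value: {s.value: 0 for s in ResponseStatus} for d in Domain
    }
    for ind in reg.indicators:
        status = a.response(ind.code).status
        overall[status] += 1
        by_method[ind.method.value][status.value] += 1
        by_domain[ind.domain.value][status.value] += 1
    return CompletenessSummary(
        answered=overall[ResponseStatus.answered],
        missing=overall[ResponseStatus.missing],
        not_applicable=overall[ResponseStatus.not_applicable],
        by_method=by_method,
        by_domain=by_domain,
    )
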