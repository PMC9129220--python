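"""Shared fixtures: the shipped registry and hand-built assessments.

PASS_VALUES / FAIL_VALUES are written out by hand from the published
thresholds (not derived from the registry file) so fixtures stay independent
of the code they exercise.
"""

from __future__ import annotations

import datetime

import numpy as np
import pytest

from icuqa import Assessment, IndicatorResponse, ResponseStatus, default_registry

#: An answered value per indicator that passes its rule (descriptive
#: indicators get any plausible value).
PASS_VALUES = {
    "A01": 0.6, "A02": True, "A03": 3, "A04": 1, "A05": 2, "A06": 0,
    "A07": 2, "A08": 4, "A09": True, "A10": True, "A11": True, "A12": True,
    "A13": True, "A14": True, "A15": False, "A16": False, "A17": 90.0,
    "A18": 1, "A19": 0,
    "B01": 24, "B02": 12, "B03": 12, "B04": 24, "B05": True, "B06": True,
    "B07": True, "B08": True, "B09": True, "B10": True, "B11": True,
    "B12": True,
    "C01": True, "C02": 5, "C03": 240, "C04": 0.5, "C05": 0.5, "C06": True,
    "C07": True, "C08": 10, "C09": True, "C10": "no",
    "C11": "yes: CT pulmonary angiography", "C13": True, "C14": True,
}

#: A failing answered value for every scored indicator.
FAIL_VALUES = {
    "A01": 0.4, "A09": False, "A10": False, "A11": False, "A12": False,
    "A13": False, "A14": False, "A15": True, "A16": True, "A17": 50.0,
    "A18": 0, "A19": 2,
    "B01": 10, "B02": 3, "B03": 6, "B04": 12, "B05": False, "B06": False,
    "B07": False, "B08": False, "B09": False, "B10": False, "B11": False,
    "B12": False,
    "C01": False, "C04": 0.3, "C05": 0.2, "C06": False, "C07": False,
    "C08": 30, "C09": False, "C13": False, "C14": False,
}

SCORED_CODES = sorted(FAIL_VALUES)
MISSING = "MISSING"
NA = "NA"


def make_assessment(overrides=None, icu_id="icu-test",
                    visit_date=datetime.date(2021, 3, 1), collector_id="c1"):
    """All-pass assessment with per-code overrides (value, MISSING, or NA)."""
    overrides = overrides or {}
    responses = {}
    for code, default in PASS_VALUES.items():
        v = overrides.get(code, default)
        if v == MISSING:
            responses[code] = IndicatorResponse(
                indicator_code=code, status=ResponseStatus.missing
            )
        elif v == NA:
            responses[code] = IndicatorResponse(
                indicator_code=code, status=ResponseStatus.not_applicable
            )
        else:
            responses[code] = IndicatorResponse(
                indicator_code=code, status=ResponseStatus.answered, value=v
            )
    return Assessment(
        icu_id=icu_id,
        visit_date=visit_date,
        collector_id=collector_id,
        responses=responses,
    )


def random_state_assessment(rng: np.random.Generator, p_missing=0.1, p_na=0.1):
    """Random mix of pass/fail/missing/NA per indicator (scored codes can
    fail; descriptive codes stay at their plausible value)."""
    overrides = {}
    for code in PASS_VALUES:
        u = rng.random()
        if u < p_missing:
            overrides[code] = MISSING
        elif u < p_missing + p_na:
            overrides[code] = NA
        elif code in FAIL_VALUES and rng.random() < 0.5:
            overrides[code] = FAIL_VALUES[code]
    return make_assessment(overrides)


def random_raw_assessment(reg, rng: np.random.Generator,
                          p_missing=0.08, p_na=0.07):
    """Raw random values over each indicator's full plausible range, landing
    on either side of every threshold (for oracle-equivalence checks)."""
    from icuqa.registry import ResponseType

    responses = {}
    for ind in reg.indicators:
        u = rng.random()
        if u < p_missing:
            responses[ind.code] = IndicatorResponse(
                indicator_code=ind.code, status=ResponseStatus.missing
            )
            continue
        if u < p_missing + p_na:
            responses[ind.code] = IndicatorResponse(
                indicator_code=ind.code, status=ResponseStatus.not_applicable
            )
            continue
        t = ind.response_type
        if t is ResponseType.boolean:
            v = bool(rng.random() < 0.5)
        elif t is ResponseType.count:
            v = int(rng.integers(0, 30))
        elif t is ResponseType.duration_minutes:
            v = int(rng.integers(0, 60))
        elif t is ResponseType.ratio:
            v = float(rng.uniform(0.0, 1.2))
        elif t is ResponseType.percentage:
            v = float(rng.uniform(0.0, 100.0))
        else:
            v = "yes: ultrasound" if rng.random() < 0.5 else "no"
        responses[ind.code] = IndicatorResponse(
            indicator_code=ind.code, status=ResponseStatus.answered, value=v
        )
    return Assessment(
        icu_id="icu-rand",
        visit_date=datetime.date(2021, 3, 1),
        collector_id="c1",
        responses=responses,
    )


@pytest.fixture(scope="session")
def reg():
    return default_registry()


@pytest.fixture()
def all_pass():
    return make_assessment()


@pytest.fixture()
def all_fail():
    return make_assessment(dict(FAIL_VALUES))
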