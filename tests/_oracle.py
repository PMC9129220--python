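"""Independent brute-force oracle for the 26-item scoring protocol.

The item table below is hand-coded directly from the published scoring
protocol and deliberately shares nothing with the package's registry file or
scoring engine: it enumerates the 26 items literally and applies the
dichotomization thresholds, the all-must-pass group semantics, and the
missing-data deduction step by step.
"""

from __future__ import annotations

from icuqa.assessment import Assessment, ResponseStatus

# (domain, [(code, kind, threshold-or-None), ...]) — one tuple per point.
ORACLE_ITEMS = [
    ("staffing", [("C14", "yes", None)]),
    ("staffing", [("A01", "ge", 0.5), ("C04", "ge", 0.5), ("C05", "ge", 0.5)]),
    ("staffing", [("C01", "yes", None)]),
    ("infrastructure", [("A09", "yes", None)]),
    ("infrastructure", [("A10", "yes", None)]),
    ("infrastructure", [("C06", "yes", None)]),
    ("infrastructure", [("C07", "yes", None)]),
    ("infrastructure", [("C08", "le", 15)]),
    ("equipment_drugs", [("A11", "yes", None)]),
    ("equipment_drugs", [("A12", "yes", None)]),
    ("clinical_management", [("A17", "ge", 80)]),
    ("clinical_management", [("A18", "ge", 1)]),
    (
        "clinical_management",
        [("B01", "gt", 12), ("B02", "gt", 6), ("B03", "gt", 6), ("B04", "gt", 12)],
    ),
    ("clinical_management", [("B05", "yes", None)]),
    ("clinical_management", [("B07", "yes", None)]),
    ("clinical_management", [("B09", "yes", None), ("B10", "yes", None)]),
    ("clinical_management", [("B11", "yes", None), ("B12", "yes", None)]),
    ("clinical_management", [("B06", "yes", None)]),
    ("clinical_management", [("B08", "yes", None)]),
    ("clinical_management", [("A19", "eq0", None)]),
    ("clinical_management", [("A15", "no", None)]),
    ("clinical_management", [("A16", "no", None)]),
    ("training_development", [("C09", "yes", None)]),
    ("training_development", [("C13", "yes", None)]),
    ("protocols", [("A13", "yes", None)]),
    ("protocols", [("A14", "yes", None)]),
]


def _verdict(a: Assessment, code: str, kind: str, threshold):
    resp = a.response(code)
    if resp.status is ResponseStatus.missing:
        return "missing"
    if resp.status is ResponseStatus.not_applicable:
        return "na"
    v = resp.value
    if kind == "yes":
        return "pass" if v is True else "fail"
    if kind == "no":
        return "pass" if v is False else "fail"
    if kind == "eq0":
        return "pass" if v == 0 else "fail"
    if kind == "ge":
        return "pass" if v >= threshold else "fail"
    if kind == "le":
        return "pass" if v <= threshold else "fail"
    if kind == "gt":
        return "pass" if v > threshold else "fail"
    raise AssertionError(kind)


def oracle_score(a: Assessment, penalty: str = "per_item", na: str = "vacuous"):
    """Literal walk over the protocol table.

    Returns (total, per_item_points, per_item_penalty, max_points).
    """
    points, pens = [], []
    max_points = 0
    for _, members in ORACLE_ITEMS:
        verdicts = [_verdict(a, c, k, t) for c, k, t in members]
        n_missing = verdicts.count("missing")
        if n_missing:
            points.append(0)
            pens.append(1 if penalty == "per_item" else n_missing)
            max_points += 1
            continue
        if na == "exclude" and all(v == "na" for v in verdicts):
            points.append(0)
            pens.append(0)
            continue  # excluded from the denominator
        max_points += 1
        considered = [
            v for v in verdicts if not (na == "exclude" and v == "na")
        ]
        ok = all(v in ("pass", "na") for v in considered)
        points.append(1 if ok else 0)
        pens.append(0)
    total = max(0, sum(points) - sum(pens))
    return total, points, pens, max_points


def oracle_kappa(x, y) -> float:
    """Closed-form 2x2-table Cohen's kappa (counts a, b, c, d)."""
    n = len(x)
    a = sum(1 for i, j in zip(x, y) if i and j)
    b = sum(1 for i, j in zip(x, y) if i and not j)
    c = sum(1 for i, j in zip(x, y) if not i and j)
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)
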