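"""Core value types shared by every module.

These carry no computation beyond construction-time normalisation; all
guideline logic lives in the ruleset and engine modules.  Validation is
deliberately *reported* rather than raised (:func:`validate_case`) so that a
caller can collect every problem with a case record in one pass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

AGE_RANGE = (0, 120)

DECISION_KINDS = ("screening", "first_surveillance", "subsequent_surveillance", "cessation")
MODALITIES = ("stool_test", "colonoscopy", "none")
PRIOR_LESION_TYPES = ("adenoma", "serrated", "both", "none")


@dataclass(frozen=True)
class FamilyHistory:
    """Family history of colorectal cancer: counts of affected relatives by
    degree of relationship plus the youngest age at diagnosis per degree."""

    first_degree_count: int = 0
    first_degree_min_dx_age: Optional[int] = None
    second_degree_count: int = 0
    second_degree_min_dx_age: Optional[int] = None


@dataclass(frozen=True)
class LesionFindings:
    """Colonoscopy findings: counts of conventional adenomas and clinically
    significant serrated polyps (CSSPs) plus risk-feature flags.

    Feature codes are class-prefixed (e.g. ``adenoma_size_ge_10mm``,
    ``cssp_dysplasia``) and must belong to the vocabulary declared by the
    ruleset in use; the vocabulary is data, not an enum, so guideline
    revisions need no code change.
    """

    adenoma_count: int = 0
    cssp_count: int = 0
    feature_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "feature_flags", frozenset(self.feature_flags))


@dataclass(frozen=True)
class SurveillanceContext:
    """Inputs specific to a follow-up round: the interval that preceded the
    latest procedure and the lesion type previously identified."""

    prior_interval: int  # months
    prior_lesion_type: str  # one of PRIOR_LESION_TYPES


@dataclass(frozen=True)
class ComorbidityProfile:
    """Age plus comorbid conditions, for the modified Charlson score used by
    the surveillance-cessation rules."""

    age: int
    conditions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "conditions", frozenset(self.conditions))


@dataclass(frozen=True)
class PatientCase:
    """A complete case record as presented in a clinical vignette."""

    family_history: FamilyHistory
    index_findings: LesionFindings
    comorbidity: ComorbidityProfile
    followup_findings: Optional[LesionFindings] = None
    context: Optional[SurveillanceContext] = None


@dataclass(frozen=True)
class Recommendation:
    """One guideline recommendation with row-level provenance.

    Exactly the fields relevant to ``decision_kind`` are populated:
    screening -> modality + start_age; surveillance -> interval (months);
    cessation -> continue_surveillance.  ``provenance`` is the
    (table_id, row_id) pair of the matched decision-table row and is always
    present.
    """

    decision_kind: str
    provenance: tuple[str, str]
    modality: Optional[str] = None
    start_age: Optional[int] = None
    interval: Optional[int] = None
    continue_surveillance: Optional[bool] = None

    def to_dict(self) -> dict:
        d = {"decision_kind": self.decision_kind, "provenance": list(self.provenance)}
        for f in ("modality", "start_age", "interval", "continue_surveillance"):
            v = getattr(self, f)
            if v is not None:
                d[f] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Recommendation":
        return cls(
            decision_kind=d["decision_kind"],
            provenance=tuple(d["provenance"]),
            modality=d.get("modality"),
            start_age=d.get("start_age"),
            interval=d.get("interval"),
            continue_surveillance=d.get("continue_surveillance"),
        )


def _check_age(violations: list[str], name: str, value) -> None:
    if value is None:
        return
    if not (AGE_RANGE[0] <= value <= AGE_RANGE[1]):
        violations.append(f"{name}: age {value} outside [{AGE_RANGE[0]}, {AGE_RANGE[1]}]")


def validate_case(case: PatientCase) -> list[str]:
    """Return a list of invariant violations for ``case`` (empty iff valid).

    Pure: the same case always yields the same list.  Violations name the
    offending field and the rule breached; nothing is raised.
    """
    v: list[str] = []
    fh = case.family_history
    for deg in ("first", "second"):
        count = getattr(fh, f"{deg}_degree_count")
        age = getattr(fh, f"{deg}_degree_min_dx_age")
        if count < 0:
            v.append(f"family_history.{deg}_degree_count: must be >= 0, got {count}")
        if count >= 1 and age is None:
            v.append(
                f"family_history.{deg}_degree_min_dx_age: required when "
                f"{deg}_degree_count >= 1"
            )
        if count == 0 and age is not None:
            v.append(
                f"family_history.{deg}_degree_min_dx_age: must be absent when "
                f"{deg}_degree_count == 0"
            )
        _check_age(v, f"family_history.{deg}_degree_min_dx_age", age)

    for label, findings in (("index_findings", case.index_findings),
                            ("followup_findings", case.followup_findings)):
        if findings is None:
            continue
        if findings.adenoma_count < 0:
            v.append(f"{label}.adenoma_count: must be >= 0")
        if findings.cssp_count < 0:
            v.append(f"{label}.cssp_count: must be >= 0")
        for flag in sorted(findings.feature_flags):
            if flag.startswith("adenoma_") and findings.adenoma_count < 1:
                v.append(f"{label}.feature_flags: {flag} requires adenoma_count >= 1")
            elif flag.startswith("cssp_") and findings.cssp_count < 1:
                v.append(f"{label}.feature_flags: {flag} requires cssp_count >= 1")

    if case.context is not None:
        if case.context.prior_interval <= 0:
            v.append("context.prior_interval: must be > 0 months")
        if case.context.prior_lesion_type not in PRIOR_LESION_TYPES:
            v.append(
                "context.prior_lesion_type: "
                f"{case.context.prior_lesion_type!r} not one of {PRIOR_LESION_TYPES}"
            )

    if (case.context is None) != (case.followup_findings is None):
        v.append("context: must be present iff followup_findings is present")

    _check_age(v, "comorbidity.age", case.comorbidity.age)
    return v


# ---------------------------------------------------------------------------
# JSON serialisation (field names exactly as in the type definitions)

def case_to_dict(case: PatientCase) -> dict:
    d = asdict(case)
    d["index_findings"]["feature_flags"] = sorted(case.index_findings.feature_flags)
    if case.followup_findings is not None:
        d["followup_findings"]["feature_flags"] = sorted(case.followup_findings.feature_flags)
    d["comorbidity"]["conditions"] = sorted(case.comorbidity.conditions)
    return d


def case_from_dict(d: dict) -> PatientCase:
    fh = FamilyHistory(**d["family_history"])
    idx = LesionFindings(
        adenoma_count=d["index_findings"].get("adenoma_count", 0),
        cssp_count=d["index_findings"].get("cssp_count", 0),
        feature_flags=frozenset(d["index_findings"].get("feature_flags", [])),
    )
    fu = None
    if d.get("followup_findings") is not None:
        fu = LesionFindings(
            adenoma_count=d["followup_findings"].get("adenoma_count", 0),
            cssp_count=d["followup_findings"].get("cssp_count", 0),
            feature_flags=frozenset(d["followup_findings"].get("feature_flags", [])),
        )
    ctx = None
    if d.get("context") is not None:
        ctx = SurveillanceContext(**d["context"])
    com = ComorbidityProfile(
        age=d["comorbidity"]["age"],
        conditions=frozenset(d["comorbidity"].get("conditions", [])),
    )
    return PatientCase(family_history=fh, index_findings=idx, comorbidity=com,
                       followup_findings=fu, context=ctx)


def case_to_json(case: PatientCase) -> str:
    return json.dumps(case_to_dict(case), indent=2, sort_keys=True)


def case_from_json(text: str) -> PatientCase:
    return case_from_dict(json.loads(text))
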