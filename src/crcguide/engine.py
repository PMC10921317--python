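"""Deterministic recommendation computation.

The four calculators of the digital application: family-history screening,
first surveillance interval, subsequent surveillance interval, and the
surveillance-cessation (stopping) rule.  Each calculator bins the raw case
inputs using the bins declared by the table in play, selects the table by
discriminator values (a hash lookup), and then linearly scans that table's
rows for the unique match.  Correctness is defined by equivalence with
:func:`scan_point`, a naive full-row scan over the whole section — the same
exhaustive strategy used to validate the original application against every
scenario of the guideline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .domain import (ComorbidityProfile, FamilyHistory, LesionFindings, PatientCase,
                     Recommendation, SurveillanceContext)
from .errors import CoverageError, CrcGuideError, IntegrityError, VocabularyError
from .ruleset import Band, Rule, Ruleset, Table


@dataclass(frozen=True)
class CharlsonWeights:
    """Modified-Charlson configuration: condition weights, age points and the
    minimum age at which the stopping rule is assessed.  The stopping
    thresholds themselves are the cessation table's rows."""

    condition_weights: dict[str, int]
    age_bands: tuple[Band, ...]
    age_points: dict[str, int]  # band label -> points
    min_assessment_age: int = 75

    @classmethod
    def from_ruleset(cls, ruleset: Ruleset) -> "CharlsonWeights":
        return cls(condition_weights=dict(ruleset.charlson_weights),
                   age_bands=ruleset.charlson_age_points,
                   age_points=dict(ruleset.charlson_age_point_values),
                   min_assessment_age=ruleset.min_assessment_age)


def charlson_score(profile: ComorbidityProfile, weights: CharlsonWeights) -> int:
    """Sum of condition weights plus age-band points (always >= 0)."""
    total = 0
    for cond in sorted(profile.conditions):
        if cond not in weights.condition_weights:
            raise VocabularyError(f"unknown condition code {cond!r}")
        total += weights.condition_weights[cond]
    for band in weights.age_bands:
        if band.contains(profile.age):
            total += weights.age_points[band.label]
            break
    return total


# ---------------------------------------------------------------------------
# Binding raw inputs to a table's declared bins

def lesion_profile(findings: LesionFindings) -> str:
    if findings.adenoma_count > 0 and findings.cssp_count > 0:
        return "mixed"
    if findings.cssp_count > 0:
        return "serrated_only"
    return "adenoma_only"


def _risk_flag(findings: LesionFindings, lesion_class: str,
               vocabulary: dict[str, str]) -> Optional[str]:
    """'f' if any declared feature of the class is flagged, 'nf' otherwise;
    None when no lesion of the class is present."""
    for flag in findings.feature_flags:
        if flag not in vocabulary:
            raise VocabularyError(f"unknown feature code {flag!r}")
    count = findings.adenoma_count if lesion_class == "adenoma" else findings.cssp_count
    if count == 0:
        return None
    flagged = any(vocabulary.get(f) == lesion_class for f in findings.feature_flags)
    return "f" if flagged else "nf"


def _sources_for(ruleset: Ruleset, fh: FamilyHistory | None,
                 findings: LesionFindings | None,
                 ctx: SurveillanceContext | None,
                 profile: ComorbidityProfile | None,
                 score: int | None) -> dict[str, object]:
    src: dict[str, object] = {}
    if fh is not None:
        src["family_history.first_degree_count"] = fh.first_degree_count
        src["family_history.first_degree_min_dx_age"] = fh.first_degree_min_dx_age
        src["family_history.second_degree_count"] = fh.second_degree_count
        src["family_history.second_degree_min_dx_age"] = fh.second_degree_min_dx_age
    if findings is not None:
        src["findings.adenoma_count"] = findings.adenoma_count
        src["findings.cssp_count"] = findings.cssp_count
        src["findings.adenoma_risk"] = _risk_flag(findings, "adenoma", ruleset.vocabulary)
        src["findings.cssp_risk"] = _risk_flag(findings, "cssp", ruleset.vocabulary)
    if ctx is not None:
        src["context.prior_interval"] = ctx.prior_interval
    if profile is not None:
        src["comorbidity.age"] = profile.age
    if score is not None:
        src["charlson_score"] = score
    return src


def bind_point(table: Table, sources: dict[str, object]) -> dict[str, str]:
    """Bin raw source values into the table's declared labels (selector
    values included).  Raises :class:`CoverageError` when a value falls in no
    declared bin."""
    point = dict(table.select)
    for v in table.variables:
        raw = sources.get(v.source)
        if raw is None:
            if v.absent_label is None:
                raise CoverageError(
                    f"table {table.table_id}: no value for {v.source} and no "
                    f"absent label declared for {v.name}", point)
            point[v.name] = v.absent_label
            continue
        if v.kind == "integer-range":
            label = v.band_for(int(raw))
            if label is None:
                raise CoverageError(
                    f"table {table.table_id}: value {raw} of {v.source} falls in "
                    f"no declared bin of {v.name}", point)
            point[v.name] = label
        else:
            label = str(raw)
            if label not in v.labels():
                raise CoverageError(
                    f"table {table.table_id}: value {label!r} of {v.source} not in "
                    f"declared domain of {v.name}", point)
            point[v.name] = label
    return point


# ---------------------------------------------------------------------------
# Matching

def match_point(ruleset: Ruleset, section: str, point: dict[str, str]) -> tuple[Table, Rule]:
    """Indexed lookup: select the table whose discriminator values match the
    point, then scan that table's rows for the unique match."""
    candidates = [t for t in ruleset.section(section)
                  if all(point.get(k) == v for k, v in t.select.items())]
    if not candidates:
        raise CoverageError(f"{section}: no table for input point", point)
    if len(candidates) > 1:
        raise IntegrityError(f"{section}: multiple tables claim point {point}")
    table = candidates[0]
    hits = [r for r in table.rows if r.matches(point)]
    if not hits:
        raise CoverageError(
            f"{section}: no row of table {table.table_id} matches input point", point)
    if len(hits) > 1:
        raise IntegrityError(
            f"{section}: rows {[r.row_id for r in hits]} of table "
            f"{table.table_id} all match point {point}")
    return table, hits[0]


def scan_point(ruleset: Ruleset, section: str, point: dict[str, str]) -> tuple[Table, Rule]:
    """Naive oracle: scan every row of every table in the section, selector
    clauses treated as ordinary predicates."""
    hits = []
    for t in ruleset.section(section):
        if not all(point.get(k) == v for k, v in t.select.items()):
            continue
        for r in t.rows:
            if r.matches(point):
                hits.append((t, r))
    if not hits:
        raise CoverageError(f"{section}: no row matches input point", point)
    if len(hits) > 1:
        raise IntegrityError(
            f"{section}: rows {[r.row_id for _, r in hits]} all match {point}")
    return hits[0]


def _select_table(ruleset: Ruleset, section: str,
                  discriminators: dict[str, str]) -> Table:
    for t in ruleset.section(section):
        if t.select == discriminators or all(
                discriminators.get(k) == v for k, v in t.select.items()):
            return t
    raise CoverageError(f"{section}: no table for {discriminators}", discriminators)


def _lookup(ruleset: Ruleset, section: str, discriminators: dict[str, str],
            sources: dict[str, object]) -> tuple[Table, Rule]:
    table = _select_table(ruleset, section, discriminators)
    point = bind_point(table, sources)
    return match_point(ruleset, section, point)


# ---------------------------------------------------------------------------
# The four calculators

def screening_recommendation(ruleset: Ruleset, fh: FamilyHistory) -> Recommendation:
    """Screening modality and start age from family history alone."""
    sources = _sources_for(ruleset, fh, None, None, None, None)
    table, row = _lookup(ruleset, "screening", {}, sources)
    return Recommendation(
        decision_kind="screening",
        modality=row.recommendation.get("modality"),
        start_age=row.recommendation.get("start_age"),
        provenance=(table.table_id, row.row_id),
    )


def first_surveillance(ruleset: Ruleset, findings: LesionFindings) -> Recommendation:
    """Interval to the first surveillance colonoscopy from index findings."""
    sources = _sources_for(ruleset, None, findings, None, None, None)
    disc = {"lesion_profile": lesion_profile(findings)}
    table, row = _lookup(ruleset, "first_surveillance", disc, sources)
    return Recommendation(
        decision_kind="first_surveillance",
        interval=row.recommendation.get("interval"),
        provenance=(table.table_id, row.row_id),
    )


def subsequent_surveillance(ruleset: Ruleset, findings: LesionFindings,
                            ctx: SurveillanceContext) -> Recommendation:
    """Interval to the next surveillance colonoscopy: the table is selected by
    the prior lesion type and the current lesion profile (the two consecutive
    tables a user of the printed guideline must navigate), then the row by the
    prior interval and current findings."""
    if ctx.prior_lesion_type not in ruleset.discriminators.get("prior_lesion_type", ()):
        raise CoverageError(
            f"subsequent_surveillance: prior lesion type {ctx.prior_lesion_type!r} "
            "has no decision table", {"prior_lesion_type": ctx.prior_lesion_type})
    sources = _sources_for(ruleset, None, findings, ctx, None, None)
    disc = {"prior_lesion_type": ctx.prior_lesion_type,
            "lesion_profile": lesion_profile(findings)}
    table, row = _lookup(ruleset, "subsequent_surveillance", disc, sources)
    return Recommendation(
        decision_kind="subsequent_surveillance",
        interval=row.recommendation.get("interval"),
        provenance=(table.table_id, row.row_id),
    )


def cessation_decision(ruleset: Ruleset, profile: ComorbidityProfile,
                       weights: CharlsonWeights | None = None) -> Recommendation:
    """Whether surveillance should continue, from the (age band, modified
    Charlson score) stopping table.  Patients below the minimum
    cessation-assessment age always continue."""
    weights = weights or CharlsonWeights.from_ruleset(ruleset)
    score = charlson_score(profile, weights)
    table = ruleset.section("cessation")[0]
    if profile.age < weights.min_assessment_age:
        return Recommendation(decision_kind="cessation", continue_surveillance=True,
                              provenance=(table.table_id, "below_assessment_age"))
    sources = _sources_for(ruleset, None, None, None, profile, score)
    table, row = _lookup(ruleset, "cessation", {}, sources)
    return Recommendation(
        decision_kind="cessation",
        continue_surveillance=bool(row.recommendation.get("continue_surveillance")),
        provenance=(table.table_id, row.row_id),
    )


def recommend(ruleset: Ruleset, case: PatientCase) -> list[Recommendation]:
    """All recommendations for a case, in guideline order: screening, first
    surveillance, subsequent surveillance (when a follow-up round is present)
    and the stopping rule.  A pure composition of the four calculators;
    component errors are re-raised annotated with the decision kind."""
    out: list[Recommendation] = []
    steps: list[tuple[str, object]] = [
        ("screening", lambda: screening_recommendation(ruleset, case.family_history)),
        ("first_surveillance", lambda: first_surveillance(ruleset, case.index_findings)),
    ]
    if case.context is not None and case.followup_findings is not None:
        steps.append(("subsequent_surveillance",
                      lambda: subsequent_surveillance(ruleset, case.followup_findings,
                                                      case.context)))
    steps.append(("cessation", lambda: cessation_decision(ruleset, case.comorbidity)))
    for kind, step in steps:
        try:
            out.append(step())
        except CrcGuideError as e:
            raise type(e)(f"[{kind}] {e}") from e
    return out
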