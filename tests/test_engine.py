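"""Engine correctness: exhaustive oracle equivalence and the Charlson /
cessation calculators.

The central check mirrors the validation strategy of the original
application: every enumerable scenario is computed individually and the
indexed table lookup must agree with a naive scan over all rows.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcguide.domain import (ComorbidityProfile, FamilyHistory, LesionFindings,
                             PatientCase, SurveillanceContext)
from crcguide.engine import (CharlsonWeights, bind_point, cessation_decision,
                             charlson_score, first_surveillance, lesion_profile,
                             match_point, recommend, scan_point,
                             screening_recommendation, subsequent_surveillance)
from crcguide.errors import CoverageError, IntegrityError, VocabularyError
from crcguide.ruleset import enumerate_scenarios, load_ruleset
from crcguide.skeleton import CHARLSON_WEIGHTS

SECTIONS = ("screening", "first_surveillance", "subsequent_surveillance", "cessation")


# ---------------------------------------------------------------------------
# point -> representative raw inputs (inverse binning for test construction)

def _rep_value(table, var_name, label):
    v = table.variable(var_name)
    if label == v.absent_label:
        return None
    for b in v.bands:
        if b.label == label:
            return b.min
    return label


def _family_history(table, point):
    return FamilyHistory(
        first_degree_count=_rep_value(table, "fd_count", point["fd_count"]),
        first_degree_min_dx_age=_rep_value(table, "fd_dx_age", point["fd_dx_age"]),
        second_degree_count=_rep_value(table, "sd_count", point["sd_count"]),
        second_degree_min_dx_age=_rep_value(table, "sd_dx_age", point["sd_dx_age"]),
    )


def _findings(table, point):
    adenoma = cssp = 0
    flags = set()
    if "adenoma_band" in point:
        adenoma = _rep_value(table, "adenoma_band", point["adenoma_band"])
    if "cssp_band" in point:
        cssp = _rep_value(table, "cssp_band", point["cssp_band"])
    profile = point.get("lesion_profile")
    if profile == "serrated_only" and "adenoma_band" not in point:
        adenoma = 0
    if profile == "mixed":
        assert adenoma >= 1 and cssp >= 1
    if point.get("adenoma_risk") == "f":
        flags.add("adenoma_size_ge_10mm")
    if point.get("cssp_risk") == "f":
        flags.add("cssp_dysplasia")
    return LesionFindings(adenoma_count=adenoma, cssp_count=cssp,
                          feature_flags=frozenset(flags))


@pytest.mark.parametrize("section", SECTIONS)
def test_indexed_lookup_equals_naive_scan_on_every_scenario(skeleton, section):
    points = enumerate_scenarios(skeleton, section)
    assert points
    for point in points:
        t1, r1 = match_point(skeleton, section, point)
        t2, r2 = scan_point(skeleton, section, point)
        assert (t1.table_id, r1.row_id) == (t2.table_id, r2.row_id)


def test_screening_calculator_matches_scan_for_every_scenario(skeleton):
    table = skeleton.section("screening")[0]
    for point in enumerate_scenarios(skeleton, "screening"):
        fh = _family_history(table, point)
        rec = screening_recommendation(skeleton, fh)
        _, row = scan_point(skeleton, "screening", point)
        assert rec.provenance == (table.table_id, row.row_id)
        assert rec.modality == row.recommendation["modality"]


@pytest.mark.parametrize("section, op", [
    ("first_surveillance", "first"),
    ("subsequent_surveillance", "subsequent"),
])
def test_surveillance_calculators_match_scan_for_every_scenario(skeleton, section, op):
    tables = {t.table_id: t for t in skeleton.section(section)}
    for point in enumerate_scenarios(skeleton, section):
        t_scan, row = scan_point(skeleton, section, point)
        table = tables[t_scan.table_id]
        findings = _findings(table, point)
        assert lesion_profile(findings) == point["lesion_profile"]
        if op == "first":
            rec = first_surveillance(skeleton, findings)
        else:
            ctx = SurveillanceContext(
                prior_interval=_rep_value(table, "interval_band",
                                          point["interval_band"]),
                prior_lesion_type=point["prior_lesion_type"])
            rec = subsequent_surveillance(skeleton, findings, ctx)
        assert rec.provenance == (t_scan.table_id, row.row_id)
        assert rec.interval == row.recommendation["interval"]


def test_zero_relatives_hits_population_risk_row(skeleton):
    rec = screening_recommendation(skeleton, FamilyHistory())
    assert rec.modality == "stool_test"
    assert rec.decision_kind == "screening"


def test_no_lesions_hits_lowest_risk_first_surveillance_row(skeleton):
    rec = first_surveillance(skeleton, LesionFindings())
    table = skeleton.section("first_surveillance")[0]
    intervals = [r.recommendation["interval"] for r in table.rows]
    assert rec.interval == max(intervals)


def test_age_bin_boundary_is_deterministic(skeleton):
    # 59 and 60 straddle the declared first-degree diagnosis-age bin edge
    low = screening_recommendation(skeleton, FamilyHistory(1, 59, 0, None))
    high = screening_recommendation(skeleton, FamilyHistory(1, 60, 0, None))
    assert low.provenance != high.provenance
    again = screening_recommendation(skeleton, FamilyHistory(1, 59, 0, None))
    assert again == low


def test_undeclared_prior_lesion_type_is_a_coverage_error(skeleton):
    with pytest.raises(CoverageError):
        subsequent_surveillance(
            skeleton, LesionFindings(adenoma_count=1),
            SurveillanceContext(prior_interval=36, prior_lesion_type="none"))


def test_constructed_gap_raises_coverage_error(skeleton_doc):
    rows = skeleton_doc["sections"]["first_surveillance"][0]["rows"]
    target = next(r for r in rows
                  if r["when"] == {"adenoma_band": "1", "adenoma_risk": "nf"})
    rows.remove(target)
    mutated = load_ruleset(skeleton_doc)
    with pytest.raises(CoverageError):
        first_surveillance(mutated, LesionFindings(adenoma_count=1))


def test_duplicate_row_raises_integrity_error(skeleton_doc):
    rows = skeleton_doc["sections"]["first_surveillance"][0]["rows"]
    dup = dict(rows[1])
    dup["id"] = "FS-DUP"
    rows.append(dup)
    mutated = load_ruleset(skeleton_doc)
    with pytest.raises(IntegrityError):
        first_surveillance(mutated, LesionFindings(adenoma_count=1))


# ---------------------------------------------------------------------------
# Charlson score

@pytest.fixture(scope="module")
def weights(skeleton):
    return CharlsonWeights.from_ruleset(skeleton)


def _age_points_oracle(age):
    for lo, hi, pts in ((0, 40, 0), (41, 50, 1), (51, 60, 2), (61, 70, 3),
                        (71, 80, 4), (81, 120, 5)):
        if lo <= age <= hi:
            return pts
    raise AssertionError(age)


def test_young_healthy_profile_scores_zero(skeleton, weights):
    assert charlson_score(ComorbidityProfile(age=35), weights) == 0


def test_single_condition_is_weight_plus_age_points(skeleton, weights):
    score = charlson_score(
        ComorbidityProfile(age=66, conditions=frozenset({"metastatic_solid_tumour"})),
        weights)
    assert score == 6 + 3


def test_unknown_condition_is_a_vocabulary_error(skeleton, weights):
    with pytest.raises(VocabularyError, match="gout"):
        charlson_score(ComorbidityProfile(age=50, conditions=frozenset({"gout"})),
                       weights)


@settings(deadline=None, max_examples=60)
@given(age=st.integers(0, 120),
       conditions=st.sets(st.sampled_from(sorted(CHARLSON_WEIGHTS))))
def test_charlson_equals_brute_force_resummation(age, conditions):
    from crcguide.skeleton import reference_skeleton
    skeleton = reference_skeleton()
    w = CharlsonWeights.from_ruleset(skeleton)
    expected = sum(CHARLSON_WEIGHTS[c] for c in conditions) + _age_points_oracle(age)
    assert charlson_score(
        ComorbidityProfile(age=age, conditions=frozenset(conditions)), w) == expected


@settings(deadline=None, max_examples=40)
@given(age=st.integers(0, 120),
       conditions=st.sets(st.sampled_from(sorted(CHARLSON_WEIGHTS))),
       extra=st.sampled_from(sorted(CHARLSON_WEIGHTS)))
def test_charlson_monotone_in_condition_set(age, conditions, extra):
    from crcguide.skeleton import reference_skeleton
    skeleton = reference_skeleton()
    w = CharlsonWeights.from_ruleset(skeleton)
    base = charlson_score(ComorbidityProfile(age=age, conditions=frozenset(conditions)), w)
    more = charlson_score(
        ComorbidityProfile(age=age, conditions=frozenset(conditions | {extra})), w)
    assert more >= base


# ---------------------------------------------------------------------------
# Cessation

def test_below_assessment_age_always_continues(skeleton):
    heavy = frozenset({"metastatic_solid_tumour", "aids", "dementia"})
    rec = cessation_decision(skeleton, ComorbidityProfile(age=50, conditions=heavy))
    assert rec.continue_surveillance is True


def test_score_above_stop_bound_stops(skeleton):
    heavy = frozenset({"metastatic_solid_tumour", "moderate_severe_liver_disease"})
    rec = cessation_decision(skeleton, ComorbidityProfile(age=76, conditions=heavy))
    assert rec.continue_surveillance is False


def test_boundary_score_follows_declared_band(skeleton):
    # age 76 contributes 4 points; +1 condition point = 5, first point of the
    # middle score band, which the 75-79 row declares as continue
    rec = cessation_decision(
        skeleton, ComorbidityProfile(age=76, conditions=frozenset({"diabetes"})))
    _, row = scan_point(skeleton, "cessation",
                        {"age_band": "75_79", "score_band": "5_6"})
    assert rec.continue_surveillance == row.recommendation["continue_surveillance"]
    assert rec.provenance[1] == row.row_id


def test_cessation_monotone_in_score(skeleton):
    """Raising the Charlson score at fixed age never flips stop -> continue."""
    ladder = [frozenset(), frozenset({"diabetes"}),
              frozenset({"diabetes", "hemiplegia"}),
              frozenset({"diabetes", "hemiplegia", "metastatic_solid_tumour"})]
    for age in (75, 80, 85, 90):
        continuing = [cessation_decision(
            skeleton, ComorbidityProfile(age=age, conditions=c)).continue_surveillance
            for c in ladder]
        # once stopped, never continues again as score rises
        assert continuing == sorted(continuing, reverse=True)


# ---------------------------------------------------------------------------
# Composition

def _full_case():
    return PatientCase(
        family_history=FamilyHistory(1, 52, 0, None),
        index_findings=LesionFindings(adenoma_count=3),
        followup_findings=LesionFindings(adenoma_count=1),
        context=SurveillanceContext(prior_interval=36, prior_lesion_type="adenoma"),
        comorbidity=ComorbidityProfile(age=72),
    )


def test_case_without_followup_yields_three_recommendations(skeleton):
    case = PatientCase(
        family_history=FamilyHistory(),
        index_findings=LesionFindings(adenoma_count=1),
        comorbidity=ComorbidityProfile(age=60),
    )
    recs = recommend(skeleton, case)
    assert [r.decision_kind for r in recs] == ["screening", "first_surveillance",
                                               "cessation"]


def test_full_case_composition_equals_single_op_calls(skeleton):
    case = _full_case()
    recs = recommend(skeleton, case)
    assert [r.decision_kind for r in recs] == [
        "screening", "first_surveillance", "subsequent_surveillance", "cessation"]
    assert recs[0] == screening_recommendation(skeleton, case.family_history)
    assert recs[1] == first_surveillance(skeleton, case.index_findings)
    assert recs[2] == subsequent_surveillance(skeleton, case.followup_findings,
                                              case.context)
    assert recs[3] == cessation_decision(skeleton, case.comorbidity)
    # determinism, provenance included
    assert recommend(skeleton, case) == recs
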