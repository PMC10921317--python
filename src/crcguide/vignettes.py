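"""The six clinical vignettes of the crossover quiz.

Three difficulty-matched pairs — (alpha, beta), (gamma, theta), (delta,
omega) — each pair navigating the same decision tables: the first pair
exercises the conventional-adenoma surveillance tables, the second the
serrated-polyp tables, the third the mixed-findings tables.  The cases are
SYNTHETIC fixtures (the study's vignettes are not public); their answer keys
are not stored but derived from the recommendation engine on whichever
ruleset is in play, so key and engine can never disagree.

Each vignette is scored on six items: screening start age and modality, the
first and subsequent surveillance intervals, and the continue/stop decision
at each of the two intended procedures (the patient's age advanced by the
recommended interval each time).
"""

from __future__ import annotations

from .domain import (ComorbidityProfile, FamilyHistory, LesionFindings, PatientCase,
                     SurveillanceContext)
from .engine import cessation_decision, recommend
from .evaluation import VIGNETTE_PAIRS, Vignette
from .ruleset import Ruleset

VIGNETTE_CASES: dict[str, PatientCase] = {
    "alpha": PatientCase(
        family_history=FamilyHistory(first_degree_count=1, first_degree_min_dx_age=52),
        index_findings=LesionFindings(adenoma_count=3,
                                      feature_flags=frozenset({"adenoma_size_ge_10mm"})),
        followup_findings=LesionFindings(adenoma_count=1),
        context=SurveillanceContext(prior_interval=36, prior_lesion_type="adenoma"),
        comorbidity=ComorbidityProfile(age=72, conditions=frozenset({"diabetes"})),
    ),
    "beta": PatientCase(
        family_history=FamilyHistory(first_degree_count=1, first_degree_min_dx_age=47),
        index_findings=LesionFindings(
            adenoma_count=4, feature_flags=frozenset({"adenoma_high_grade_dysplasia"})),
        followup_findings=LesionFindings(adenoma_count=2),
        context=SurveillanceContext(prior_interval=36, prior_lesion_type="adenoma"),
        comorbidity=ComorbidityProfile(
            age=73, conditions=frozenset({"chronic_pulmonary_disease"})),
    ),
    "gamma": PatientCase(
        family_history=FamilyHistory(second_degree_count=1, second_degree_min_dx_age=58),
        index_findings=LesionFindings(cssp_count=2,
                                      feature_flags=frozenset({"cssp_dysplasia"})),
        followup_findings=LesionFindings(cssp_count=3),
        context=SurveillanceContext(prior_interval=60, prior_lesion_type="serrated"),
        comorbidity=ComorbidityProfile(
            age=70, conditions=frozenset({"myocardial_infarction"})),
    ),
    "theta": PatientCase(
        family_history=FamilyHistory(second_degree_count=2, second_degree_min_dx_age=55),
        index_findings=LesionFindings(cssp_count=5),
        followup_findings=LesionFindings(cssp_count=1,
                                         feature_flags=frozenset({"cssp_size_ge_10mm"})),
        context=SurveillanceContext(prior_interval=36, prior_lesion_type="serrated"),
        comorbidity=ComorbidityProfile(
            age=74, conditions=frozenset({"moderate_severe_renal_disease"})),
    ),
    "delta": PatientCase(
        family_history=FamilyHistory(first_degree_count=1, first_degree_min_dx_age=65),
        index_findings=LesionFindings(adenoma_count=2, cssp_count=1),
        followup_findings=LesionFindings(adenoma_count=1, cssp_count=1),
        context=SurveillanceContext(prior_interval=18, prior_lesion_type="both"),
        comorbidity=ComorbidityProfile(
            age=76, conditions=frozenset({"congestive_heart_failure", "diabetes"})),
    ),
    "omega": PatientCase(
        family_history=FamilyHistory(first_degree_count=3, first_degree_min_dx_age=58),
        index_findings=LesionFindings(adenoma_count=5, cssp_count=3),
        followup_findings=LesionFindings(adenoma_count=4, cssp_count=6),
        context=SurveillanceContext(prior_interval=24, prior_lesion_type="both"),
        comorbidity=ComorbidityProfile(age=78, conditions=frozenset({"dementia"})),
    ),
}


def vignette_key(ruleset: Ruleset, case: PatientCase) -> dict[str, object]:
    """Derive the six scored answers for a case from the engine.

    The cessation question is answered at each intended procedure: the
    patient's age advanced by the first interval, then additionally by the
    subsequent interval (months rounded down to whole years).
    """
    recs = {r.decision_kind: r for r in recommend(ruleset, case)}
    first = recs["first_surveillance"].interval
    subsequent = recs["subsequent_surveillance"].interval
    age1 = case.comorbidity.age + first // 12
    age2 = age1 + subsequent // 12
    ces1 = cessation_decision(ruleset, ComorbidityProfile(
        age=age1, conditions=case.comorbidity.conditions))
    ces2 = cessation_decision(ruleset, ComorbidityProfile(
        age=age2, conditions=case.comorbidity.conditions))
    return {
        "screening_start_age": recs["screening"].start_age,
        "screening_modality": recs["screening"].modality,
        "first_interval": first,
        "subsequent_interval": subsequent,
        "cessation_first": ces1.continue_surveillance,
        "cessation_subsequent": ces2.continue_surveillance,
    }


def build_vignettes(ruleset: Ruleset) -> dict[str, Vignette]:
    """All six vignettes with engine-derived keys against ``ruleset``."""
    pair_of = {vid: f"{a}-{b}" for a, b in VIGNETTE_PAIRS for vid in (a, b)}
    return {
        vid: Vignette(vignette_id=vid, case=case,
                      key=vignette_key(ruleset, case), pair_id=pair_of[vid])
        for vid, case in VIGNETTE_CASES.items()
    }
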