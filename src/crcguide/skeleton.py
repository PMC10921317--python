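"""Reference skeleton ruleset builder.

Builds the packaged decision-table skeleton whose structure mirrors the
published Australian colorectal-cancer guideline: 90 screening scenarios in
one table, 37 first-surveillance scenarios across 3 tables (conventional
adenomas only / serrated polyps only / mixed findings), 140
subsequent-surveillance scenarios across 9 tables (3 prior lesion types x 3
current lesion profiles), and a cessation table keyed on age band and
modified Charlson score.

Recommendation payloads are SYNTHETIC placeholders (provenance
``skeleton``): they are internally consistent, monotone-in-risk values
generated from each row's coordinates, not transcriptions of the guideline.
Transcribing authoritative values from the published guideline is a
data-entry task that changes no code and no logic test.

Regenerate the packaged file with ``python -m crcguide.skeleton``.
"""

from __future__ import annotations

import sys
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .ruleset import Ruleset, load_ruleset

DATA_FILE = "skeleton.yaml"

# Standard Charlson comorbidity weights; age contributes one point per
# decade of age over 40 (configuration data, swappable per ruleset file).
CHARLSON_WEIGHTS = {
    "myocardial_infarction": 1, "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1, "cerebrovascular_disease": 1,
    "dementia": 1, "chronic_pulmonary_disease": 1,
    "connective_tissue_disease": 1, "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1, "diabetes": 1,
    "diabetes_with_end_organ_damage": 2, "hemiplegia": 2,
    "moderate_severe_renal_disease": 2, "solid_tumour": 2,
    "leukemia": 2, "lymphoma": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumour": 6, "aids": 6,
}

AGE_POINTS = [
    {"label": "le40", "min": 0, "max": 40, "points": 0},
    {"label": "41_50", "min": 41, "max": 50, "points": 1},
    {"label": "51_60", "min": 51, "max": 60, "points": 2},
    {"label": "61_70", "min": 61, "max": 70, "points": 3},
    {"label": "71_80", "min": 71, "max": 80, "points": 4},
    {"label": "ge81", "min": 81, "max": 120, "points": 5},
]

VOCABULARY = {
    "adenoma_size_ge_10mm": "adenoma",
    "adenoma_high_grade_dysplasia": "adenoma",
    "adenoma_villous": "adenoma",
    "cssp_size_ge_10mm": "cssp",
    "cssp_dysplasia": "cssp",
}

_INTERVALS = [120, 60, 36, 18, 12, 6]  # months, by increasing severity


def _interval_for(severity: int) -> int:
    return _INTERVALS[min(severity, len(_INTERVALS) - 1)]


def _bands(spec: list[tuple[str, int, int | None]]) -> list[dict]:
    return [{"label": l, "min": lo, "max": hi} for l, lo, hi in spec]


def _screening_table() -> dict:
    fd_counts = _bands([("0", 0, 0), ("1", 1, 1), ("2", 2, 2), ("3plus", 3, None)])
    fd_ages = _bands([("lt45", 0, 44), ("45_59", 45, 59), ("ge60", 60, None)])
    sd_counts = _bands([("0", 0, 0), ("1", 1, 1), ("2plus", 2, None)])
    sd_ages = _bands([("lt50", 0, 49), ("50_59", 50, 59), ("60_69", 60, 69),
                      ("ge70", 70, None)])
    fd_sev = {("0", "na"): 0, ("1", "ge60"): 1, ("1", "45_59"): 2, ("1", "lt45"): 3,
              ("2", "ge60"): 3, ("2", "45_59"): 4, ("2", "lt45"): 5,
              ("3plus", "ge60"): 4, ("3plus", "45_59"): 5, ("3plus", "lt45"): 6}
    sd_sev = {("0", "na"): 0, ("1", "ge70"): 0, ("1", "60_69"): 0, ("1", "50_59"): 1,
              ("1", "lt50"): 1, ("2plus", "ge70"): 1, ("2plus", "60_69"): 1,
              ("2plus", "50_59"): 2, ("2plus", "lt50"): 2}
    rows = []
    i = 0
    for fd in fd_sev:
        for sd in sd_sev:
            i += 1
            sev = fd_sev[fd] + sd_sev[sd]
            rec = {
                "modality": "stool_test" if sev <= 1 else "colonoscopy",
                "start_age": max(35, 50 - 5 * max(0, sev - 1)),
            }
            rows.append({"id": f"SCR-{i:03d}",
                         "when": {"fd_count": fd[0], "fd_dx_age": fd[1],
                                  "sd_count": sd[0], "sd_dx_age": sd[1]},
                         "rec": rec})
    return {
        "id": "SCR",
        "select": {},
        "vars": [
            {"name": "fd_count", "kind": "integer-range",
             "source": "family_history.first_degree_count", "bands": fd_counts},
            {"name": "fd_dx_age", "kind": "integer-range",
             "source": "family_history.first_degree_min_dx_age", "bands": fd_ages,
             "absent_label": "na", "na_if": {"var": "fd_count", "equals": "0"}},
            {"name": "sd_count", "kind": "integer-range",
             "source": "family_history.second_degree_count", "bands": sd_counts},
            {"name": "sd_dx_age", "kind": "integer-range",
             "source": "family_history.second_degree_min_dx_age", "bands": sd_ages,
             "absent_label": "na", "na_if": {"var": "sd_count", "equals": "0"}},
        ],
        "rows": rows,
    }


def _adenoma_var(bands: list[tuple[str, int, int | None]]) -> list[dict]:
    return [
        {"name": "adenoma_band", "kind": "integer-range",
         "source": "findings.adenoma_count", "bands": _bands(bands)},
        {"name": "adenoma_risk", "kind": "category",
         "source": "findings.adenoma_risk", "values": ["nf", "f"],
         "absent_label": "na", "na_if": {"var": "adenoma_band", "equals": "0"}},
    ]


def _cssp_vars(bands: list[tuple[str, int, int | None]]) -> list[dict]:
    return [
        {"name": "cssp_band", "kind": "integer-range",
         "source": "findings.cssp_count", "bands": _bands(bands)},
        {"name": "cssp_risk", "kind": "category",
         "source": "findings.cssp_risk", "values": ["nf", "f"]},
    ]


def _count_risk_rows(prefix: str, count_labels: list[str], risk: bool,
                     base_sev, rec_for) -> list[dict]:
    """Rows over a (count band, optional risk flag) grid; band '0' pairs only
    with risk 'na'."""
    rows = []
    i = 0
    for cl in count_labels:
        risks = ["na"] if cl == "0" else (["nf", "f"] if risk else [None])
        for r in risks:
            i += 1
            sev = base_sev(cl) + (1 if r == "f" else 0)
            row = {"id": f"{prefix}-{i:02d}", "when": {}, "rec": rec_for(sev)}
            rows.append((row, cl, r, sev))
    return rows


def _first_surveillance_tables() -> list[dict]:
    tables = []
    # adenomas only (includes the no-significant-lesion case)
    a_bands = [("0", 0, 0), ("1", 1, 1), ("2", 2, 2), ("3", 3, 3), ("4", 4, 4),
               ("5_9", 5, 9), ("10plus", 10, None)]
    sev_a = {"0": 0, "1": 1, "2": 1, "3": 2, "4": 2, "5_9": 3, "10plus": 4}
    rows = []
    i = 0
    for cl, _, _ in a_bands:
        for r in (["na"] if cl == "0" else ["nf", "f"]):
            i += 1
            sev = sev_a[cl] + (1 if r == "f" else 0)
            rows.append({"id": f"FS-A-{i:02d}",
                         "when": {"adenoma_band": cl, "adenoma_risk": r},
                         "rec": {"interval": _interval_for(sev)}})
    tables.append({"id": "FS-A", "select": {"lesion_profile": "adenoma_only"},
                   "vars": _adenoma_var(a_bands), "rows": rows})

    # serrated polyps only
    c_bands = [("1_2", 1, 2), ("3_4", 3, 4), ("5plus", 5, None)]
    sev_c = {"1_2": 1, "3_4": 2, "5plus": 3}
    rows = []
    i = 0
    for cl, _, _ in c_bands:
        for r in ("nf", "f"):
            i += 1
            sev = sev_c[cl] + (1 if r == "f" else 0)
            rows.append({"id": f"FS-S-{i:02d}",
                         "when": {"cssp_band": cl, "cssp_risk": r},
                         "rec": {"interval": _interval_for(sev)}})
    tables.append({"id": "FS-S", "select": {"lesion_profile": "serrated_only"},
                   "vars": _cssp_vars(c_bands), "rows": rows})

    # both lesion classes present
    am_bands = [("1", 1, 1), ("2", 2, 2), ("3", 3, 3), ("4", 4, 4),
                ("5_9", 5, 9), ("10plus", 10, None)]
    rows = []
    i = 0
    for acl, _, _ in am_bands:
        for ccl, _, _ in c_bands:
            i += 1
            sev = sev_a[acl] + sev_c[ccl]
            rows.append({"id": f"FS-M-{i:02d}",
                         "when": {"adenoma_band": acl, "cssp_band": ccl},
                         "rec": {"interval": _interval_for(sev)}})
    tables.append({
        "id": "FS-M", "select": {"lesion_profile": "mixed"},
        "vars": [
            {"name": "adenoma_band", "kind": "integer-range",
             "source": "findings.adenoma_count", "bands": _bands(am_bands)},
            {"name": "cssp_band", "kind": "integer-range",
             "source": "findings.cssp_count", "bands": _bands(c_bands)},
        ],
        "rows": rows,
    })
    return tables


def _subsequent_tables() -> list[dict]:
    interval_var = {"name": "interval_band", "kind": "integer-range",
                    "source": "context.prior_interval",
                    "bands": _bands([("le36", 1, 36), ("gt36", 37, None)])}
    prior_sev = {"adenoma": 0, "serrated": 0, "both": 1}
    c_bands = [("1_2", 1, 2), ("3_4", 3, 4), ("5plus", 5, None)]
    sev_c = {"1_2": 1, "3_4": 2, "5plus": 3}
    tables = []
    for prior in ("adenoma", "serrated", "both"):
        p = prior[0].upper()
        # current: adenomas only (prior 'both' uses a coarser count binning)
        if prior == "both":
            a_bands = [("0", 0, 0), ("1_2", 1, 2), ("3_4", 3, 4), ("5plus", 5, None)]
            sev_a = {"0": 0, "1_2": 1, "3_4": 2, "5plus": 3}
        else:
            a_bands = [("0", 0, 0), ("1", 1, 1), ("2", 2, 2), ("3_4", 3, 4),
                       ("5plus", 5, None)]
            sev_a = {"0": 0, "1": 1, "2": 1, "3_4": 2, "5plus": 3}
        rows = []
        i = 0
        for ib in ("le36", "gt36"):
            for cl, _, _ in a_bands:
                for r in (["na"] if cl == "0" else ["nf", "f"]):
                    i += 1
                    sev = sev_a[cl] + (1 if r == "f" else 0) + prior_sev[prior] \
                        + (1 if ib == "le36" else 0)
                    rows.append({"id": f"SS-{p}A-{i:02d}",
                                 "when": {"interval_band": ib, "adenoma_band": cl,
                                          "adenoma_risk": r},
                                 "rec": {"interval": _interval_for(sev)}})
        tables.append({"id": f"SS-{p}A",
                       "select": {"prior_lesion_type": prior,
                                  "lesion_profile": "adenoma_only"},
                       "vars": [interval_var] + _adenoma_var(a_bands),
                       "rows": rows})

        # current: serrated only
        rows = []
        i = 0
        for ib in ("le36", "gt36"):
            for cl, _, _ in c_bands:
                for r in ("nf", "f"):
                    i += 1
                    sev = sev_c[cl] + (1 if r == "f" else 0) + prior_sev[prior] \
                        + (1 if ib == "le36" else 0)
                    rows.append({"id": f"SS-{p}S-{i:02d}",
                                 "when": {"interval_band": ib, "cssp_band": cl,
                                          "cssp_risk": r},
                                 "rec": {"interval": _interval_for(sev)}})
        tables.append({"id": f"SS-{p}S",
                       "select": {"prior_lesion_type": prior,
                                  "lesion_profile": "serrated_only"},
                       "vars": [interval_var] + _cssp_vars(c_bands),
                       "rows": rows})

        # current: both classes
        am_bands = [("1_2", 1, 2), ("3_4", 3, 4), ("5plus", 5, None)]
        sev_am = {"1_2": 1, "3_4": 2, "5plus": 3}
        rows = []
        i = 0
        for ib in ("le36", "gt36"):
            for acl, _, _ in am_bands:
                for ccl, _, _ in c_bands:
                    i += 1
                    sev = sev_am[acl] + sev_c[ccl] + prior_sev[prior] \
                        + (1 if ib == "le36" else 0)
                    rows.append({"id": f"SS-{p}M-{i:02d}",
                                 "when": {"interval_band": ib, "adenoma_band": acl,
                                          "cssp_band": ccl},
                                 "rec": {"interval": _interval_for(sev)}})
        tables.append({
            "id": f"SS-{p}M",
            "select": {"prior_lesion_type": prior, "lesion_profile": "mixed"},
            "vars": [interval_var,
                     {"name": "adenoma_band", "kind": "integer-range",
                      "source": "findings.adenoma_count", "bands": _bands(am_bands)},
                     {"name": "cssp_band", "kind": "integer-range",
                      "source": "findings.cssp_count", "bands": _bands(c_bands)}],
            "rows": rows,
        })
    return tables


def _cessation_table() -> dict:
    # Score bands sit above the age-point floor (age >= 75 alone contributes
    # 4 points), so every band is reachable in at least one age band.
    age_bands = _bands([("75_79", 75, 79), ("80_84", 80, 84), ("ge85", 85, None)])
    score_bands = _bands([("0_4", 0, 4), ("5_6", 5, 6), ("ge7", 7, None)])
    cont = {("75_79", "0_4"): True, ("75_79", "5_6"): True, ("75_79", "ge7"): False,
            ("80_84", "0_4"): True, ("80_84", "5_6"): False, ("80_84", "ge7"): False,
            ("ge85", "0_4"): True, ("ge85", "5_6"): False, ("ge85", "ge7"): False}
    rows = []
    for i, ((ab, sb), c) in enumerate(sorted(cont.items()), start=1):
        rows.append({"id": f"CES-{i:02d}", "when": {"age_band": ab, "score_band": sb},
                     "rec": {"continue_surveillance": c}})
    return {
        "id": "CES", "select": {},
        "vars": [
            {"name": "age_band", "kind": "integer-range",
             "source": "comorbidity.age", "bands": age_bands},
            {"name": "score_band", "kind": "integer-range",
             "source": "charlson_score", "bands": score_bands},
        ],
        "rows": rows,
    }


def build_skeleton() -> dict:
    """The reference skeleton ruleset as a plain document (YAML-serialisable)."""
    return {
        "meta": {"name": "reference-skeleton", "provenance": "skeleton",
                 "description": "Synthetic placeholder ruleset matching the "
                                "published guideline's table structure and "
                                "scenario counts (90 screening, 37 first "
                                "surveillance, 140 subsequent surveillance)."},
        "vocabulary": dict(VOCABULARY),
        "charlson": {"weights": dict(CHARLSON_WEIGHTS), "age_points": AGE_POINTS},
        "cessation": {"min_assessment_age": 75},
        "discriminators": {
            "lesion_profile": ["adenoma_only", "serrated_only", "mixed"],
            "prior_lesion_type": ["adenoma", "serrated", "both"],
        },
        "manifest": {"screening": 1, "first_surveillance": 3,
                     "subsequent_surveillance": 9, "cessation": 1},
        "sections": {
            "screening": [_screening_table()],
            "first_surveillance": _first_surveillance_tables(),
            "subsequent_surveillance": _subsequent_tables(),
            "cessation": [_cessation_table()],
        },
    }


def skeleton_yaml() -> str:
    return yaml.safe_dump(build_skeleton(), sort_keys=False, default_flow_style=None,
                          width=100)


@lru_cache(maxsize=1)
def reference_skeleton() -> Ruleset:
    """Load the packaged reference skeleton ruleset."""
    text = resources.files("crcguide").joinpath(f"data/{DATA_FILE}").read_text()
    return load_ruleset(yaml.safe_load(text))


def write_skeleton(path: str | Path) -> None:
    Path(path).write_text(skeleton_yaml())


if __name__ == "__main__":
    target = Path(sys.argv[1]) if len(sys.argv) > 1 else (
        Path(__file__).parent / "data" / DATA_FILE)
    write_skeleton(target)
    print(f"wrote {target}")
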