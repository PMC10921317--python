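"""Measurement instruments of the crossover evaluation.

System Usability Scale (SUS) scoring with slider-to-Likert binning, letter
grades and percentile normalisation against the Sauro–Lewis reference
distribution; guideline-concordance scoring of clinical vignettes; the eight
vignette combinations of the crossover design; and the stratified allocation
schedule generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .domain import PatientCase
from .errors import DomainError, FormatError

# --- SUS -------------------------------------------------------------------

# Reference distribution for percentile normalisation (Sauro–Lewis): SUS
# scores across tested systems are approximately normal with mean 68, SD 12.5.
SUS_REFERENCE_MEAN = 68.0
SUS_REFERENCE_SD = 12.5

# Letter grades with percentile bands: lower bound exclusive, upper inclusive.
SUS_GRADE_BANDS = (
    ("F", 0.0, 51.7, (0, 15)),
    ("D", 51.7, 62.6, (15, 34)),
    ("C", 62.6, 72.5, (35, 64)),
    ("B", 72.5, 78.8, (65, 84)),
    ("A", 78.8, 100.0, (85, 100)),
)

ODD_ITEMS = (0, 2, 4, 6, 8)   # positively worded statements
EVEN_ITEMS = (1, 3, 5, 7, 9)  # negatively worded statements


@dataclass(frozen=True)
class SUSResponse:
    """Ten slider values in [0, 100], one per SUS statement in order."""

    sliders: tuple[float, ...]

    def __post_init__(self):
        if len(self.sliders) != 10:
            raise FormatError(f"SUS response needs exactly 10 sliders, "
                              f"got {len(self.sliders)}")
        for i, v in enumerate(self.sliders):
            if not (0 <= v <= 100):
                raise DomainError(f"slider q{i + 1}={v} outside [0, 100]")


def slider_to_likert(v: float) -> int:
    """Map a 0–100 slider to a 1–5 Likert level.

    Bins: 0–20 strongly disagree (1); 21–40 disagree (2); 41–60 neutral (3);
    61–80 agree (4); 81–100 strongly agree (5).  Non-integer sliders are
    rounded half-up first, so boundary values belong to the lower bin.
    """
    if not (0 <= v <= 100):
        raise DomainError(f"slider value {v} outside [0, 100]")
    r = math.floor(v + 0.5)
    return 1 + min(4, max(0, (r - 1) // 20))


def sus_score(r: SUSResponse) -> float:
    """Standard SUS total: 2.5 * [sum_odd (L-1) + sum_even (5-L)], in [0,100]
    and always a multiple of 2.5."""
    likert = [slider_to_likert(v) for v in r.sliders]
    total = sum(likert[i] - 1 for i in ODD_ITEMS) + sum(5 - likert[i] for i in EVEN_ITEMS)
    return 2.5 * total


def sus_grade(score: float) -> tuple[str, tuple[int, int]]:
    """Letter grade and percentile band for a SUS score.

    Bands: A >78.8; B 72.6–78.8; C 62.7–72.5; D 51.7–62.6; F ≤51.7 (bounds
    half-open so attainable scores — multiples of 2.5 — tile [0,100]).
    """
    if not (0 <= score <= 100):
        raise DomainError(f"SUS score {score} outside [0, 100]")
    for grade, lo, hi, pct in SUS_GRADE_BANDS:
        if score <= hi or grade == "A":
            if grade == "F" or score > lo:
                return grade, pct
    raise AssertionError("unreachable")  # pragma: no cover


def sus_percentile(score: float) -> int:
    """Percentile rank of a SUS score among tested systems, via the normal
    reference distribution (mean 68, SD 12.5): round(100*Phi((s-68)/12.5))."""
    if not (0 <= score <= 100):
        raise DomainError(f"SUS score {score} outside [0, 100]")
    z = (score - SUS_REFERENCE_MEAN) / SUS_REFERENCE_SD
    phi = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    return int(math.floor(100.0 * phi + 0.5))


# --- Vignette scoring ------------------------------------------------------

# The six scored items of every vignette.
SCORED_ITEMS = (
    "screening_start_age",
    "screening_modality",
    "first_interval",
    "subsequent_interval",
    "cessation_first",
    "cessation_subsequent",
)


@dataclass(frozen=True)
class ScoreWeights:
    """Per-item nonnegative integer weights; must sum to the 6-point vignette
    maximum.  Default: one point per item (the cessation question is posed
    once per intended procedure, hence two cessation items)."""

    weights: Mapping[str, int] = field(
        default_factory=lambda: {item: 1 for item in SCORED_ITEMS})

    def __post_init__(self):
        if set(self.weights) != set(SCORED_ITEMS):
            raise FormatError("weights must cover exactly the six scored items")
        if any(w < 0 for w in self.weights.values()):
            raise FormatError("weights must be nonnegative")
        if sum(self.weights.values()) != 6:
            raise FormatError("weights must sum to the 6-point vignette maximum")


VIGNETTE_IDS = ("alpha", "beta", "gamma", "theta", "delta", "omega")
VIGNETTE_PAIRS = (("alpha", "beta"), ("gamma", "theta"), ("delta", "omega"))


@dataclass(frozen=True)
class Vignette:
    """One clinical vignette: the case, its engine-derived answer key and the
    difficulty-matched pair it belongs to."""

    vignette_id: str
    case: PatientCase
    key: Mapping[str, object]
    pair_id: str


def _answers_match(item: str, given, expected) -> bool:
    if given is None:
        return False
    if item in ("first_interval", "subsequent_interval", "screening_start_age"):
        try:
            return int(given) == int(expected)
        except (TypeError, ValueError):
            return False
    if item in ("cessation_first", "cessation_subsequent"):
        if isinstance(given, str):
            given = {"true": True, "false": False,
                     "continue": True, "stop": False}.get(given.lower(), given)
        return bool(given) == bool(expected)
    return str(given) == str(expected)


def score_vignette(answers: Mapping[str, object], key: Mapping[str, object],
                   weights: ScoreWeights | None = None) -> int:
    """Sum of item weights over answers matching the key (0–6).

    Missing items score as wrong; unknown item names are a format error.
    """
    weights = weights or ScoreWeights()
    if not isinstance(answers, Mapping):
        raise FormatError("answers must be a mapping of item -> answer")
    unknown = set(answers) - set(SCORED_ITEMS)
    if unknown:
        raise FormatError(f"unknown answer items: {sorted(unknown)}")
    missing_key = set(SCORED_ITEMS) - set(key)
    if missing_key:
        raise FormatError(f"key missing items: {sorted(missing_key)}")
    return sum(weights.weights[item]
               for item in SCORED_ITEMS
               if _answers_match(item, answers.get(item), key[item]))


def score_section(vignette_scores: Sequence[int]) -> int:
    """Section total over exactly three vignettes (0–18)."""
    if len(vignette_scores) != 3:
        raise FormatError(f"a section comprises exactly 3 vignettes, "
                          f"got {len(vignette_scores)}")
    for s in vignette_scores:
        if not (0 <= s <= 6):
            raise FormatError(f"vignette score {s} outside [0, 6]")
    return int(sum(vignette_scores))


# --- Crossover combinations and randomization ------------------------------

# The eight vignette combinations of the crossover design: each pair
# contributes exactly one member per section.
QUIZ_COMBINATIONS = {
    1: (("alpha", "gamma", "delta"), ("beta", "theta", "omega")),
    2: (("alpha", "gamma", "omega"), ("beta", "theta", "delta")),
    3: (("alpha", "theta", "delta"), ("beta", "gamma", "omega")),
    4: (("alpha", "theta", "omega"), ("beta", "gamma", "delta")),
    5: (("beta", "gamma", "delta"), ("alpha", "theta", "omega")),
    6: (("beta", "gamma", "omega"), ("alpha", "theta", "delta")),
    7: (("beta", "theta", "delta"), ("alpha", "gamma", "omega")),
    8: (("beta", "theta", "omega"), ("alpha", "gamma", "delta")),
}


def build_quiz(combination: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Section-1 and section-2 vignette triples for a combination (1–8)."""
    if combination not in QUIZ_COMBINATIONS:
        raise DomainError(f"combination must be 1–8, got {combination}")
    return QUIZ_COMBINATIONS[combination]


@dataclass(frozen=True)
class Allocation:
    """One randomization slot: stratum (combination 1–8), group label and
    which aid is used first."""

    slot_id: str
    group: str  # specialist | nonspecialist
    combination: int
    first_tool: str  # DA | SR

    @property
    def sections(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return build_quiz(self.combination)


def generate_allocation_schedule(seed: int, per_stratum: int = 14,
                                 groups: Sequence[str] = ("specialist", "nonspecialist"),
                                 ) -> list[Allocation]:
    """Stratified crossover allocation schedule.

    For each group a randomly permuted schedule is generated over 8 strata
    (vignette combinations 1–8) with ``per_stratum`` slots per stratum and
    the first aid assigned 1:1 within each stratum (imbalance of exactly one
    when ``per_stratum`` is odd).  The default of 14 per stratum yields
    8 x 14 = 112 allocations per group-pair schedule request, split evenly
    between the two group schedules.  Deterministic in ``seed``; the multiset
    of (stratum, first_tool) slots is seed-independent, only order varies.
    """
    if per_stratum < 1:
        raise DomainError("per_stratum must be >= 1")
    rng = np.random.default_rng(seed)
    allocations: list[Allocation] = []
    # alternate groups across strata so each group schedule covers all strata
    for combination in range(1, 9):
        tools = ["DA"] * ((per_stratum + 1) // 2) + ["SR"] * (per_stratum // 2)
        order = rng.permutation(len(tools))
        for slot, idx in enumerate(order):
            group = groups[slot % len(groups)] if groups else "all"
            allocations.append(Allocation(
                slot_id=f"C{combination}-{slot + 1:02d}",
                group=group,
                combination=combination,
                first_tool=tools[idx],
            ))
    return allocations
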