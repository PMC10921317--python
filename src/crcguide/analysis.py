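"""Trial statistics and the synthetic participant simulator.

The statistical battery of the crossover evaluation: paired Wilcoxon
signed-rank comparison of concordance scores between the two aids,
Mann-Whitney U between specialist groups, Spearman correlation of usability
with performance, chi-square balance checks of the randomization,
Kolmogorov-Smirnov (Lilliefors) normality assessment, and the noncentral-t
sample-size calculation.  The simulator draws per-item Bernoulli concordance
with tool-specific probabilities so the whole pipeline runs with no external
participant data.

Small-sample signed-rank and rank-sum p-values are computed exactly (the
full sign/label permutation distribution, midranks for ties); larger samples
use the tie-corrected normal approximations from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import DegenerateDataError, DivergenceError, DomainError, FormatError
from .evaluation import (Allocation, ScoreWeights, SCORED_ITEMS, SUSResponse,
                         generate_allocation_schedule, sus_score)

EXACT_WILCOXON_MAX_N = 25
EXACT_MWU_MAX_N = 20  # pooled

SCORES_COLUMNS = ("participant_id", "group", "score_sr", "score_da", "sus",
                  "combination", "first_tool")


@dataclass
class AnalysisResult:
    """Container for one statistical comparison."""

    name: str
    n: int
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    medians: dict[str, float] = field(default_factory=dict)
    iqrs: dict[str, tuple[float, float]] = field(default_factory=dict)
    improvement_ratio: Optional[float] = None
    correlation: Optional[float] = None
    d_statistic: Optional[float] = None
    notes: dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"name": self.name, "n": self.n}
        for k in ("statistic", "p_value", "improvement_ratio", "correlation",
                  "d_statistic"):
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v)
        if self.medians:
            out["medians"] = {k: float(v) for k, v in self.medians.items()}
        if self.iqrs:
            out["iqrs"] = {k: [float(a), float(b)] for k, (a, b) in self.iqrs.items()}
        if self.notes:
            out["notes"] = self.notes
        return out


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    # linear interpolation between order statistics (the convention that
    # yields quartiles like 7.75 on integer scores at n=80)
    q1, q2, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(q2), (float(q1), float(q3))


# ---------------------------------------------------------------------------
# Exact rank-test machinery

def _signed_rank_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign assignments, midranks
    for tied |differences|.  Returns (W, p)."""
    ranks = stats.rankdata(np.abs(diffs))
    r2 = np.rint(ranks * 2).astype(int)  # doubled midranks are integers
    w2 = int(r2[diffs > 0].sum())
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = dist + shifted
    dist /= dist.sum()
    mu = total / 2.0
    dev = abs(w2 - mu)
    support = np.arange(total + 1)
    p = float(dist[np.abs(support - mu) >= dev - 1e-9].sum())
    return float(w2 / 2.0), min(1.0, p)


def _mwu_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by exhaustive label enumeration over
    the pooled midranks.  Returns (U of the first sample, p)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n = len(a), len(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mu)
    hits = 0
    count = 0
    base = n1 * (n1 + 1) / 2.0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - base
        count += 1
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return u_obs, hits / count


# ---------------------------------------------------------------------------
# The battery

def paired_compare(scores, name: str = "SR_vs_DA") -> AnalysisResult:
    """Related-samples Wilcoxon signed-rank comparison of the two aids.

    ``scores`` is a DataFrame with ``score_sr``/``score_da`` columns (or any
    mapping providing them).  Zero differences are dropped (signed-rank
    convention) and their count reported; the p-value is exact for <= 25
    remaining pairs, otherwise the tie-corrected normal approximation.  The
    improvement ratio is the ratio of median scores (reported in trial
    summaries as a relative risk).
    """
    sr = np.asarray(scores["score_sr"], dtype=float)
    da = np.asarray(scores["score_da"], dtype=float)
    if len(sr) != len(da) or len(sr) < 2:
        raise FormatError("paired comparison needs >= 2 participants with both scores")
    med_sr, iqr_sr = _median_iqr(sr)
    med_da, iqr_da = _median_iqr(da)
    result = AnalysisResult(
        name=name, n=len(sr),
        medians={"SR": med_sr, "DA": med_da},
        iqrs={"SR": iqr_sr, "DA": iqr_da},
        improvement_ratio=(med_da / med_sr) if med_sr > 0 else None,
    )
    diffs = da - sr
    nz = diffs[diffs != 0]
    result.notes["zeros_dropped"] = int(len(diffs) - len(nz))
    if len(nz) == 0:
        result.statistic = 0.0
        result.p_value = 1.0
        result.notes["degenerate"] = "all paired differences are zero"
        return result
    if len(nz) <= EXACT_WILCOXON_MAX_N:
        result.statistic, result.p_value = _signed_rank_exact_p(nz)
        result.notes["method"] = "exact"
    else:
        w = stats.wilcoxon(da, sr, zero_method="wilcox", correction=False,
                           method="approx", alternative="two-sided")
        result.statistic, result.p_value = float(w.statistic), float(w.pvalue)
        result.notes["method"] = "normal approximation, tie-corrected"
    return result


def group_compare(a: Sequence[float], b: Sequence[float],
                  name: str = "specialist_vs_nonspecialist") -> AnalysisResult:
    """Independent-samples Mann-Whitney U comparison of two groups.

    Exact label-permutation p for pooled n <= 20, otherwise the
    tie-corrected asymptotic p.  The statistic is U of the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise FormatError("both groups must be non-empty")
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    result = AnalysisResult(name=name, n=len(a) + len(b),
                            medians={"a": med_a, "b": med_b},
                            iqrs={"a": iqr_a, "b": iqr_b})
    if len(a) + len(b) <= EXACT_MWU_MAX_N:
        result.statistic, result.p_value = _mwu_exact_p(a, b)
        result.notes["method"] = "exact"
    else:
        r = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        result.statistic, result.p_value = float(r.statistic), float(r.pvalue)
        result.notes["method"] = "normal approximation, tie-corrected"
    return result


def usability_correlation(sus: Sequence[float], da_scores: Sequence[float],
                          name: str = "usability_vs_DA_score") -> AnalysisResult:
    """Spearman rank correlation (average ranks for ties) between usability
    and performance with the application; two-sided p."""
    sus = np.asarray(sus, dtype=float)
    da = np.asarray(da_scores, dtype=float)
    if len(sus) != len(da) or len(sus) < 3:
        raise FormatError("correlation needs >= 3 paired observations")
    result = AnalysisResult(name=name, n=len(sus))
    if np.all(sus == sus[0]) or np.all(da == da[0]):
        result.notes["degenerate"] = "constant vector: correlation undefined"
        return result
    rho, p = stats.spearmanr(sus, da)
    result.correlation, result.p_value = float(rho), float(p)
    return result


def allocation_contingency(allocations: Sequence[Allocation],
                           pair_index: int = 0) -> pd.DataFrame:
    """Tool-order x vignette-order contingency table of a schedule: which aid
    is used first against which member of a vignette pair appears first."""
    from .evaluation import VIGNETTE_PAIRS, build_quiz
    pair = VIGNETTE_PAIRS[pair_index]
    rows = []
    for a in allocations:
        section1, _ = build_quiz(a.combination)
        first_member = pair[0] if pair[0] in section1 else pair[1]
        rows.append((a.first_tool, first_member))
    df = pd.DataFrame(rows, columns=["first_tool", "first_vignette"])
    return pd.crosstab(df["first_tool"], df["first_vignette"])


def balance_check(table, name: str = "allocation_balance") -> AnalysisResult:
    """Pearson chi-square test of independence on a contingency table
    (sum over cells of (O-E)^2/E, no continuity correction).

    ``table`` is a 2-D array/DataFrame of counts, or a sequence of
    :class:`Allocation` from which the tool-order x vignette-order table is
    built.
    """
    if len(table) and isinstance(next(iter(table), None), Allocation):
        table = allocation_contingency(table)
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise DegenerateDataError("contingency table needs >= 2 categories per factor")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateDataError("contingency table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return AnalysisResult(name=name, n=int(obs.sum()), statistic=float(chi2),
                          p_value=float(p), notes={"dof": int(dof)})


def normality(scores: Sequence[float], name: str = "normality") -> AnalysisResult:
    """Kolmogorov-Smirnov normality assessment against a normal with the
    sample mean and SD.

    D = max |ECDF - fitted normal CDF|; the p-value uses the Lilliefors
    correction for estimated parameters, with the plain (uncorrected) KS p
    also reported since it is the optimistic bound.
    """
    x = np.sort(np.asarray(scores, dtype=float))
    n = len(x)
    if n < 5:
        raise FormatError("normality assessment needs n >= 5")
    if np.all(x == x[0]):
        raise DegenerateDataError("constant sample: normality undefined")
    mean, sd = x.mean(), x.std(ddof=1)
    cdf = stats.norm.cdf(x, loc=mean, scale=sd)
    i = np.arange(1, n + 1)
    d = float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))
    _, p_lillie = lilliefors(x, dist="norm", pvalmethod="table")
    p_plain = float(stats.kstest(x, "norm", args=(mean, sd)).pvalue)
    return AnalysisResult(name=name, n=n, d_statistic=d, p_value=float(p_lillie),
                          notes={"p_plain_ks": p_plain, "mean": float(mean),
                                 "sd": float(sd)})


# ---------------------------------------------------------------------------
# Power

@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test power specification on the percent-accuracy scale."""

    mean0: float = 60.0
    mean1: float = 70.0
    sd: float = 20.0
    alpha: float = 0.05
    power: float = 0.8
    ratio: float = 1.0  # n2 / n1

    def __post_init__(self):
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise DomainError("alpha and power must lie in (0, 1)")
        if self.sd <= 0 or self.ratio <= 0:
            raise DomainError("sd and allocation ratio must be positive")

    @property
    def effect_size(self) -> float:
        return abs(self.mean1 - self.mean0) / self.sd


def _two_sample_power(n1: int, d: float, alpha: float, ratio: float) -> float:
    n2 = max(2, int(round(n1 * ratio)))
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest per-group n reaching the target power for a two-sided
    two-sample t test at effect size (mean1-mean0)/sd, by noncentral-t
    iteration over integer n."""
    d = spec.effect_size
    if d == 0:
        raise DivergenceError("zero effect size: the target power is unreachable")
    for n1 in range(2, 1_000_001):
        if _two_sample_power(n1, d, spec.alpha, spec.ratio) >= spec.power:
            return n1
    raise DivergenceError("sample size search did not converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# Simulator

@dataclass(frozen=True)
class SimulationSpec:
    """Synthetic trial conditions.

    Defaults emulate the study setting: 80 analysed participants, per-item
    guideline-concordance probabilities 10/18 with the standard resource and
    14/18 with the application (so expected section scores of 10 and 14 out
    of 18), a specialist fraction of 37/80, and favourable usability-slider
    responses (positively worded items near 85/100).
    """

    n: int = 80
    p_sr: float = 10.0 / 18.0
    p_da: float = 14.0 / 18.0
    specialist_fraction: float = 37.0 / 80.0
    sus_pos_mean: float = 85.0
    sus_slider_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_sr, self.p_da, self.specialist_fraction):
            if not (0 <= p <= 1):
                raise DomainError(f"probability {p} outside [0, 1]")
        if self.n < 1:
            raise DomainError("n must be >= 1")


@dataclass
class SimulatedTrial:
    scores: pd.DataFrame
    allocations: list[Allocation]
    sus_responses: list[SUSResponse]


def simulate_trial(spec: SimulationSpec,
                   weights: ScoreWeights | None = None) -> SimulatedTrial:
    """Draw a synthetic participant dataset.

    Allocations come from the stratified schedule generator (round-robin
    across strata so any n covers the strata evenly); each section score is
    the weighted sum of independent per-item Bernoulli concordance draws
    (18 score points per section) with the tool-specific probability; SUS
    sliders are truncated-normal around the favourable/unfavourable anchors.
    Bit-exactly reproducible from ``spec.seed``.
    """
    weights = weights or ScoreWeights()
    item_weights = [weights.weights[i] for i in SCORED_ITEMS] * 3  # 3 vignettes
    rng = np.random.default_rng(spec.seed)
    per_stratum = max(1, math.ceil(spec.n / 8))
    schedule = generate_allocation_schedule(spec.seed, per_stratum=per_stratum)
    # round-robin across strata so truncation at n keeps strata balanced
    schedule = sorted(schedule, key=lambda a: (a.slot_id.split("-")[1], a.combination))
    allocations = schedule[: spec.n]

    n_spec = int(round(spec.n * spec.specialist_fraction))
    group_labels = np.array(["specialist"] * n_spec
                            + ["nonspecialist"] * (spec.n - n_spec))
    rng.shuffle(group_labels)

    rows = []
    sus_responses = []
    for i, alloc in enumerate(allocations):
        score_sr = int(sum(w for w in item_weights if rng.random() < spec.p_sr))
        score_da = int(sum(w for w in item_weights if rng.random() < spec.p_da))
        sliders = []
        for q in range(10):
            anchor = spec.sus_pos_mean if q % 2 == 0 else 100.0 - spec.sus_pos_mean
            sliders.append(float(np.clip(rng.normal(anchor, spec.sus_slider_sd),
                                         0.0, 100.0)))
        resp = SUSResponse(tuple(sliders))
        sus_responses.append(resp)
        rows.append({
            "participant_id": f"P{i + 1:03d}",
            "group": group_labels[i],
            "score_sr": score_sr,
            "score_da": score_da,
            "sus": sus_score(resp),
            "combination": alloc.combination,
            "first_tool": alloc.first_tool,
        })
    return SimulatedTrial(scores=pd.DataFrame(rows, columns=list(SCORES_COLUMNS)),
                          allocations=allocations, sus_responses=sus_responses)


# ---------------------------------------------------------------------------
# Tabular IO

def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCORES_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise FormatError(f"scores file missing columns: {sorted(missing)}")
    return df


def write_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
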