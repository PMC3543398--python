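"""Group-level time-course analysis of repeated MMSE assessments.

First-round analysis: test whether scores change across assessment
occasions (Friedman's test on within-patient ranks, post-hoc Wilcoxon
signed-rank pairs) and summarize the group recovery curve by ordinary
least squares of score on ln(day) or day, reported with R-squared.

The rank tests are authored here because the analysis contract pins the
exact conventions: average ranks for ties, zero differences dropped, the
signed-rank statistic reported as min(W+, W-), an exact null distribution
for small samples (computed by convolution over sign assignments, valid
with tied ranks), and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .models import AssessmentSeries, ModelKind

WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    pvalue: float


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    pvalue: float
    n_used: int  # pairs remaining after dropping zero differences
    degenerate: bool = False  # all differences were zero


@dataclass(frozen=True)
class CurveFit:
    kind: ModelKind
    intercept_a: float
    slope_b: float
    r_squared: float


class OccasionMatrix:
    """Complete patient-by-occasion grid of scores and assessment days."""

    def __init__(
        self,
        patients: Sequence[str],
        occasions: Sequence[str],
        scores: np.ndarray,
        days: np.ndarray,
    ):
        scores = np.asarray(scores, dtype=float)
        days = np.asarray(days, dtype=float)
        n, k = len(patients), len(occasions)
        if scores.shape != (n, k) or days.shape != (n, k):
            raise ValueError(
                f"grid must be complete: expected shape {(n, k)}, "
                f"got scores {scores.shape}, days {days.shape}"
            )
        if np.isnan(scores).any() or np.isnan(days).any():
            raise ValueError("grid must be complete (no missing cells)")
        if (np.diff(days, axis=1) <= 0).any():
            raise ValueError("each patient's days must be strictly increasing")
        self.patients = list(patients)
        self.occasions = list(occasions)
        self.scores = scores
        self.days = days

    @classmethod
    def from_cohort(cls, cohort: Sequence[AssessmentSeries]) -> "OccasionMatrix":
        lengths = {len(s) for s in cohort}
        if len(lengths) != 1:
            raise ValueError(
                f"all series must have the same number of occasions, got {sorted(lengths)}"
            )
        k = lengths.pop()
        return cls(
            patients=[s.patient_id for s in cohort],
            occasions=[f"occasion_{j + 1}" for j in range(k)],
            scores=np.array([s.scores for s in cohort], dtype=float),
            days=np.array([s.days for s in cohort], dtype=float),
        )


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of a 1-D array."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def friedman_test(m) -> FriedmanResult:
    """Friedman's rank test across assessment occasions.

    Scores are ranked within each patient with average ranks for ties; the
    chi-square statistic (with the standard tie correction) is referred to
    a chi-square distribution with (occasions - 1) degrees of freedom.
    A grid with no rank variation at all (every patient constant) carries
    no evidence: statistic 0, p = 1.
    """
    scores = m.scores if isinstance(m, OccasionMatrix) else np.asarray(m, dtype=float)
    if scores.ndim != 2:
        raise ValueError("expected a patient-by-occasion grid")
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >=2 patients and >=2 occasions, got {n}x{k}")
    if np.isnan(scores).any():
        raise ValueError("grid must be complete (no missing cells)")

    ranks = stats.rankdata(scores, axis=1)
    col_sums = ranks.sum(axis=0)
    statistic = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)

    ties = sum(_tie_term(row) for row in scores)
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction <= 0:
        return FriedmanResult(statistic=0.0, pvalue=1.0)
    statistic /= correction
    pvalue = float(stats.chi2.sf(statistic, df=k - 1))
    return FriedmanResult(statistic=float(statistic), pvalue=pvalue)


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ by convolution over independent sign flips.

    Ranks are multiples of 1/2 (average ranks), so doubling puts the
    statistic on an integer lattice; entry ``s`` of the result is
    P(2*W+ = s) under the exchangeable-signs null.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt / 2.0
    return dist


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped; absolute differences receive average
    ranks; the reported statistic is min(W+, W-).  The p-value is exact
    (convolution over all sign assignments) for up to 25 informative pairs
    and a tie-corrected normal approximation beyond that.  If every
    difference is zero the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D arrays with >=1 pair")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0, degenerate=True)

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    if n <= WILCOXON_EXACT_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_distribution(doubled)
        w2 = int(round(2 * w_plus))
        cdf = float(dist[: w2 + 1].sum())
        sf = float(dist[w2:].sum())
        pvalue = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n * (n + 1) / 4.0
        tie_sum = _tie_term(np.abs(d))
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_sum / 48.0
        z = (w_plus - mu) / math.sqrt(sigma2)
        pvalue = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(statistic=statistic, pvalue=pvalue, n_used=n)


def fit_group_curve(
    cohort: Sequence[AssessmentSeries],
    kind: ModelKind,
    mode: str = "occasion_summary",
) -> CurveFit:
    """OLS of MMSE score on ln(day) or day across the cohort.

    ``occasion_summary`` (default) regresses the per-occasion mean score on
    the per-occasion mean day — the group recovery curve through the
    occasion summaries.  ``pooled`` regresses every observation on its own
    day, a sensitivity variant dominated by between-patient spread.
    """
    kind = ModelKind(kind)
    if mode not in ("pooled", "occasion_summary"):
        raise ValueError(f"mode must be 'pooled' or 'occasion_summary', got {mode!r}")

    if mode == "pooled":
        days = np.array([o.day for s in cohort for o in s.observations], dtype=float)
        scores = np.array([o.score for s in cohort for o in s.observations], dtype=float)
    else:
        m = OccasionMatrix.from_cohort(cohort)
        days = m.days.mean(axis=0)
        scores = m.scores.mean(axis=0)

    if len(np.unique(days)) < 2:
        raise ValueError("need >=2 distinct day values to fit a curve")
    x = np.log(days) if kind is ModelKind.LOGARITHMIC else days
    if np.ptp(x) == 0:
        raise ValueError("regressor has zero variance")
    res = stats.linregress(x, scores)
    return CurveFit(
        kind=kind,
        intercept_a=float(res.intercept),
        slope_b=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


@dataclass
class GroupRecoveryReport:
    """Friedman/post-hoc results plus group curve fits and occasion summaries."""

    n_patients: int
    occasions: List[str]
    friedman_stat: float
    friedman_p: float
    pairwise: List[dict]
    fits: Dict[str, CurveFit]
    occasion_summary: List[dict]
    mode: str
    bonferroni: bool

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "occasions": self.occasions,
            "friedman_stat": self.friedman_stat,
            "friedman_p": self.friedman_p,
            "pairwise": self.pairwise,
            "fits": {
                k: {
                    "a": f.intercept_a,
                    "b": f.slope_b,
                    "r_squared": f.r_squared,
                }
                for k, f in self.fits.items()
            },
            "occasion_summary": self.occasion_summary,
            "mode": self.mode,
            "bonferroni": self.bonferroni,
        }

    def to_text(self) -> str:
        lines = [
            f"Group recovery analysis ({self.n_patients} patients, "
            f"{len(self.occasions)} occasions)",
            "",
            f"{'occasion':<12}{'mean day':>10}{'median':>8}{'IQR':>12}",
        ]
        for row in self.occasion_summary:
            iqr = f"{row['q1']:.0f}-{row['q3']:.0f}"
            lines.append(
                f"{row['occasion']:<12}{row['mean_day']:>10.1f}"
                f"{row['median']:>8.1f}{iqr:>12}"
            )
        lines.append("")
        lines.append(
            f"Friedman chi-square = {self.friedman_stat:.4g}, p = {self.friedman_p:.4g}"
        )
        for pair in self.pairwise:
            lines.append(
                f"Wilcoxon {pair['occasions'][0]} vs {pair['occasions'][1]}: "
                f"W = {pair['statistic']:.4g}, p = {pair['pvalue']:.4g}"
            )
        lines.append("")
        for kind, f in self.fits.items():
            lines.append(
                f"{kind} fit ({self.mode}): a = {f.intercept_a:.4g}, "
                f"b = {f.slope_b:.4g}, R^2 = {f.r_squared:.4g}"
            )
        return "\n".join(lines)


def analyze_group(
    cohort: Sequence[AssessmentSeries],
    mode: str = "occasion_summary",
    bonferroni: bool = False,
) -> GroupRecoveryReport:
    """Run the full first-round analysis on a cohort.

    Post-hoc Wilcoxon tests compare each later occasion against baseline
    (the study's post-hoc question); p-values are reported unadjusted
    unless ``bonferroni`` is set.
    """
    m = OccasionMatrix.from_cohort(cohort)
    fr = friedman_test(m)

    k = len(m.occasions)
    n_pairs = k - 1
    pairwise = []
    for j in range(1, k):
        res = wilcoxon_signed_rank(m.scores[:, j], m.scores[:, 0])
        p = min(1.0, res.pvalue * n_pairs) if bonferroni else res.pvalue
        pairwise.append(
            {
                "occasions": [m.occasions[0], m.occasions[j]],
                "statistic": res.statistic,
                "pvalue": p,
                "degenerate": res.degenerate,
            }
        )

    fits = {
        kind.value: fit_group_curve(cohort, kind, mode=mode)
        for kind in (ModelKind.LOGARITHMIC, ModelKind.LINEAR)
    }
    summary = []
    for j, label in enumerate(m.occasions):
        col = m.scores[:, j]
        summary.append(
            {
                "occasion": label,
                "mean_day": float(m.days[:, j].mean()),
                "median": float(np.median(col)),
                "q1": float(np.percentile(col, 25)),
                "q3": float(np.percentile(col, 75)),
            }
        )
    return GroupRecoveryReport(
        n_patients=len(m.patients),
        occasions=m.occasions,
        friedman_stat=fr.statistic,
        friedman_p=fr.pvalue,
        pairwise=pairwise,
        fits=fits,
        occasion_summary=summary,
        mode=mode,
        bonferroni=bonferroni,
    )
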