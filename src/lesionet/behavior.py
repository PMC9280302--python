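"""Behavioral scores with their eligibility filters.

Covers the standard rodent battery: spontaneous alternation in a Y-maze
(working memory), novel-arm time in a two-trial Y-maze (spatial recognition),
novel-object discrimination index (visual recognition), open-arm time in an
elevated plus maze (anxiety-like behavior), plus the distribution-gated
two-group comparison used for all of them.

Alternation scoring: a visit scores as an alternation when the animal enters
the least recently visited of the three arms; the score is
``100 * alternations / (n_visits - 2)``.  A never-visited arm counts as least
recently visited (visit time -inf); at most one arm is unvisited from visit 3
on, so no tie-break beyond that is needed.  Scores are computed only for
animals making strictly more than 15 arm visits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedScoreError, ValidationError

MIN_VISITS_FOR_ALTERNATION = 15  # eligibility: strictly more than this
MIN_SAMPLE_EXPLORATION_S = 10.0  # eligibility: at least this (inclusive)


@dataclass
class VisitSequence:
    """Timestamped Y-maze arm entries for one subject.

    Timestamps strictly increase and consecutive arms differ (an entry is
    counted only when the animal moves into a *new* arm).
    """

    subject_id: str
    visits: list[tuple[float, str]]  # (t_s, arm)

    def __post_init__(self) -> None:
        for i in range(1, len(self.visits)):
            if self.visits[i][0] <= self.visits[i - 1][0]:
                raise ValidationError(
                    f"subject {self.subject_id!r}: timestamps must strictly increase "
                    f"(visit {i + 1})"
                )
            if self.visits[i][1] == self.visits[i - 1][1]:
                raise ValidationError(
                    f"subject {self.subject_id!r}: consecutive visits to the same arm "
                    f"(visit {i + 1}, arm {self.visits[i][1]!r})"
                )

    @property
    def arms(self) -> list[str]:
        return [a for _, a in self.visits]

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class ArmTimeBudget:
    """Seconds spent per arm in the test trial of the spatial Y-maze."""

    subject_id: str
    start_s: float
    novel_s: float
    other_s: float

    def __post_init__(self) -> None:
        for name in ("start_s", "novel_s", "other_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"subject {self.subject_id!r}: {name} must be >= 0")


@dataclass
class ExplorationTrial:
    """Object-exploration durations for one novel-object-recognition session."""

    subject_id: str
    sample_total_s: float
    test_novel_s: float
    test_familiar_s: float

    def __post_init__(self) -> None:
        for name in ("sample_total_s", "test_novel_s", "test_familiar_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"subject {self.subject_id!r}: {name} must be >= 0")


def alternation_score(seq: VisitSequence) -> float:
    """Spontaneous alternation score in percent.

    Scans visits 3..n; an alternation is an entry into the arm whose last
    visit is oldest (never visited = -inf).  Returns
    ``100 * alternations / (n - 2)``.
    """
    arms = seq.arms
    n = len(arms)
    if n < 3:
        raise UndefinedScoreError(
            f"subject {seq.subject_id!r}: alternation score needs >= 3 visits, got {n}"
        )
    arm_set = sorted(set(arms))
    if len(arm_set) > 3:
        raise ValidationError(
            f"subject {seq.subject_id!r}: more than 3 distinct arms: {arm_set}"
        )
    # With < 3 distinct arms observed, the unvisited arm(s) stay at -inf.
    all_arms = arm_set + [f"__unseen_{i}" for i in range(3 - len(arm_set))]
    last_visit: dict[str, float] = {a: -math.inf for a in all_arms}
    alternations = 0
    last_visit[arms[0]] = 0
    last_visit[arms[1]] = 1
    for i in range(2, n):
        least_recent = min(last_visit, key=lambda a: last_visit[a])
        if arms[i] == least_recent:
            alternations += 1
        last_visit[arms[i]] = i
    return 100.0 * alternations / (n - 2)


def alternation_eligible(seq: VisitSequence) -> bool:
    """True iff the animal made strictly more than 15 arm visits."""
    return seq.n_visits > MIN_VISITS_FOR_ALTERNATION


def novel_arm_percent(budget: ArmTimeBudget, denominator: str = "all_three") -> float:
    """Percentage of trial time spent in the novel arm.

    ``denominator`` selects the normalization: ``"all_three"`` (default)
    divides by time in all three arms; ``"other_two"`` divides by time in the
    start + other arms only (an alternative reading of the same ratio, in
    which case the result may exceed 100).
    """
    total = budget.start_s + budget.novel_s + budget.other_s
    if total <= 0:
        raise UndefinedScoreError(
            f"subject {budget.subject_id!r}: no arm time recorded"
        )
    if denominator == "all_three":
        return 100.0 * budget.novel_s / total
    if denominator == "other_two":
        other = budget.start_s + budget.other_s
        if other <= 0:
            raise UndefinedScoreError(
                f"subject {budget.subject_id!r}: zero time in start+other arms"
            )
        return 100.0 * budget.novel_s / other
    raise ValidationError(f"unknown denominator {denominator!r}")


def discrimination_index(trial: ExplorationTrial) -> float:
    """(novel - familiar) / (novel + familiar) exploration time, in [-1, 1]."""
    total = trial.test_novel_s + trial.test_familiar_s
    if total <= 0:
        raise UndefinedScoreError(
            f"subject {trial.subject_id!r}: zero test-phase exploration"
        )
    return (trial.test_novel_s - trial.test_familiar_s) / total


def exploration_eligible(trial: ExplorationTrial) -> bool:
    """True iff the sample phase reached at least 10 s of exploration."""
    return trial.sample_total_s >= MIN_SAMPLE_EXPLORATION_S


def open_arm_percent(open_s: float, total_s: float) -> float:
    """Percentage of session time spent in the open arms of the plus maze."""
    if total_s <= 0:
        raise ValidationError("total_s must be > 0")
    if open_s < 0:
        raise ValidationError("open_s must be >= 0")
    if open_s > total_s:
        raise ValidationError(f"open_s ({open_s}) exceeds total_s ({total_s})")
    return 100.0 * open_s / total_s


def _ks_normal(x: np.ndarray, alpha: float) -> bool:
    """Plain KS test against a normal fitted to the sample.

    Parameters are estimated from the sample itself (no Lilliefors
    correction), which makes the gate conservative: it under-rejects
    normality.  A zero-variance sample is treated as non-normal.
    """
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return False
    p = stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue
    return p >= alpha


def group_compare(a, b, alpha: float = 0.05) -> tuple[str, float, float]:
    """Two-group comparison with a normality-gated test choice.

    Both samples are screened with a Kolmogorov-Smirnov test against a fitted
    normal; if both pass at ``alpha`` a two-sided equal-variance Student
    t-test is used, otherwise a two-sided Mann-Whitney U.  Returns
    ``(test_name, statistic, p)`` with test_name in {"t", "mannwhitney"}.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"group_compare needs >= 3 values per group, got {a.size} and {b.size}"
        )
    if _ks_normal(a, alpha) and _ks_normal(b, alpha):
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            return ("t", 0.0, 1.0)
        res = stats.ttest_ind(a, b, equal_var=True)
        return ("t", float(res.statistic), float(res.pvalue))
    if np.array_equal(np.sort(a), np.sort(b)):
        # identical samples: U test p is exactly 1 under tie handling
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ("mannwhitney", float(res.statistic), 1.0)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ("mannwhitney", float(res.statistic), float(res.pvalue))


def paired_compare(diffs, alpha: float = 0.05) -> tuple[str, float, float]:
    """Same distribution-gated logic applied to paired differences.

    Normal-looking differences get a one-sample t-test against zero (the
    paired t-test), otherwise a Wilcoxon signed-rank test.  All-zero
    differences are a degenerate identity course: statistic 0, p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 3:
        raise InsufficientDataError(
            f"paired_compare needs >= 3 paired differences, got {d.size}"
        )
    if np.all(d == 0):
        return ("paired_t", 0.0, 1.0)
    if _ks_normal(d, alpha):
        res = stats.ttest_1samp(d, 0.0)
        return ("paired_t", float(res.statistic), float(res.pvalue))
    res = stats.wilcoxon(d)
    return ("wilcoxon", float(res.statistic), float(res.pvalue))
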