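"""System Usability Scale scoring, item benchmarks and grading.

The SUS is a 10-item usability questionnaire on a 1-5 Likert scale. A
respondent's score is the standard Brooke transform: odd (positively
phrased) items contribute value - 1, even (negatively phrased) items
contribute 5 - value, and the sum is scaled by 2.5 onto 0-100. Because
the transform is affine in the items, the mean score of a group equals
the transform applied to the per-item means — this identity is exact and
is relied on when only item-level means are available.

Item-level results are tested against the published per-item benchmark
means (Sauro & Lewis): odd items should exceed their benchmark, even
items should fall below it, both as strict inequalities. The total score
is graded on Bangor's adjective scale and the Sauro-Lewis curved letter
grading, whose published band edges are stored as package data; 68 is the
published all-studies average and serves as the above-average threshold.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import yaml

from .accuracy import round_half_up
from .markers import UNDEFINED, Undefined, is_defined
from .records import SUSResponseSet

__all__ = [
    "SUS_ITEM_BENCHMARKS",
    "Grade",
    "SUSReport",
    "score_respondent",
    "transform_item_means",
    "summarize",
    "benchmark_items",
    "grade",
]

#: published per-item benchmark means (Sauro & Lewis), items 1..10
SUS_ITEM_BENCHMARKS = (3.39, 2.44, 3.67, 1.85, 3.55, 2.20, 3.71, 2.25, 3.72, 2.09)

_ODD = tuple(range(0, 10, 2))  # 0-based indices of items 1,3,5,7,9
_EVEN = tuple(range(1, 10, 2))


def _load_bands() -> dict:
    text = (
        importlib.resources.files("scs_triage")
        .joinpath("data", "grade_bands.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


_BANDS = _load_bands()


def score_respondent(items: Sequence[int]) -> float:
    """Score one respondent's 10 Likert answers onto 0-100."""
    if len(items) != 10:
        raise ValueError("a SUS response has exactly 10 items")
    for i, v in enumerate(items, start=1):
        if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
            raise ValueError(f"item_{i}: response {v!r} outside the 1-5 scale")
    arr = np.asarray(items, dtype=float)
    return float(2.5 * ((arr[list(_ODD)] - 1).sum() + (5 - arr[list(_EVEN)]).sum()))


def transform_item_means(item_means: Sequence[float]) -> float:
    """Apply the SUS transform to per-item means.

    Exactly equals the mean per-respondent score (the transform is affine).
    """
    arr = np.asarray(item_means, dtype=float)
    if arr.shape != (10,):
        raise ValueError("expected 10 item means")
    return float(2.5 * ((arr[list(_ODD)] - 1).sum() + (5 - arr[list(_EVEN)]).sum()))


@dataclass(frozen=True)
class Grade:
    adjective: str
    letter: str
    above_average: bool


def grade(score: float) -> Grade:
    """Adjective (Bangor) and curved letter grade (Sauro-Lewis) of a score."""
    if not 0 <= score <= 100:
        raise ValueError(f"SUS score {score} outside [0, 100]")
    letter = next(
        band["letter"]
        for band in _BANDS["letter_bands"]
        if score <= band["upper"] + 1e-9
    )
    adjective = min(
        _BANDS["adjective_anchors"], key=lambda a: abs(a["score"] - score)
    )["adjective"]
    return Grade(
        adjective=adjective,
        letter=letter,
        above_average=score >= _BANDS["average_threshold"],
    )


def benchmark_items(
    item_means: Sequence[float],
    benchmarks: Sequence[float] = SUS_ITEM_BENCHMARKS,
) -> list[bool]:
    """Per-item benchmark verdicts, strict inequalities.

    Odd items pass iff mean > benchmark; even items pass iff mean <
    benchmark (even items are negatively phrased, lower is better).
    """
    means = np.asarray(item_means, dtype=float)
    bench = np.asarray(benchmarks, dtype=float)
    if means.shape != (10,) or bench.shape != (10,):
        raise ValueError("expected 10 item means and 10 benchmarks")
    return [
        bool(means[i] > bench[i]) if i in _ODD else bool(means[i] < bench[i])
        for i in range(10)
    ]


@dataclass(frozen=True)
class SUSReport:
    """Group-level SUS summary."""

    scores: tuple[float, ...]
    mean: float
    sd: Union[float, Undefined]
    item_means: tuple[float, ...]
    benchmark_pass: tuple[bool, ...]
    grade: Grade

    @property
    def n_respondents(self) -> int:
        return len(self.scores)

    def to_json(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "mean": self.mean,
            "mean_rounded": round_half_up(self.mean, 1),
            "sd": self.sd if is_defined(self.sd) else "undefined",
            "scores": list(self.scores),
            "item_means": list(self.item_means),
            "item_benchmarks": list(SUS_ITEM_BENCHMARKS),
            "benchmark_pass": list(self.benchmark_pass),
            "grade": {
                "adjective": self.grade.adjective,
                "letter": self.grade.letter,
                "above_average": self.grade.above_average,
            },
        }


def summarize(responses: SUSResponseSet) -> SUSReport:
    """Score every respondent and summarise the group.

    The standard deviation uses the sample (n - 1) convention and is the
    undefined marker for a single respondent.
    """
    if responses.n_respondents < 1:
        raise ValueError("at least one respondent is required")
    scores = tuple(
        score_respondent(list(row))
        for row in responses.responses.itertuples(index=False)
    )
    item_means = tuple(float(v) for v in responses.item_means())
    sd: Union[float, Undefined]
    if len(scores) > 1:
        sd = float(np.std(scores, ddof=1))
    else:
        sd = UNDEFINED
    mean = float(np.mean(scores))
    return SUSReport(
        scores=scores,
        mean=mean,
        sd=sd,
        item_means=item_means,
        benchmark_pass=tuple(benchmark_items(item_means)),
        grade=grade(mean),
    )
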