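"""Inter- and intra-rater reliability for binary eligibility calls.

Implements Cohen's kappa (two raters, chance correction from the raters'
own marginals), Fleiss' kappa (multiple raters, pooled marginals; equal to
Scott's pi for two raters), and the overall/positive/negative specific
agreement proportions of de Vet and colleagues. Kappa values at or above
0.70 are flagged reliable, the conventional threshold for evaluative use.

Degenerate inputs: when the expected agreement p_e equals 1 (every call in
one category), observed agreement is necessarily 1 as well and kappa is
defined as 1. Specific-agreement components with an empty denominator are
reported as the explicit undefined marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Union

import numpy as np
import pandas as pd

from .markers import UNDEFINED, Undefined, is_defined
from .records import RatingMatrix

__all__ = [
    "RELIABILITY_THRESHOLD",
    "PairCounts",
    "SpecificAgreement",
    "AgreementReport",
    "pair_counts",
    "cohen_kappa",
    "fleiss_kappa",
    "specific_agreement",
    "intra_rater",
    "agreement_report",
]

#: kappa at or above this value is considered reliable
RELIABILITY_THRESHOLD = 0.70

Value = Union[float, Undefined]


@dataclass(frozen=True)
class PairCounts:
    """Paired 2x2 cross-counts: a=both positive, d=both negative."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _as_binary(vec, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-d vector")
    if not np.isin(arr, (0, 1, True, False)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(int)


def pair_counts(ratings_a, ratings_b) -> PairCounts:
    """Cross-tabulate two raters' calls on the same subjects."""
    a = _as_binary(ratings_a, "ratings_a")
    b = _as_binary(ratings_b, "ratings_b")
    if a.size != b.size:
        raise ValueError(
            f"rating vectors differ in length ({a.size} vs {b.size})"
        )
    return PairCounts(
        a=int(((a == 1) & (b == 1)).sum()),
        b=int(((a == 1) & (b == 0)).sum()),
        c=int(((a == 0) & (b == 1)).sum()),
        d=int(((a == 0) & (b == 0)).sum()),
    )


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa between two raters.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the product of the two
    raters' own marginal proportions. When p_e = 1 (both raters degenerate
    on the same category) observed agreement is also 1 and kappa is 1.
    """
    counts = pair_counts(ratings_a, ratings_b)
    n = counts.n
    p_o = (counts.a + counts.d) / n
    row_pos = (counts.a + counts.b) / n
    col_pos = (counts.a + counts.c) / n
    p_e = row_pos * col_pos + (1 - row_pos) * (1 - col_pos)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def fleiss_kappa(matrix: RatingMatrix) -> float:
    """Fleiss' kappa over a complete subjects x raters binary grid.

    Chance agreement uses category proportions pooled over all raters; for
    two raters this reduces to Scott's pi. When every call is in one
    category kappa is defined as 1.
    """
    if matrix.n_raters < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")
    if matrix.n_subjects < 2:
        raise ValueError("Fleiss' kappa needs at least 2 subjects")
    calls = matrix.calls.to_numpy()
    n_subjects, n_raters = calls.shape
    n_pos = calls.sum(axis=1)
    n_neg = n_raters - n_pos
    p_i = (n_pos * (n_pos - 1) + n_neg * (n_neg - 1)) / (n_raters * (n_raters - 1))
    p_bar = float(p_i.mean())
    prop_pos = float(n_pos.sum()) / (n_subjects * n_raters)
    p_e = prop_pos**2 + (1 - prop_pos) ** 2
    if p_e == 1.0:
        return 1.0
    return (p_bar - p_e) / (1 - p_e)


@dataclass(frozen=True)
class SpecificAgreement:
    """Overall, positive and negative agreement of a rater pair."""

    overall: Value
    positive: Value
    negative: Value

    def to_json(self) -> dict:
        return {
            name: (v if is_defined(v) else "undefined")
            for name, v in (
                ("overall", self.overall),
                ("positive", self.positive),
                ("negative", self.negative),
            )
        }


def specific_agreement(ratings_a, ratings_b) -> SpecificAgreement:
    """Overall (a+d)/n, positive 2a/(2a+b+c), negative 2d/(2d+b+c).

    Components with an empty denominator (no positive or no negative calls
    at all) are the undefined marker.
    """
    counts = pair_counts(ratings_a, ratings_b)
    pos_den = 2 * counts.a + counts.b + counts.c
    neg_den = 2 * counts.d + counts.b + counts.c
    return SpecificAgreement(
        overall=(counts.a + counts.d) / counts.n,
        positive=(2 * counts.a / pos_den) if pos_den else UNDEFINED,
        negative=(2 * counts.d / neg_den) if neg_den else UNDEFINED,
    )


@dataclass(frozen=True)
class PairResult:
    rater_a: str
    rater_b: str
    kappa: float
    agreement: SpecificAgreement

    @property
    def reliable(self) -> bool:
        return self.kappa >= RELIABILITY_THRESHOLD


@dataclass(frozen=True)
class AgreementReport:
    """Multi-rater reliability summary.

    Pooled positive/negative/overall agreement is the unweighted mean over
    all rater pairs (the pooling scheme is labelled in the output).
    """

    fleiss: float
    pairwise: tuple[PairResult, ...]
    label: str = "inter-rater"

    @property
    def cohen_matrix(self) -> pd.DataFrame:
        raters = sorted(
            {p.rater_a for p in self.pairwise} | {p.rater_b for p in self.pairwise}
        )
        mat = pd.DataFrame(np.nan, index=raters, columns=raters)
        for p in self.pairwise:
            mat.loc[p.rater_a, p.rater_b] = p.kappa
            mat.loc[p.rater_b, p.rater_a] = p.kappa
        return mat

    def pooled(self, component: str) -> Value:
        values = [
            getattr(p.agreement, component)
            for p in self.pairwise
            if is_defined(getattr(p.agreement, component))
        ]
        if not values:
            return UNDEFINED
        return float(np.mean(values))

    def to_json(self) -> dict:
        return {
            "label": self.label,
            "fleiss_kappa": self.fleiss,
            "reliability_threshold": RELIABILITY_THRESHOLD,
            "pairwise": [
                {
                    "rater_a": p.rater_a,
                    "rater_b": p.rater_b,
                    "cohen_kappa": p.kappa,
                    "reliable": p.reliable,
                    "agreement": p.agreement.to_json(),
                }
                for p in self.pairwise
            ],
            "pooled_agreement": {
                "scheme": "mean over rater pairs",
                "overall": _json_value(self.pooled("overall")),
                "positive": _json_value(self.pooled("positive")),
                "negative": _json_value(self.pooled("negative")),
            },
        }


def _json_value(v: Value):
    return v if is_defined(v) else "undefined"


def agreement_report(matrix: RatingMatrix, label: str = "inter-rater") -> AgreementReport:
    """Fleiss' kappa plus all pairwise Cohen kappas and specific agreement."""
    pairs = []
    for ra, rb in combinations(matrix.raters, 2):
        col_a, col_b = matrix.column(ra), matrix.column(rb)
        pairs.append(
            PairResult(
                rater_a=str(ra),
                rater_b=str(rb),
                kappa=cohen_kappa(col_a, col_b),
                agreement=specific_agreement(col_a, col_b),
            )
        )
    return AgreementReport(
        fleiss=fleiss_kappa(matrix), pairwise=tuple(pairs), label=label
    )


def intra_rater(ratings_test, ratings_retest, rater_id: str = "rater") -> dict:
    """Test-retest reliability of one rater: Cohen's kappa + agreement."""
    kappa = cohen_kappa(ratings_test, ratings_retest)
    agreement = specific_agreement(ratings_test, ratings_retest)
    return {
        "label": "intra-rater",
        "rater_id": rater_id,
        "cohen_kappa": kappa,
        "reliable": kappa >= RELIABILITY_THRESHOLD,
        "agreement": agreement.to_json(),
    }
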