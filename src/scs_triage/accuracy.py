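"""Diagnostic accuracy of the triage indication vs. the referral decision.

The triage conclusion (indication yes/no) is crossed with the reference
standard — the SCS-eligibility conclusion of the orthopaedic consult —
into a 2x2 table, from which sensitivity, specificity and the predictive
values are computed with 95% confidence intervals. Metrics with an empty
denominator are reported as an explicit undefined marker, never silently
as NaN or zero.

Interval methods: Clopper-Pearson (exact beta, the default), Wilson score,
and the rule of three for boundary counts (k = 0 or k = n), whose 95%
bound is 3/n on the empty side.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence, Union

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .markers import UNDEFINED, Undefined, is_defined

__all__ = [
    "ContingencyTable2x2",
    "MetricEstimate",
    "AccuracyReport",
    "build_table",
    "accuracy_metrics",
    "ci_proportion",
    "round_half_up",
]

CIMethod = Literal["clopper_pearson", "wilson", "rule_of_three"]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 digit rounds to 0.1, not 0.0)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of triage indication (rows) vs. reference referral (columns).

    ``tp``: indication yes & referral yes; ``fp``: indication yes &
    referral no; ``fn``: indication no & referral yes; ``tn``: both no.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swap_axes(self) -> "ContingencyTable2x2":
        """Transpose: prediction becomes reference and vice versa."""
        return ContingencyTable2x2(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)


def build_table(
    predictions: Sequence[int], references: Sequence[int]
) -> ContingencyTable2x2:
    """Cross-tabulate binary triage indications against reference labels."""
    pred = np.asarray(predictions)
    ref = np.asarray(references)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError(
            f"predictions and references must be equal-length 1-d vectors "
            f"(got shapes {pred.shape} and {ref.shape})"
        )
    for name, vec in (("predictions", pred), ("references", ref)):
        if not np.isin(vec, (0, 1, True, False)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    pred = pred.astype(bool)
    ref = ref.astype(bool)
    return ContingencyTable2x2(
        tp=int((pred & ref).sum()),
        fp=int((pred & ~ref).sum()),
        fn=int((~pred & ref).sum()),
        tn=int((~pred & ~ref).sum()),
    )


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with a two-sided 95% interval and its method name."""

    value: float
    lower: float
    upper: float
    method: str

    def __post_init__(self):
        if not (0 <= self.lower <= self.value <= self.upper <= 1):
            raise ValueError(
                f"estimate {self.value} outside its interval "
                f"[{self.lower}, {self.upper}]"
            )

    def as_percent(self, ndigits: int = 1) -> float:
        return round_half_up(100 * self.value, ndigits)

    def to_json(self) -> dict:
        return {
            "value": self.value,
            "percent": self.as_percent(),
            "ci95_lower": self.lower,
            "ci95_upper": self.upper,
            "ci_method": self.method,
        }


Metric = Union[MetricEstimate, Undefined]


def ci_proportion(
    k: int, n: int, method: CIMethod = "clopper_pearson"
) -> tuple[float, float]:
    """Two-sided 95% confidence interval for a binomial proportion k/n.

    ``rule_of_three`` applies only at the boundaries: for k = 0 the
    interval is [0, 3/n], for k = n it is [1 - 3/n, 1].
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if method == "rule_of_three":
        if k == 0:
            return (0.0, min(1.0, 3 / n))
        if k == n:
            return (max(0.0, 1 - 3 / n), 1.0)
        raise ValueError("rule_of_three requires k = 0 or k = n")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lower, upper = proportion_confint(k, n, alpha=0.05, method=sm_method)
    # boundary cases are exact by construction; avoid float round-off there
    lower = 0.0 if k == 0 else float(np.clip(lower, 0, 1))
    upper = 1.0 if k == n else float(np.clip(upper, 0, 1))
    return (lower, upper)


@dataclass(frozen=True)
class AccuracyReport:
    """Se/Sp/PPV/NPV with intervals, plus the counts they came from."""

    table: ContingencyTable2x2
    se: Metric
    sp: Metric
    ppv: Metric
    npv: Metric
    ci_method: str

    def to_json(self) -> dict:
        out = {
            "counts": {
                "tp": self.table.tp,
                "fp": self.table.fp,
                "fn": self.table.fn,
                "tn": self.table.tn,
                "total": self.table.total,
            },
            "ci_method": self.ci_method,
        }
        for name in ("se", "sp", "ppv", "npv"):
            metric = getattr(self, name)
            out[name] = metric.to_json() if is_defined(metric) else "undefined"
        return out

    def to_text(self) -> str:
        lines = [
            "Predictive accuracy (triage indication vs. reference referral)",
            f"  counts: tp={self.table.tp} fp={self.table.fp} "
            f"fn={self.table.fn} tn={self.table.tn}",
        ]
        labels = {
            "se": "sensitivity",
            "sp": "specificity",
            "ppv": "positive predictive value",
            "npv": "negative predictive value",
        }
        for name, label in labels.items():
            metric = getattr(self, name)
            if is_defined(metric):
                lines.append(
                    f"  {label}: {metric.as_percent():.1f}% "
                    f"(95% CI {100 * metric.lower:.1f}-{100 * metric.upper:.1f}, "
                    f"{metric.method})"
                )
            else:
                lines.append(f"  {label}: undefined (empty denominator)")
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()


def _metric(k: int, n: int, ci_method: CIMethod) -> Metric:
    if n == 0:
        return UNDEFINED
    method = ci_method
    if ci_method == "rule_of_three" and 0 < k < n:
        # rule of three only exists at the boundary; fall back to exact
        method = "clopper_pearson"
    lower, upper = ci_proportion(k, n, method)
    return MetricEstimate(value=k / n, lower=lower, upper=upper, method=method)


def accuracy_metrics(
    table: ContingencyTable2x2, ci_method: CIMethod = "clopper_pearson"
) -> AccuracyReport:
    """Compute Se, Sp, PPV and NPV with 95% intervals from a 2x2 table.

    Any metric whose denominator is zero is reported as the undefined
    marker. With ``ci_method="rule_of_three"`` the rule is applied to the
    metrics sitting at a boundary (k = 0 or k = n); interior metrics fall
    back to Clopper-Pearson, and each estimate records the method used.
    """
    return AccuracyReport(
        table=table,
        se=_metric(table.tp, table.tp + table.fn, ci_method),
        sp=_metric(table.tn, table.tn + table.fp, ci_method),
        ppv=_metric(table.tp, table.tp + table.fp, ci_method),
        npv=_metric(table.tn, table.tn + table.fn, ci_method),
        ci_method=ci_method,
    )
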