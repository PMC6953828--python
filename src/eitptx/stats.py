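"""Agreement and diagnostic-accuracy statistics for binary ratings.

Implements Cohen's kappa for a 2x2 contingency table with the large-sample
standard error under the independence null (Fleiss form), the study's
interpretation bands, sensitivity/specificity/PPV/NPV, reconstruction of 2x2
tables from printed marginals, and half-away-from-zero integer percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from scipy.stats import norm

__all__ = [
    "TwoByTwo",
    "KappaResult",
    "DiagnosticMetrics",
    "table_from_marginals",
    "table_from_labels",
    "cohen_kappa",
    "interpret_kappa",
    "diagnostic_metrics",
    "percent_of",
]


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 agreement table.

    ``a``: both raters positive; ``b``: rater 1 positive only; ``c``: rater 2
    positive only; ``d``: both negative.  When rater 2 is the reference truth,
    the cells are (TP, FP, FN, TN) in that order.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    se0: float
    z: float
    p_value: float
    band: str


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Proportions in [0, 1]; ``None`` marks an undefined (0/0) metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def table_from_marginals(n: int, r1_pos: int, r2_pos: int, both_pos: int) -> TwoByTwo:
    """Reconstruct a 2x2 table from its size, the two positive-call marginals,
    and the both-positive count."""
    for name, v in (("n", n), ("r1_pos", r1_pos), ("r2_pos", r2_pos), ("both_pos", both_pos)):
        if not isinstance(v, int) or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    if both_pos > min(r1_pos, r2_pos):
        raise ValueError(
            f"infeasible marginals: both_pos={both_pos} exceeds "
            f"min(r1_pos, r2_pos)={min(r1_pos, r2_pos)}"
        )
    if r1_pos > n or r2_pos > n:
        raise ValueError("infeasible marginals: a positive margin exceeds n")
    if r1_pos + r2_pos - both_pos > n:
        raise ValueError(
            f"infeasible marginals: r1_pos + r2_pos - both_pos = "
            f"{r1_pos + r2_pos - both_pos} exceeds n={n}"
        )
    a = both_pos
    b = r1_pos - both_pos
    c = r2_pos - both_pos
    d = n - a - b - c
    return TwoByTwo(a, b, c, d)


def table_from_labels(r1: Sequence[bool], r2: Sequence[bool]) -> TwoByTwo:
    """Tabulate paired binary labels into a 2x2 table."""
    if len(r1) != len(r2):
        raise ValueError("label lists must have equal length")
    a = b = c = d = 0
    for x, y in zip(r1, r2):
        if x and y:
            a += 1
        elif x:
            b += 1
        elif y:
            c += 1
        else:
            d += 1
    return TwoByTwo(a, b, c, d)


def cohen_kappa(table: TwoByTwo) -> KappaResult:
    """Cohen's kappa with the large-sample SE under the independence null.

    The null-hypothesis standard error (Fleiss) gives a two-sided normal
    p-value for H0: kappa = 0.
    """
    n = table.n
    a, b, c, d = table.a, table.b, table.c, table.d
    po = (a + d) / n
    # Marginal proportions: rater 1 rows, rater 2 columns.
    p1_pos = (a + b) / n
    p2_pos = (a + c) / n
    p1_neg = 1.0 - p1_pos
    p2_neg = 1.0 - p2_pos
    pe = p1_pos * p2_pos + p1_neg * p2_neg
    if math.isclose(pe, 1.0, abs_tol=1e-15):
        raise ValueError("kappa undefined: expected agreement is 1 (degenerate marginals)")
    kappa = (po - pe) / (1.0 - pe)

    s = p1_pos * p2_pos * (p1_pos + p2_pos) + p1_neg * p2_neg * (p1_neg + p2_neg)
    var0 = (pe + pe * pe - s) / (n * (1.0 - pe) ** 2)
    se0 = math.sqrt(max(var0, 0.0))
    if se0 > 0:
        z = kappa / se0
        p_value = float(2.0 * norm.sf(abs(z)))
    else:
        z = math.inf if kappa > 0 else (-math.inf if kappa < 0 else 0.0)
        p_value = 0.0 if kappa != 0 else 1.0
    return KappaResult(
        kappa=kappa,
        p_observed=po,
        p_expected=pe,
        se0=se0,
        z=z,
        p_value=p_value,
        band=interpret_kappa(kappa),
    )


_BANDS = (
    (0.2, "no agreement"),
    (0.4, "minimal agreement"),
    (0.6, "weak agreement"),
    (0.8, "strong agreement"),
    (0.9, "very strong agreement"),
)


def interpret_kappa(kappa: float) -> str:
    """Map kappa to its interpretation band (negatives count as no agreement)."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa out of range [-1, 1]: {kappa}")
    for upper, label in _BANDS:
        if kappa < upper:
            return label
    return "almost perfect agreement"


def diagnostic_metrics(table: TwoByTwo) -> DiagnosticMetrics:
    """Diagnostic accuracy with rater 2 as reference truth.

    sensitivity = a/(a+c), specificity = d/(b+d), ppv = a/(a+b),
    npv = d/(c+d); zero denominators yield ``None`` rather than 0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return DiagnosticMetrics(
        sensitivity=ratio(a, a + c),
        specificity=ratio(d, b + d),
        ppv=ratio(a, a + b),
        npv=ratio(d, c + d),
    )


def percent_of(count: int, total: int) -> int:
    """Integer percentage with half-away-from-zero rounding (exact arithmetic)."""
    if not isinstance(count, int) or not isinstance(total, int):
        raise ValueError("count and total must be integers")
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return math.floor(Fraction(100 * count, total) + Fraction(1, 2))
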