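"""Two-set physico-chemical comparison: median split + Fisher's exact test.

For each propensity scale, every protein in both sets receives a windowed
mean score; the pooled median of the two score vectors splits proteins into
high/low halves, and the resulting 2x2 table (set x side-of-median) is
tested with the two-sided Fisher exact test.  A comparison is called
enriched for one set only when p falls below a stringent threshold
(default 1e-5) and that set holds the larger above-median fraction;
otherwise it is non-significant — the yellow state of the tri-state
comparison matrices.

The exact test is computed with integer hypergeometric weights and the
standard two-sided "no more probable" rule: p is the sum of probabilities
of all tables with the observed margins whose probability does not exceed
the observed table's.  Working in exact integer arithmetic makes tied
tables unambiguous (no mid-p, no float tie tolerance).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np

from .io_sets import ProteinSet
from .propensity import DEFAULT_WINDOW, ScaleRegistry, set_scores

DEFAULT_ALPHA = 1e-5
LOW_N = 10   # sets smaller than this are annotated, not rejected


class Call(str, enum.Enum):
    A_ENRICHED = "A_ENRICHED"
    B_ENRICHED = "B_ENRICHED"
    NON_SIGNIFICANT = "NON_SIGNIFICANT"


@dataclass(frozen=True)
class ComparisonOutcome:
    set_a: str
    set_b: str
    scale_name: str
    feature_class: str
    direction: Call
    p_value: float
    odds_ratio: float
    counts: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False
    low_n: bool = False

    @property
    def significant(self) -> bool:
        return self.direction is not Call.NON_SIGNIFICANT

    @property
    def color(self) -> str:
        """Report parity with the tri-state heatmaps: red = signal (A)
        enriched, green = negative (B) enriched, yellow = non-significant."""
        return {Call.A_ENRICHED: "red", Call.B_ENRICHED: "green",
                Call.NON_SIGNIFICANT: "yellow"}[self.direction]


def score_split(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[tuple[tuple[int, int], tuple[int, int]], bool]:
    """Split both score vectors at their pooled median.

    Returns ``((a_hi, a_lo), (b_hi, b_lo))`` where *hi* counts scores
    strictly above the pooled median (ties go low), plus a degeneracy flag
    set when every pooled score is identical (no split exists).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("score vectors must be non-empty")
    pooled = np.concatenate([a, b])
    degenerate = bool(np.all(pooled == pooled[0]))
    m = float(np.median(pooled))
    a_hi = int(np.sum(a > m))
    b_hi = int(np.sum(b > m))
    table = ((a_hi, a.size - a_hi), (b_hi, b.size - b_hi))
    return table, degenerate


@lru_cache(maxsize=100_000)
def _hypergeom_weights(c1: int, c2: int, r1: int) -> tuple[int, ...]:
    """Integer weights w(k) = C(c1,k)·C(c2,r1−k) for every feasible n11=k;
    table probability is w(k)/C(c1+c2, r1)."""
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    return tuple(comb(c1, k) * comb(c2, r1 - k) for k in range(lo, hi + 1))


def fisher_two_sided(
    table: Sequence[Sequence[int]],
) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p_value)``.  The odds ratio is the sample ratio
    n11·n22 / (n12·n21), infinite when the denominator is zero with a
    positive numerator, and NaN for the empty 0/0 case.  The p-value is the
    exact sum of hypergeometric probabilities of all margin-fixed tables no
    more probable than the observed one, evaluated in integer arithmetic.
    """
    (n11, n12), (n21, n22) = ((int(table[0][0]), int(table[0][1])),
                              (int(table[1][0]), int(table[1][1])))
    if min(n11, n12, n21, n22) < 0:
        raise ValueError("contingency table entries must be non-negative")
    r1, r2 = n11 + n12, n21 + n22
    c1, c2 = n11 + n21, n12 + n22
    if r1 + r2 == 0:
        raise ValueError("empty contingency table")

    num, den = n11 * n22, n12 * n21
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = math.nan

    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return odds, 1.0

    weights = _hypergeom_weights(c1, c2, r1)
    lo = max(0, r1 - c2)
    w_obs = weights[n11 - lo]
    p = Fraction(sum(w for w in weights if w <= w_obs), comb(c1 + c2, r1))
    return odds, float(p)


def compare_sets(
    set_a: ProteinSet,
    set_b: ProteinSet,
    registry: ScaleRegistry,
    feature_class: str,
    alpha: float = DEFAULT_ALPHA,
    window: int = DEFAULT_WINDOW,
) -> list[ComparisonOutcome]:
    """Run the median-split Fisher comparison on every scale of a class.

    Set A is the *signal* side: ``A_ENRICHED`` means p < alpha with A
    holding the larger above-median fraction.  Degenerate splits (all
    scores identical) are reported non-significant.
    """
    scales = registry.by_class(feature_class)
    if not scales:
        raise ValueError(f"registry has no scales for {feature_class!r}")
    low_n = len(set_a) < LOW_N or len(set_b) < LOW_N
    out = []
    for scale in scales:
        sa = set_scores(set_a, scale, window=window)
        sb = set_scores(set_b, scale, window=window)
        out.append(
            outcome_from_scores(sa, sb, set_a.name, set_b.name,
                                scale.name, feature_class, alpha, low_n)
        )
    return out


def outcome_from_scores(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    name_a: str,
    name_b: str,
    scale_name: str,
    feature_class: str,
    alpha: float = DEFAULT_ALPHA,
    low_n: bool = False,
) -> ComparisonOutcome:
    """Median split + Fisher test + tri-state call on precomputed scores."""
    table, degenerate = score_split(scores_a, scores_b)
    odds, p = fisher_two_sided(table)
    (a_hi, a_lo), (b_hi, b_lo) = table
    if degenerate or p >= alpha:
        call = Call.NON_SIGNIFICANT
    else:
        frac_a = a_hi / (a_hi + a_lo)
        frac_b = b_hi / (b_hi + b_lo)
        if frac_a > frac_b:
            call = Call.A_ENRICHED
        elif frac_b > frac_a:
            call = Call.B_ENRICHED
        else:
            call = Call.NON_SIGNIFICANT
    return ComparisonOutcome(
        set_a=name_a, set_b=name_b, scale_name=scale_name,
        feature_class=feature_class, direction=call,
        p_value=1.0 if degenerate else p,
        odds_ratio=odds, counts=table, degenerate=degenerate, low_n=low_n,
    )
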