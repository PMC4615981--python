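"""Many-vs-many comparison matrices and the signed signal-strength score.

Given a group of *signal* protein sets (e.g. the CNS-disease sets) and a
group of *negative* sets (e.g. the cancer sets), every (signal, negative)
pair is compared on every scale of one feature class, giving a grid of
tri-state outcomes.  The grid is summarised by the signed signal-strength
statistic: with N comparisons of which k are significant in the majority
direction, the score is ±k/N rounded half-up to two decimals — positive
when the majority of significant calls favour the signal sets, negative
when they favour the negative sets.  Non-significant comparisons count
toward N but never toward k, so e.g. 17 concordant calls out of 18
comparisons give +0.94.

``agreement_score`` applies the same arithmetic across an up-regulated and
a down-regulated matrix of the same axes, scoring how consistently the two
move in opposite directions (anti-correlated features score negatively).

``null_calibration`` re-runs the comparison on randomly drawn same-size
subsets of a background pool to measure the empirical false-positive rate
of the whole procedure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .enrichment import (
    DEFAULT_ALPHA,
    Call,
    ComparisonOutcome,
    compare_sets,
    outcome_from_scores,
)
from .io_sets import ProteinSet
from .propensity import DEFAULT_WINDOW, ScaleRegistry, set_scores


def _invert_odds(odds: float) -> float:
    if np.isnan(odds):
        return odds
    if odds == 0.0:
        return np.inf
    if np.isinf(odds):
        return 0.0
    return 1.0 / odds


class Trend(str, enum.Enum):
    SIGNAL_ENRICHED = "SIGNAL_ENRICHED"
    NEGATIVE_ENRICHED = "NEGATIVE_ENRICHED"
    MIXED = "MIXED"


@dataclass(frozen=True)
class SignalStrength:
    n_follow: int
    n_total: int
    value: float          # ±(n_follow/n_total), half-up to 2 decimals
    trend: Trend

    def __post_init__(self) -> None:
        if self.n_total < 1 or self.n_follow < 0 or self.n_follow > self.n_total:
            raise ValueError("invalid signal-strength counts")


@dataclass
class ComparisonMatrix:
    signal_sets: list[str]
    negative_sets: list[str]
    feature_class: str
    cells: dict[tuple[str, str], list[ComparisonOutcome]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        expected = {(s, n) for s in self.signal_sets for n in self.negative_sets}
        if set(self.cells) != expected:
            raise ValueError("comparison matrix cells do not cover the grid")

    def outcomes(self) -> list[ComparisonOutcome]:
        """All outcomes in deterministic (signal, negative, scale) order."""
        out = []
        for s in self.signal_sets:
            for n in self.negative_sets:
                out.extend(self.cells[(s, n)])
        return out

    def transposed(self) -> "ComparisonMatrix":
        """Exchange the signal and negative axes (flips every call)."""
        flip = {Call.A_ENRICHED: Call.B_ENRICHED,
                Call.B_ENRICHED: Call.A_ENRICHED,
                Call.NON_SIGNIFICANT: Call.NON_SIGNIFICANT}
        cells = {}
        for (s, n), outs in self.cells.items():
            cells[(n, s)] = [
                ComparisonOutcome(
                    set_a=o.set_b, set_b=o.set_a, scale_name=o.scale_name,
                    feature_class=o.feature_class,
                    direction=flip[o.direction], p_value=o.p_value,
                    odds_ratio=_invert_odds(o.odds_ratio),
                    counts=(o.counts[1], o.counts[0]),
                    degenerate=o.degenerate, low_n=o.low_n,
                )
                for o in outs
            ]
        return ComparisonMatrix(self.negative_sets, self.signal_sets,
                                self.feature_class, cells)


def build_matrix(
    signal: Sequence[ProteinSet],
    negative: Sequence[ProteinSet],
    registry: ScaleRegistry,
    feature_class: str,
    alpha: float = DEFAULT_ALPHA,
    window: int = DEFAULT_WINDOW,
) -> ComparisonMatrix:
    """Compare every signal set against every negative set (signal = A)."""
    if not signal or not negative:
        raise ValueError("signal and negative set lists must be non-empty")
    cells = {}
    for s in signal:
        for n in negative:
            cells[(s.name, n.name)] = compare_sets(
                s, n, registry, feature_class, alpha=alpha, window=window
            )
    return ComparisonMatrix(
        [s.name for s in signal], [n.name for n in negative],
        feature_class, cells,
    )


def _round_half_up(x: float, places: int = 2) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def signal_strength(
    outcomes: ComparisonMatrix | Iterable[ComparisonOutcome],
) -> SignalStrength:
    """Signed majority fraction of significant comparison calls.

    Each outcome contributes one call (A = signal side).  The majority
    trend is whichever direction holds more significant calls; the value is
    ±(majority count)/(total), rounded half-up to two decimals, positive
    for a signal-enriched majority.  Exact ties are reported MIXED with a
    positive sign.
    """
    if isinstance(outcomes, ComparisonMatrix):
        outcomes = outcomes.outcomes()
    outcomes = list(outcomes)
    n_total = len(outcomes)
    if n_total == 0:
        raise ValueError("signal_strength needs at least one comparison")
    n_sig = sum(1 for o in outcomes if o.direction is Call.A_ENRICHED)
    n_neg = sum(1 for o in outcomes if o.direction is Call.B_ENRICHED)
    if n_sig > n_neg:
        trend, n_follow, sign = Trend.SIGNAL_ENRICHED, n_sig, 1.0
    elif n_neg > n_sig:
        trend, n_follow, sign = Trend.NEGATIVE_ENRICHED, n_neg, -1.0
    else:
        trend, n_follow, sign = Trend.MIXED, n_sig, 1.0
    return SignalStrength(
        n_follow=n_follow,
        n_total=n_total,
        value=sign * _round_half_up(n_follow / n_total),
        trend=trend,
    )


def agreement_score(
    matrix_up: ComparisonMatrix, matrix_down: ComparisonMatrix
) -> SignalStrength:
    """Cross-matrix trend agreement between up- and down-regulated runs.

    Slots where both matrices are significant in *opposite* directions
    (signal enriched in one, depleted in the other — the single-hypothesis
    pattern) count toward an anti-correlated majority and give a negative
    value; slots significant in the *same* direction count toward a
    positive value.  31 opposite-trending slots of 36 give −0.86.
    """
    if (matrix_up.signal_sets != matrix_down.signal_sets
            or matrix_up.negative_sets != matrix_down.negative_sets):
        raise ValueError("matrices must share signal/negative axes")
    up, down = matrix_up.outcomes(), matrix_down.outcomes()
    if len(up) != len(down):
        raise ValueError("matrices must share their scale battery")
    n_total = len(up)
    n_anti = n_same = 0
    for u, d in zip(up, down):
        if u.scale_name != d.scale_name:
            raise ValueError("matrices must share their scale battery")
        if u.significant and d.significant:
            if u.direction is d.direction:
                n_same += 1
            else:
                n_anti += 1
    if n_anti > n_same:
        trend, n_follow, sign = Trend.NEGATIVE_ENRICHED, n_anti, -1.0
    elif n_same > n_anti:
        trend, n_follow, sign = Trend.SIGNAL_ENRICHED, n_same, 1.0
    else:
        trend, n_follow, sign = Trend.MIXED, n_anti, 1.0
    return SignalStrength(
        n_follow=n_follow, n_total=n_total,
        value=sign * _round_half_up(n_follow / n_total), trend=trend,
    )


@dataclass(frozen=True)
class NullCalibration:
    n_reps: int
    n_comparisons: int
    n_significant: int
    significant_fraction: float
    n_signal_calls: int      # significant with the first subset enriched
    n_negative_calls: int
    alpha: float


def null_calibration(
    background: ProteinSet,
    set_sizes: tuple[int, int],
    n_reps: int,
    registry: ScaleRegistry,
    feature_class: str,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
) -> NullCalibration:
    """Empirical significant-call rate on random same-size subsets.

    Per replicate two *disjoint* subsets of the stated sizes are drawn
    without replacement from the background and compared on every scale of
    the feature class.  Scores are computed once per background protein and
    scale, so replicates only re-sample indices.  Deterministic under
    ``seed``.
    """
    n1, n2 = set_sizes
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n1 + n2 > len(background):
        raise ValueError(
            f"set sizes {set_sizes} exceed background of {len(background)}"
        )
    scales = registry.by_class(feature_class)
    if not scales:
        raise ValueError(f"registry has no scales for {feature_class!r}")
    all_scores = {s.name: set_scores(background, s, window=window)
                  for s in scales}
    rng = np.random.default_rng(seed)
    n_sig = n_a = n_b = n_cmp = 0
    for _ in range(n_reps):
        idx = rng.choice(len(background), size=n1 + n2, replace=False)
        ia, ib = idx[:n1], idx[n1:]
        for s in scales:
            sc = all_scores[s.name]
            o = outcome_from_scores(sc[ia], sc[ib], "rand_a", "rand_b",
                                    s.name, feature_class, alpha=alpha)
            n_cmp += 1
            if o.significant:
                n_sig += 1
                if o.direction is Call.A_ENRICHED:
                    n_a += 1
                else:
                    n_b += 1
    return NullCalibration(
        n_reps=n_reps, n_comparisons=n_cmp, n_significant=n_sig,
        significant_fraction=n_sig / n_cmp,
        n_signal_calls=n_a, n_negative_calls=n_b, alpha=alpha,
    )
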