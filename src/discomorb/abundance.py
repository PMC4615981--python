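"""Reference-proteome abundance comparison (two-sample Kolmogorov–Smirnov).

Disease sets are matched against an abundance table (id -> abundance in
arbitrary positive units, log10-transformed on ingest) and their
log-abundance distribution is compared with a background distribution by
the two-sample KS test.  The direction call (LOWER / HIGHER / NS) compares
medians when the test is significant — e.g. proteins up-regulated in CNS
disorders sit in the poorly-abundant tail of the reference proteome.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_sets import ProteinSet


class AbundanceDirection(str, enum.Enum):
    LOWER = "LOWER"
    HIGHER = "HIGHER"
    NS = "NS"


class MatchError(KeyError):
    """No set member could be matched to the abundance table."""


@dataclass
class AbundanceTable:
    """id -> log10 abundance; built from raw positive abundances."""

    log10_values: dict[str, float]

    @classmethod
    def from_raw(cls, values: Mapping[str, float]) -> "AbundanceTable":
        out: dict[str, float] = {}
        for pid, v in values.items():
            if pid in out:
                raise ValueError(f"duplicate abundance id {pid!r}")
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(
                    f"abundance for {pid!r} must be a positive finite "
                    f"number, got {v!r}"
                )
            out[pid] = math.log10(v)
        if not out:
            raise ValueError("empty abundance table")
        return cls(out)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        """Plain ``id<TAB>abundance`` rows; optional header line."""
        raw: dict[str, float] = {}
        for i, line in enumerate(Path(path).read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, val = line.split("\t")[:2]
            if i == 0 and val.lower() in ("abundance", "value"):
                continue
            if pid in raw:
                raise ValueError(f"{path}: duplicate abundance id {pid!r}")
            raw[pid] = float(val)
        return cls.from_raw(raw)

    def __len__(self) -> int:
        return len(self.log10_values)

    def background(self) -> np.ndarray:
        """All log10 abundances, in insertion order."""
        return np.array(list(self.log10_values.values()))


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> tuple[float, float]:
    """Two-sample KS statistic and p-value.

    D is the supremum absolute difference between the two empirical
    distribution functions; p comes from the asymptotic Kolmogorov
    distribution with the usual sqrt(nm/(n+m)) effective-sample correction,
    or from the exact permutation distribution with ``exact=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS samples must be non-empty")
    res = stats.ks_2samp(x, y, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AbundanceReport:
    set_name: str
    n_members: int
    n_matched: int
    n_unmatched: int
    median_log10: float
    background_median_log10: float
    D: float
    p_value: float
    direction: AbundanceDirection


def set_abundance_comparison(
    pset: ProteinSet,
    table: AbundanceTable,
    background: Sequence[float] | None = None,
    alpha: float = 0.05,
    exact: bool = False,
) -> AbundanceReport:
    """KS-compare a set's log-abundances against a background vector.

    Members are matched by protein id first, then by gene symbol; the
    unmatched count is always reported.  ``background`` defaults to the
    whole table.  Direction is decided by the median difference only when
    p < alpha.
    """
    vals = []
    n_unmatched = 0
    for rec in pset:
        if rec.id in table.log10_values:
            vals.append(table.log10_values[rec.id])
        elif rec.gene in table.log10_values:
            vals.append(table.log10_values[rec.gene])
        else:
            n_unmatched += 1
    if not vals:
        raise MatchError(
            f"set {pset.name!r}: no member found in the abundance table"
        )
    bg = table.background() if background is None else np.asarray(background,
                                                                  dtype=float)
    D, p = ks_two_sample(vals, bg, exact=exact)
    med, bg_med = float(np.median(vals)), float(np.median(bg))
    if p < alpha and med < bg_med:
        direction = AbundanceDirection.LOWER
    elif p < alpha and med > bg_med:
        direction = AbundanceDirection.HIGHER
    else:
        direction = AbundanceDirection.NS
    return AbundanceReport(
        set_name=pset.name, n_members=len(pset), n_matched=len(vals),
        n_unmatched=n_unmatched, median_log10=med,
        background_median_log10=bg_med, D=D, p_value=p, direction=direction,
    )
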