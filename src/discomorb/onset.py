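"""Structural disorder vs. age of onset: binning, normalisation and fits.

Single-point substitutions in neurodegeneration genes carry an age of
onset; each mutant protein receives a structural-disorder score (the
B-value score: mean of a [0, 1]-normalised flexibility scale over residues
above a floor).  Observations are grouped into onset-age bins (default
2.5 years), the disorder axis is Z-normalised, and the binned relationship
is fitted with a four-parameter logistic

    AGE(z) = A + (B - A) / (1 + exp(k * (z - m)))

(lower asymptote A, upper asymptote B, steepness k, midpoint m; k > 0
gives a decreasing curve) and, for comparison, with ordinary linear
regression.  The Pearson correlation between the Z-scored disorder and age
is reported alongside each fit; disorder anti-correlating with onset gives
r < 0.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .io_sets import CANONICAL, ProteinRecord
from .propensity import (
    DEFAULT_BVALUE_FLOOR,
    PropensityScale,
    bvalue_disorder_score,
)

DEFAULT_BIN_WIDTH = 2.5   # years

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class OnsetModel(str, enum.Enum):
    SIGMOID = "SIGMOID"
    LINEAR = "LINEAR"


@dataclass(frozen=True)
class MutationRecord:
    """A single-point substitution with its associated age of onset."""

    protein_id: str
    substitution: str          # e.g. "A53T" (1-based position)
    onset_age: float

    def __post_init__(self) -> None:
        if not _SUB_RE.match(self.substitution):
            raise ValueError(
                f"malformed substitution {self.substitution!r} "
                f"(expected e.g. 'A53T')"
            )
        ref, _, alt = self.parse()
        if ref not in CANONICAL or alt not in CANONICAL:
            raise ValueError(
                f"substitution {self.substitution!r}: non-canonical residue"
            )
        if not self.onset_age > 0:
            raise ValueError(
                f"onset age must be positive, got {self.onset_age}"
            )

    def parse(self) -> tuple[str, int, str]:
        m = _SUB_RE.match(self.substitution)
        return m.group(1), int(m.group(2)), m.group(3)


def read_mutation_tsv(path: str | Path) -> list[MutationRecord]:
    """``protein_id<TAB>substitution<TAB>onset_age`` rows, optional header."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pid, sub, age = line.split("\t")[:3]
        if i == 0 and not _SUB_RE.match(sub):
            continue  # header
        out.append(MutationRecord(pid, sub, float(age)))
    return out


def apply_substitution(record: ProteinRecord, substitution: str,
                       force: bool = False) -> ProteinRecord:
    """Return the mutant record; validates the reference residue."""
    m = _SUB_RE.match(substitution)
    if not m:
        raise ValueError(f"malformed substitution {substitution!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if pos < 1 or pos > len(record.sequence):
        raise ValueError(
            f"{record.id}: substitution position {pos} outside sequence "
            f"of length {len(record.sequence)}"
        )
    found = record.sequence[pos - 1]
    if found != ref and not force:
        raise ValueError(
            f"{record.id}: reference residue mismatch at {pos} "
            f"(sequence has {found}, substitution says {ref})"
        )
    seq = record.sequence[:pos - 1] + alt + record.sequence[pos:]
    return ProteinRecord(id=f"{record.id}:{substitution}",
                         gene=record.gene, sequence=seq)


def mutation_disorder(
    record: MutationRecord,
    sequences: Mapping[str, ProteinRecord],
    bvalue_scale: PropensityScale,
    mode: str = "mutant",
    floor: float = DEFAULT_BVALUE_FLOOR,
    force: bool = False,
) -> float:
    """B-value disorder score of the (mutant or wild-type) protein."""
    if mode not in ("mutant", "wildtype"):
        raise ValueError(f"mode must be 'mutant' or 'wildtype', got {mode!r}")
    try:
        wt = sequences[record.protein_id]
    except KeyError:
        raise KeyError(
            f"no sequence for mutated protein {record.protein_id!r}"
        ) from None
    prot = (apply_substitution(wt, record.substitution, force=force)
            if mode == "mutant" else wt)
    return bvalue_disorder_score(prot, bvalue_scale, floor=floor)


@dataclass(frozen=True)
class OnsetPoint:
    sd: float            # mean structural disorder in the bin
    sd_z: float          # Z-normalised disorder (NaN until normalised)
    age: float           # mean onset age in the bin, years
    n_mutations: int

    def __post_init__(self) -> None:
        if self.n_mutations < 1:
            raise ValueError("bin occupancy must be >= 1")


def bin_by_onset(
    points: Sequence[tuple[float, float]], width: float = DEFAULT_BIN_WIDTH
) -> list[OnsetPoint]:
    """Group (disorder, age) pairs into half-open onset-age bins
    ``[min_age + i*width, min_age + (i+1)*width)``; empty bins are omitted
    and occupancies sum to the input size."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    pts = [(float(sd), float(age)) for sd, age in points]
    if not pts:
        raise ValueError("no points to bin")
    min_age = min(a for _, a in pts)
    bins: dict[int, list[tuple[float, float]]] = {}
    for sd, age in pts:
        bins.setdefault(int((age - min_age) // width), []).append((sd, age))
    out = []
    for i in sorted(bins):
        members = bins[i]
        out.append(OnsetPoint(
            sd=float(np.mean([s for s, _ in members])),
            sd_z=float("nan"),
            age=float(np.mean([a for _, a in members])),
            n_mutations=len(members),
        ))
    return out


def z_normalize(values: Sequence[float]) -> np.ndarray:
    """(v - mean) / sample standard deviation (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("Z-normalisation needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("Z-normalisation of a constant vector")
    return (v - v.mean()) / sd


def z_normalize_points(points: Sequence[OnsetPoint]) -> list[OnsetPoint]:
    """Z-normalise the disorder axis across a collection of bins."""
    z = z_normalize([p.sd for p in points])
    return [OnsetPoint(p.sd, float(zi), p.age, p.n_mutations)
            for p, zi in zip(points, z)]


@dataclass(frozen=True)
class OnsetFit:
    model: OnsetModel
    params: dict[str, float]
    pearson_r: float     # corr(z-scored disorder, age) — model-independent
    pearson_p: float
    model_r: float       # corr(fitted, observed age), signed by the trend
    rmse: float
    converged: bool

    def predict(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.model is OnsetModel.LINEAR:
            return self.params["slope"] * z + self.params["intercept"]
        A, B = self.params["A"], self.params["B"]
        k, m = self.params["k"], self.params["m"]
        return logistic4(z, A, B, k, m)


def logistic4(z, A, B, k, m):
    """Four-parameter logistic, decreasing for k > 0."""
    return A + (B - A) / (1.0 + np.exp(k * (np.asarray(z, dtype=float) - m)))


def fit_onset(
    points: Sequence[OnsetPoint],
    model: OnsetModel | str = OnsetModel.SIGMOID,
    n_starts: int = 5,
    seed: int = 0,
) -> OnsetFit:
    """Least-squares fit of the binned (or raw) disorder/onset relationship.

    The sigmoid fit uses ``n_starts`` seeded multi-start initialisations
    spanning the data range (steepness and midpoint varied) and keeps the
    lowest-residual converged solution; asymptotes are reordered A <= B by
    the (A,B,k,m) <-> (B,A,-k,m) symmetry of the logistic.  Pearson r is
    computed between the Z-scored disorder and age over the given points.
    """
    model = OnsetModel(model)
    pts = list(points)
    if model is OnsetModel.LINEAR and len(pts) < 2:
        raise ValueError("linear fit needs >= 2 points")
    if model is OnsetModel.SIGMOID and len(pts) < 4:
        raise ValueError("sigmoid fit needs >= 4 points")
    z = np.array([p.sd_z for p in pts])
    if np.isnan(z).any():
        z = z_normalize([p.sd for p in pts])
    age = np.array([p.age for p in pts])
    if np.ptp(z) == 0 or np.ptp(age) == 0:
        raise ValueError("degenerate spread: constant disorder or age")
    r, rp = stats.pearsonr(z, age)

    sign_r = -1.0 if r < 0 else 1.0

    if model is OnsetModel.LINEAR:
        res = stats.linregress(z, age)
        pred = res.slope * z + res.intercept
        return OnsetFit(
            model=model,
            params={"slope": float(res.slope),
                    "intercept": float(res.intercept)},
            pearson_r=float(r), pearson_p=float(rp),
            model_r=float(abs(r) * sign_r),
            rmse=float(np.sqrt(np.mean((age - pred) ** 2))),
            converged=True,
        )

    rng = np.random.default_rng(seed)
    lo, hi = float(age.min()), float(age.max())
    span = hi - lo
    best = None
    sign0 = -1.0 if r < 0 else 1.0   # decreasing data -> k > 0
    for i in range(n_starts):
        k0 = (1.0 + 2.0 * rng.random()) * (1.0 if sign0 < 0 else -1.0)
        m0 = float(rng.uniform(z.min(), z.max()))
        p0 = (lo - 0.1 * span, hi + 0.1 * span, k0, m0)
        try:
            popt, _ = optimize.curve_fit(
                logistic4, z, age, p0=p0, maxfev=20000
            )
        except RuntimeError:
            continue
        pred = logistic4(z, *popt)
        ssr = float(np.sum((age - pred) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt)
    if best is None:
        return OnsetFit(model=model,
                        params={"A": float("nan"), "B": float("nan"),
                                "k": float("nan"), "m": float("nan")},
                        pearson_r=float(r), pearson_p=float(rp),
                        model_r=float("nan"),
                        rmse=float("nan"), converged=False)
    ssr, (A, B, k, m) = best
    if A > B:   # canonical orientation: A <= B
        A, B, k = B, A, -k
    pred = logistic4(z, A, B, k, m)
    if np.ptp(pred) > 0:
        model_r = float(abs(stats.pearsonr(pred, age).statistic) * sign_r)
    else:
        model_r = float("nan")
    return OnsetFit(
        model=model,
        params={"A": float(A), "B": float(B), "k": float(k), "m": float(m)},
        pearson_r=float(r), pearson_p=float(rp),
        model_r=model_r,
        rmse=float(np.sqrt(ssr / len(pts))),
        converged=True,
    )
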