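"""Seeded generators for every input the analysis pipeline consumes.

Real inputs — disease gene lists, proteome sequences, reference-proteome
abundances, mutation/onset tables — come from external resources.  These
generators produce synthetic stand-ins with the statistical structure the
analysis assumes, with the ground truth recorded, so every stage of the
pipeline is testable end to end:

* protein sets whose residue composition is biased toward
  disorder-promoting (P, E, S, K, Q, G) or order-promoting
  (W, F, I, Y, V, L, C) residues, with a tunable effect size;
* log10-normal abundance tables with a known median shift between a focal
  set and the background;
* (disorder, onset-age) observations drawn from a known four-parameter
  logistic with additive Gaussian noise (default 428 observations, the
  scale of a combined neurodegeneration mutation-database export);
* pre-built comparison-outcome fixtures with a requested number of
  significant concordant calls, for exercising the signal-strength
  arithmetic.

Every generator takes one explicit seed and is bit-reproducible; no global
RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .abundance import AbundanceTable
from .enrichment import Call, ComparisonOutcome
from .io_sets import CANONICAL, Direction, Disease, ProteinRecord, ProteinSet
from .onset import logistic4

#: residues over-represented in intrinsically disordered regions
DISORDER_PROMOTING = "PESKQG"
#: residues over-represented in folded cores
ORDER_PROMOTING = "WFIYVLC"

DEFAULT_EFFECT_SIZE = 0.25
DEFAULT_LENGTH_RANGE = (100, 400)

# log10-normal reference-proteome abundance model (arbitrary units):
# mean 1.5, sd 0.8 in log10 space spans the ~4 orders of magnitude of a
# typical deep proteome quantification.
DEFAULT_ABUNDANCE_LOG10_MEAN = 1.5
DEFAULT_ABUNDANCE_LOG10_SD = 0.8


@dataclass(frozen=True)
class CompositionModel:
    """Residue sampling weights + uniform length range for one preset."""

    name: str
    residue_weights: dict[str, float]
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE

    def __post_init__(self) -> None:
        if set(self.residue_weights) != set(CANONICAL):
            raise ValueError(
                f"model {self.name!r}: weights must cover exactly the 20 "
                f"canonical residues"
            )
        total = sum(self.residue_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"model {self.name!r}: weights sum to {total}, not 1"
            )
        if any(w < 0 for w in self.residue_weights.values()):
            raise ValueError(f"model {self.name!r}: negative weight")
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise ValueError(
                f"model {self.name!r}: invalid length range {self.length_range}"
            )


def _biased_weights(up: str, down: str, effect: float) -> dict[str, float]:
    w = {a: 1.0 for a in CANONICAL}
    for a in up:
        w[a] *= 1.0 + effect
    for a in down:
        w[a] *= 1.0 - effect
    total = sum(w.values())
    return {a: v / total for a, v in w.items()}


def composition_preset(name: str,
                       effect_size: float = DEFAULT_EFFECT_SIZE,
                       length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
                       ) -> CompositionModel:
    """Named presets: ``disordered``, ``ordered``, ``uniform``.

    ``effect_size`` multiplies the promoted residues' weights by
    (1 + effect) and the demoted ones by (1 - effect) before
    renormalisation; ``uniform`` ignores it.
    """
    if name == "disordered":
        w = _biased_weights(DISORDER_PROMOTING, ORDER_PROMOTING, effect_size)
    elif name == "ordered":
        w = _biased_weights(ORDER_PROMOTING, DISORDER_PROMOTING, effect_size)
    elif name == "uniform":
        w = {a: 1.0 / len(CANONICAL) for a in CANONICAL}
    else:
        raise ValueError(f"unknown composition preset {name!r}")
    return CompositionModel(name=name, residue_weights=w,
                            length_range=length_range)


def generate_set(
    model: CompositionModel,
    n: int,
    seed: int,
    set_name: str | None = None,
    disease: Disease = Disease.OTHER,
    direction: Direction = Direction.NA,
) -> ProteinSet:
    """Sample ``n`` i.i.d. sequences from the composition model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(CANONICAL))
    probs = np.array([model.residue_weights[a] for a in CANONICAL])
    lo, hi = model.length_range
    records = []
    width = len(str(n))
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=L, p=probs))
        pid = f"{model.name.upper()}{i + 1:0{width}d}"
        records.append(ProteinRecord(id=pid, gene=pid, sequence=seq))
    return ProteinSet(
        name=set_name or f"{model.name}_n{n}_s{seed}",
        disease=disease, direction=direction, records=records,
    )


@dataclass(frozen=True)
class AbundanceGroundTruth:
    background_n: int
    set_n: int
    log10_shift: float
    log10_mean: float
    log10_sd: float
    seed: int


def generate_abundance(
    background_n: int,
    set_n: int,
    log10_shift: float,
    seed: int,
    log10_mean: float = DEFAULT_ABUNDANCE_LOG10_MEAN,
    log10_sd: float = DEFAULT_ABUNDANCE_LOG10_SD,
    set_name: str = "synthetic_set",
) -> tuple[AbundanceTable, ProteinSet, AbundanceGroundTruth]:
    """Log10-normal background plus a focal set shifted by ``log10_shift``.

    Background proteins are named BG0001..; the focal set's members carry
    their own ids and abundances drawn from the shifted distribution.  The
    focal proteins are given short placeholder sequences (the abundance
    stage never reads them).
    """
    if background_n < 1 or set_n < 1:
        raise ValueError("background_n and set_n must be >= 1")
    rng = np.random.default_rng(seed)
    raw: dict[str, float] = {}
    wb = len(str(background_n))
    for i in range(background_n):
        raw[f"BG{i + 1:0{wb}d}"] = 10.0 ** rng.normal(log10_mean, log10_sd)
    records = []
    ws = len(str(set_n))
    for i in range(set_n):
        pid = f"SET{i + 1:0{ws}d}"
        raw[pid] = 10.0 ** rng.normal(log10_mean + log10_shift, log10_sd)
        records.append(ProteinRecord(id=pid, gene=pid, sequence="M" * 20))
    table = AbundanceTable.from_raw(raw)
    pset = ProteinSet(name=set_name, disease=Disease.OTHER,
                      direction=Direction.NA, records=records)
    truth = AbundanceGroundTruth(background_n, set_n, log10_shift,
                                 log10_mean, log10_sd, seed)
    return table, pset, truth


@dataclass(frozen=True)
class OnsetGeneratorSpec:
    """Ground truth for the disorder/onset generator.

    The logistic is decreasing for k > 0 (high disorder, early onset);
    defaults place onset between ~40 and ~85 years over a disorder range
    typical of B-value scores, with 2-year onset noise and 428
    observations.
    """

    A: float = 40.0           # lower onset asymptote, years
    B: float = 85.0           # upper onset asymptote, years
    k: float = 3.0            # steepness (per Z unit of disorder)
    m: float = 0.5            # midpoint, Z units
    noise_sd: float = 2.0     # years
    n_mutations: int = 428
    sd_range: tuple[float, float] = (0.30, 0.70)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_mutations < 4:
            raise ValueError("n_mutations must be >= 4")
        lo, hi = self.sd_range
        if not hi > lo:
            raise ValueError("sd_range must be increasing")


def generate_onset(
    spec: OnsetGeneratorSpec, seed: int
) -> list[tuple[float, float]]:
    """Draw (disorder, onset-age) pairs from the spec's logistic.

    Disorder is uniform over ``sd_range``; the logistic is evaluated on the
    Z-normalised disorder values, and Gaussian noise (``noise_sd`` years)
    is added to the ages, truncated below at 0.
    """
    rng = np.random.default_rng(seed)
    sd = rng.uniform(*spec.sd_range, size=spec.n_mutations)
    z = (sd - sd.mean()) / sd.std(ddof=1)
    age = logistic4(z, spec.A, spec.B, spec.k, spec.m)
    if spec.noise_sd > 0:
        age = age + rng.normal(0.0, spec.noise_sd, size=spec.n_mutations)
    age = np.maximum(age, 0.0)
    return list(zip(sd.tolist(), age.tolist()))


def make_fixture_matrix(
    n_significant_concordant: int,
    n_total: int,
    direction: str | Call = "signal",
    seed: int = 0,
    alpha: float = 1e-5,
    feature_class: str = "disorder",
) -> list[ComparisonOutcome]:
    """Comparison-outcome fixture with a requested significant count.

    Emits ``n_total`` outcomes of which ``n_significant_concordant`` are
    significant (p well below ``alpha``) and concordant in the requested
    direction (``"signal"`` -> the signal set enriched, ``"negative"`` ->
    the negative set); the remainder are non-significant.  Deterministic
    under ``seed`` (which only jitters the reported p-values).
    """
    if not 0 <= n_significant_concordant <= n_total:
        raise ValueError(
            "n_significant_concordant must lie in [0, n_total]"
        )
    if isinstance(direction, Call):
        call = direction
    elif direction in ("signal", "A", "A_ENRICHED"):
        call = Call.A_ENRICHED
    elif direction in ("negative", "B", "B_ENRICHED"):
        call = Call.B_ENRICHED
    else:
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_total):
        significant = i < n_significant_concordant
        if significant:
            p = float(alpha * 10.0 ** (-1 - 2 * rng.random()))
            counts = ((18, 2), (2, 18)) if call is Call.A_ENRICHED \
                else ((2, 18), (18, 2))
            odds = 81.0 if call is Call.A_ENRICHED else 1 / 81.0
            d = call
        else:
            p = float(0.2 + 0.6 * rng.random())
            counts = ((10, 10), (10, 10))
            odds = 1.0
            d = Call.NON_SIGNIFICANT
        out.append(ComparisonOutcome(
            set_a="fixture_signal", set_b="fixture_negative",
            scale_name=f"fixture_scale_{i + 1:02d}",
            feature_class=feature_class,
            direction=d, p_value=p, odds_ratio=odds, counts=counts,
        ))
    return out
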