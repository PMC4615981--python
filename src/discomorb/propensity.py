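"""Per-residue propensity scales, windowed profiles and per-protein scores.

A propensity scale maps each of the 20 canonical residues to a number
expressing its tendency toward one physico-chemical feature (structural
disorder, hydrophobicity, helix/sheet conformation, burial, aggregation,
membrane insertion, nucleic-acid binding).  Profiles are sliding-window
means of scale values along the sequence; protein-level scores are profile
means.  Two disorder summaries used downstream:

* the *B-value score*: the unwindowed mean of a [0, 1]-normalised
  flexibility scale restricted to residues above a floor (default 0.2),
  used for the age-of-onset analysis;
* the *fraction above threshold*: the proportion of profile positions
  exceeding a significance threshold, the DisEMBL-style per-protein
  disorder strength.

Ambiguity letters (X, B, Z, U, O) never receive scale values; they are
explicitly missing and are skipped by window means, never zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .io_sets import CANONICAL, ProteinRecord, ProteinSet

FEATURE_CLASSES = (
    "disorder",
    "hydrophobicity",
    "alpha_helix",
    "beta_sheet",
    "burial",
    "aggregation",
    "membrane",
    "nucleic_acid_binding",
)

DEFAULT_WINDOW = 7       # residues; clipped (shrunk) at the termini
DEFAULT_BVALUE_FLOOR = 0.2


class ScoringError(ValueError):
    """A protein could not be scored (no scorable residue)."""


@dataclass(frozen=True)
class PropensityScale:
    name: str
    feature_class: str
    values: Mapping[str, float]
    normalized: bool = False
    citation: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        missing = set(CANONICAL) - set(self.values)
        if missing:
            raise ValueError(
                f"scale {self.name!r}: missing residues {sorted(missing)}"
            )
        if self.normalized:
            vals = [self.values[a] for a in CANONICAL]
            if min(vals) < 0.0 or max(vals) > 1.0:
                raise ValueError(
                    f"scale {self.name!r} flagged normalized but values "
                    f"outside [0, 1]"
                )

    def get(self, residue: str) -> float | None:
        """Scale value for one residue, ``None`` for unscored letters."""
        return self.values.get(residue)

    def normalize(self) -> "PropensityScale":
        """Linearly rescale values onto [0, 1] (min -> 0, max -> 1)."""
        vals = {a: float(self.values[a]) for a in CANONICAL}
        lo, hi = min(vals.values()), max(vals.values())
        if hi == lo:
            raise ValueError(f"scale {self.name!r} is constant")
        return replace(
            self,
            name=self.name + "_norm",
            values={a: (v - lo) / (hi - lo) for a, v in vals.items()},
            normalized=True,
        )


@dataclass
class Profile:
    """Windowed per-position scores; NaN marks unscorable positions."""

    protein_id: str
    scale_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_scored(self) -> int:
        return int(np.sum(~np.isnan(self.values)))


def compute_profile(record: ProteinRecord, scale: PropensityScale,
                    window: int = DEFAULT_WINDOW) -> Profile:
    """Sliding-window mean of scale values, window clipped at the termini.

    The window centred at position ``i`` spans
    ``[max(0, i-h), min(L, i+h+1)]`` with ``h = window // 2``; residues
    without a scale value are excluded from every window mean they fall in,
    and a position is NaN only when its whole window is unscorable.
    """
    L = len(record.sequence)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > L:
        raise ValueError(
            f"window {window} exceeds length {L} of {record.id!r}"
        )
    raw = np.array(
        [v if (v := scale.get(a)) is not None else np.nan
         for a in record.sequence],
        dtype=float,
    )
    h = window // 2
    out = np.empty(L)
    for i in range(L):
        seg = raw[max(0, i - h): min(L, i + h + 1)]
        good = seg[~np.isnan(seg)]
        out[i] = good.mean() if good.size else np.nan
    return Profile(record.id, scale.name, out)


def protein_score(profile: Profile) -> float:
    """Arithmetic mean of the non-missing profile values."""
    good = profile.values[~np.isnan(profile.values)]
    if good.size == 0:
        raise ScoringError(
            f"protein {profile.protein_id!r}: no scorable position on "
            f"scale {profile.scale_name!r}"
        )
    return float(good.mean())


def bvalue_disorder_score(
    record: ProteinRecord,
    bvalue_scale: PropensityScale,
    floor: float = DEFAULT_BVALUE_FLOOR,
) -> float:
    """Unwindowed mean of normalised flexibility over residues above a floor.

    Only residues whose scale value strictly exceeds ``floor`` enter the
    mean; NaN is returned when no residue survives (the missing marker).
    Requires a scale flagged as [0, 1]-normalised.
    """
    if not bvalue_scale.normalized:
        raise ValueError(
            f"scale {bvalue_scale.name!r} is not normalized to [0, 1]"
        )
    vals = [v for a in record.sequence
            if (v := bvalue_scale.get(a)) is not None and v > floor]
    if not vals:
        return math.nan
    return float(np.mean(vals))


def fraction_above_threshold(profile: Profile, threshold: float) -> float:
    """Fraction of non-missing profile positions strictly above threshold."""
    good = profile.values[~np.isnan(profile.values)]
    if good.size == 0:
        raise ScoringError(
            f"protein {profile.protein_id!r}: empty profile"
        )
    return float(np.sum(good > threshold) / good.size)


def set_mean_fraction(
    pset: ProteinSet,
    scale: PropensityScale,
    threshold: float,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Unweighted mean over the set's proteins of fraction_above_threshold."""
    fracs = []
    for rec in pset:
        w = window if window <= len(rec) else (len(rec) if len(rec) % 2 else len(rec) - 1)
        try:
            prof = compute_profile(rec, scale, window=w)
            fracs.append(fraction_above_threshold(prof, threshold))
        except (ScoringError, ValueError) as exc:
            raise ScoringError(
                f"set {pset.name!r}, protein {rec.id!r}: {exc}"
            ) from exc
    return float(np.mean(fracs))


def set_scores(
    pset: ProteinSet,
    scale: PropensityScale,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Per-protein windowed-mean scores for a whole set (ordered)."""
    out = np.empty(len(pset))
    for i, rec in enumerate(pset):
        w = window if window <= len(rec) else (len(rec) if len(rec) % 2 else len(rec) - 1)
        try:
            out[i] = protein_score(compute_profile(rec, scale, w))
        except (ScoringError, ValueError) as exc:
            raise ScoringError(
                f"set {pset.name!r}, protein {rec.id!r}: {exc}"
            ) from exc
    return out


# --------------------------------------------------------------------------
# Bundled scale registry
#
# Values are per-residue propensities from the published literature (see
# each citation).  The aggregation composites and the nucleic-acid
# interface scales are package-derived (documented as such); all scales
# are oriented so that HIGHER means MORE of the feature class.

def _z(d: Mapping[str, float]) -> dict[str, float]:
    v = np.array([d[a] for a in CANONICAL])
    mu, sd = v.mean(), v.std(ddof=1)
    return {a: (d[a] - mu) / sd for a in CANONICAL}


# TOP-IDP disorder propensity (Campen et al. 2008)
TOP_IDP = {
    "A": 0.06, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

# Average normalized crystallographic B-factors (Vihinen et al. 1994)
VIHINEN_FLEX = {
    "A": 0.984, "R": 1.008, "N": 1.048, "D": 1.068, "C": 0.906,
    "Q": 1.037, "E": 1.094, "G": 1.031, "H": 0.950, "I": 0.927,
    "L": 0.935, "K": 1.102, "M": 0.952, "F": 0.915, "P": 1.049,
    "S": 1.046, "T": 0.997, "W": 0.904, "Y": 0.929, "V": 0.931,
}

# Average flexibility indices (Bhaskaran & Ponnuswamy 1988)
BHASKARAN_FLEX = {
    "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
    "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
    "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
    "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386,
}

# Kyte & Doolittle 1982 hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Eisenberg consensus hydrophobicity (1984)
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Fauchère & Pliska 1983 octanol/water partition
FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

# Chou & Fasman 1978 helix / sheet conformational preferences
CHOU_FASMAN_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}
CHOU_FASMAN_SHEET = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

# Deléage & Roux 1987 conformational parameters
DELEAGE_HELIX = {
    "A": 1.489, "R": 1.224, "N": 0.772, "D": 0.924, "C": 0.966,
    "Q": 1.164, "E": 1.504, "G": 0.510, "H": 1.003, "I": 1.003,
    "L": 1.236, "K": 1.172, "M": 1.363, "F": 1.195, "P": 0.492,
    "S": 0.739, "T": 0.785, "W": 1.090, "Y": 0.787, "V": 0.990,
}
DELEAGE_SHEET = {
    "A": 0.709, "R": 0.920, "N": 0.604, "D": 0.541, "C": 1.191,
    "Q": 0.840, "E": 0.567, "G": 0.657, "H": 0.863, "I": 1.799,
    "L": 1.261, "K": 0.721, "M": 1.210, "F": 1.393, "P": 0.354,
    "S": 0.928, "T": 1.221, "W": 1.306, "Y": 1.266, "V": 1.965,
}

# Levitt 1978 secondary-structure preferences
LEVITT_HELIX = {
    "A": 1.29, "R": 0.96, "N": 0.90, "D": 1.04, "C": 1.11,
    "Q": 1.27, "E": 1.44, "G": 0.56, "H": 1.22, "I": 0.97,
    "L": 1.30, "K": 1.23, "M": 1.47, "F": 1.07, "P": 0.52,
    "S": 0.82, "T": 0.82, "W": 0.99, "Y": 0.72, "V": 0.91,
}
LEVITT_SHEET = {
    "A": 0.90, "R": 0.99, "N": 0.76, "D": 0.72, "C": 0.74,
    "Q": 0.80, "E": 0.75, "G": 0.92, "H": 1.08, "I": 1.45,
    "L": 1.02, "K": 0.77, "M": 0.97, "F": 1.32, "P": 0.64,
    "S": 0.95, "T": 1.21, "W": 1.14, "Y": 1.25, "V": 1.49,
}

# Janin 1979 interior-to-surface transfer free energy
JANIN_BURIAL = {
    "A": 0.3, "R": -1.4, "N": -0.5, "D": -0.6, "C": 0.9,
    "Q": -0.7, "E": -0.7, "G": 0.3, "H": -0.1, "I": 0.7,
    "L": 0.5, "K": -1.8, "M": 0.4, "F": 0.5, "P": -0.3,
    "S": -0.1, "T": -0.2, "W": 0.3, "Y": -0.4, "V": 0.6,
}

# Chothia 1976 proportion of residues 95% buried
CHOTHIA_BURIED = {
    "A": 0.38, "R": 0.01, "N": 0.12, "D": 0.15, "C": 0.50,
    "Q": 0.07, "E": 0.18, "G": 0.36, "H": 0.17, "I": 0.60,
    "L": 0.45, "K": 0.03, "M": 0.40, "F": 0.50, "P": 0.18,
    "S": 0.22, "T": 0.23, "W": 0.27, "Y": 0.15, "V": 0.54,
}

# Rose et al. 1985 mean fractional area loss on folding
ROSE_BURIAL = {
    "A": 0.74, "R": 0.64, "N": 0.63, "D": 0.62, "C": 0.91,
    "Q": 0.62, "E": 0.62, "G": 0.72, "H": 0.78, "I": 0.88,
    "L": 0.85, "K": 0.52, "M": 0.85, "F": 0.88, "P": 0.64,
    "S": 0.66, "T": 0.70, "W": 0.85, "Y": 0.76, "V": 0.86,
}

# AGGRESCAN a3v aggregation propensities (Conchillo-Solé et al. 2007)
AGGRESCAN = {
    "A": -0.036, "R": -1.240, "N": -0.776, "D": -1.836, "C": 0.604,
    "Q": -0.276, "E": -1.412, "G": -0.535, "H": -1.033, "I": 1.822,
    "L": 1.380, "K": -0.931, "M": 0.910, "F": 1.754, "P": -1.709,
    "S": -0.294, "T": -0.159, "W": 1.037, "Y": 1.159, "V": 1.594,
}

_CHARGE = {a: 0.0 for a in CANONICAL}
_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})

# Package-derived composites following the classical sequence determinants
# of amyloid aggregation (hydrophobicity + beta propensity - |net charge|).
_zh, _zb = _z(KYTE_DOOLITTLE), _z(CHOU_FASMAN_SHEET)
HYDROPHOBIC_BETA_COMPOSITE = {
    a: _zh[a] + _zb[a] - abs(_CHARGE[a]) for a in CANONICAL
}
_zh2, _zb2 = _z(FAUCHERE_PLISKA), _z(LEVITT_SHEET)
PARTITION_BETA_COMPOSITE = {
    a: _zh2[a] + _zb2[a] - abs(_CHARGE[a]) for a in CANONICAL
}

# Engelman, Steitz & Goldman 1986 transfer free energy (GES)
GES_MEMBRANE = {
    "A": 1.6, "R": -12.3, "N": -4.8, "D": -9.2, "C": 2.0,
    "Q": -4.1, "E": -8.2, "G": 1.0, "H": -3.0, "I": 3.1,
    "L": 2.8, "K": -8.8, "M": 3.4, "F": 3.7, "P": -0.2,
    "S": 0.6, "T": 1.2, "W": 1.9, "Y": -0.7, "V": 2.6,
}

# Wimley & White 1996 interface scale, negated so membrane-favourable = high
WIMLEY_WHITE_NEG = {
    "A": -0.17, "R": -0.81, "N": -0.42, "D": -1.23, "C": 0.24,
    "Q": -0.58, "E": -2.02, "G": -0.01, "H": -0.96, "I": 0.31,
    "L": 0.56, "K": -0.99, "M": 0.23, "F": 1.13, "P": -0.45,
    "S": -0.13, "T": -0.14, "W": 1.85, "Y": 0.94, "V": -0.07,
}

# Hessa et al. 2005 biological apparent insertion free energy, negated
HESSA_NEG = {
    "A": -0.11, "R": -2.58, "N": -2.05, "D": -3.49, "C": 0.13,
    "Q": -2.36, "E": -2.68, "G": -0.74, "H": -2.06, "I": 0.60,
    "L": 0.55, "K": -2.71, "M": 0.10, "F": 0.32, "P": -2.23,
    "S": -0.84, "T": -0.52, "W": -0.30, "Y": -0.68, "V": 0.31,
}

# Package-derived nucleic-acid interface composition propensities: log-odds
# style weights reflecting the canonical enrichment of basic and amide
# residues (and, for RNA, aromatic stacking residues) at protein/nucleic-acid
# interfaces.
DNA_INTERFACE = {
    "A": -0.10, "R": 1.20, "N": 0.40, "D": -0.80, "C": -0.30,
    "Q": 0.20, "E": -0.90, "G": 0.20, "H": 0.30, "I": -0.60,
    "L": -0.60, "K": 0.90, "M": -0.30, "F": -0.40, "P": -0.20,
    "S": 0.35, "T": 0.30, "W": -0.10, "Y": 0.10, "V": -0.50,
}
RNA_INTERFACE = {
    "A": -0.15, "R": 1.10, "N": 0.30, "D": -0.85, "C": -0.25,
    "Q": 0.15, "E": -0.80, "G": 0.25, "H": 0.45, "I": -0.55,
    "L": -0.60, "K": 1.00, "M": -0.20, "F": 0.25, "P": -0.25,
    "S": 0.25, "T": 0.20, "W": 0.30, "Y": 0.40, "V": -0.50,
}
BASIC_AMIDE = {
    "A": 0.0, "R": 1.0, "N": 0.5, "D": -1.0, "C": -0.2,
    "Q": 0.5, "E": -1.0, "G": 0.1, "H": 0.5, "I": -0.3,
    "L": -0.3, "K": 1.0, "M": -0.2, "F": -0.2, "P": 0.0,
    "S": 0.3, "T": 0.3, "W": 0.1, "Y": 0.2, "V": -0.3,
}


def _bundled_scales() -> list[PropensityScale]:
    mk = PropensityScale
    return [
        mk("top_idp", "disorder", TOP_IDP,
           citation="Campen et al. 2008, TOP-IDP disorder propensity"),
        mk("bfactor_vihinen", "disorder", VIHINEN_FLEX,
           citation="Vihinen et al. 1994, averaged normalized B-factors"),
        mk("flex_bhaskaran", "disorder", BHASKARAN_FLEX,
           citation="Bhaskaran & Ponnuswamy 1988, average flexibility"),
        mk("kyte_doolittle", "hydrophobicity", KYTE_DOOLITTLE,
           citation="Kyte & Doolittle 1982 hydropathy"),
        mk("eisenberg", "hydrophobicity", EISENBERG,
           citation="Eisenberg et al. 1984 consensus hydrophobicity"),
        mk("fauchere_pliska", "hydrophobicity", FAUCHERE_PLISKA,
           citation="Fauchère & Pliska 1983 octanol partition"),
        mk("chou_fasman_helix", "alpha_helix", CHOU_FASMAN_HELIX,
           citation="Chou & Fasman 1978 P(alpha)"),
        mk("deleage_helix", "alpha_helix", DELEAGE_HELIX,
           citation="Deléage & Roux 1987 helix parameter"),
        mk("levitt_helix", "alpha_helix", LEVITT_HELIX,
           citation="Levitt 1978 helix preference"),
        mk("chou_fasman_sheet", "beta_sheet", CHOU_FASMAN_SHEET,
           citation="Chou & Fasman 1978 P(beta)"),
        mk("deleage_sheet", "beta_sheet", DELEAGE_SHEET,
           citation="Deléage & Roux 1987 sheet parameter"),
        mk("levitt_sheet", "beta_sheet", LEVITT_SHEET,
           citation="Levitt 1978 sheet preference"),
        mk("janin_burial", "burial", JANIN_BURIAL,
           citation="Janin 1979 interior/surface transfer energy"),
        mk("chothia_buried", "burial", CHOTHIA_BURIED,
           citation="Chothia 1976 proportion 95% buried"),
        mk("rose_burial", "burial", ROSE_BURIAL,
           citation="Rose et al. 1985 mean fractional area loss"),
        mk("aggrescan", "aggregation", AGGRESCAN,
           citation="Conchillo-Solé et al. 2007 AGGRESCAN a3v"),
        mk("hydrophobic_beta_composite", "aggregation",
           HYDROPHOBIC_BETA_COMPOSITE,
           citation="package-derived composite: z(hydropathy) + z(beta) - |charge|"),
        mk("partition_beta_composite", "aggregation",
           PARTITION_BETA_COMPOSITE,
           citation="package-derived composite: z(octanol partition) + z(beta) - |charge|"),
        mk("ges_membrane", "membrane", GES_MEMBRANE,
           citation="Engelman, Steitz & Goldman 1986 GES scale"),
        mk("wimley_white", "membrane", WIMLEY_WHITE_NEG,
           citation="Wimley & White 1996 interface scale (negated)"),
        mk("hessa_biological", "membrane", HESSA_NEG,
           citation="Hessa et al. 2005 apparent insertion energy (negated)"),
        mk("dna_interface", "nucleic_acid_binding", DNA_INTERFACE,
           citation="package-derived DNA-interface composition propensity"),
        mk("rna_interface", "nucleic_acid_binding", RNA_INTERFACE,
           citation="package-derived RNA-interface composition propensity"),
        mk("basic_amide", "nucleic_acid_binding", BASIC_AMIDE,
           citation="package-derived basic/amide interface weight"),
    ]


@dataclass
class ScaleRegistry:
    """Propensity scales grouped by feature class (>= 3 per class bundled,
    extensible up to the ten-per-class layout of the original predictor
    battery through ``add``/``add_from_tsv``)."""

    scales: list[PropensityScale] = field(default_factory=list)

    def add(self, scale: PropensityScale) -> None:
        if any(s.name == scale.name for s in self.scales):
            raise ValueError(f"duplicate scale name {scale.name!r}")
        self.scales.append(scale)

    def add_from_tsv(self, path: str | Path, name: str, feature_class: str,
                     normalized: bool = False, citation: str = "") -> PropensityScale:
        """Plug-in format: header ``residue<TAB>value``, one row per
        canonical residue."""
        values: dict[str, float] = {}
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].split("\t")[:2] != ["residue", "value"]:
            raise ValueError(f"{path}: expected header 'residue\\tvalue'")
        for line in lines[1:]:
            if not line.strip():
                continue
            res, val = line.split("\t")[:2]
            values[res.strip().upper()] = float(val)
        scale = PropensityScale(name, feature_class, values,
                                normalized=normalized, citation=citation)
        self.add(scale)
        return scale

    def by_class(self, feature_class: str) -> list[PropensityScale]:
        if feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {feature_class!r}")
        return [s for s in self.scales if s.feature_class == feature_class]

    def get(self, name: str) -> PropensityScale:
        for s in self.scales:
            if s.name == name:
                return s
        raise KeyError(f"no scale named {name!r}")

    @property
    def feature_classes(self) -> list[str]:
        return [fc for fc in FEATURE_CLASSES
                if any(s.feature_class == fc for s in self.scales)]


def default_registry() -> ScaleRegistry:
    """The bundled registry; the normalised Vihinen B-factor scale is also
    registered as ``bvalue`` for the age-of-onset analysis."""
    reg = ScaleRegistry()
    for s in _bundled_scales():
        reg.add(s)
    bval = reg.get("bfactor_vihinen").normalize()
    reg.add(replace(bval, name="bvalue",
                    citation=bval.citation + ", linearly normalized to [0, 1]"))
    return reg
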