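"""Sequence and set I/O: the gene -> isoform protein-set data model.

Disease gene lists are distributed as plain identifier lists (one id per
line), while the sequence universe is a FASTA file whose entries may carry a
``GN=`` gene tag (UniProt style).  A list entry may name either a single
protein accession or a gene symbol; gene symbols expand to *all* isoforms of
that gene, mirroring the many-isoforms-per-gene structure of a full
proteome (roughly four isoforms per gene in the human reference).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("discomorb")

#: the 20 canonical residues
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
#: tolerated ambiguity / rare letters, retained in sequences but unscored
AMBIGUOUS = "XBZUO"
_VALID = set(CANONICAL + AMBIGUOUS)

_GN_RE = re.compile(r"\bGN=(\S+)")


class Disease(str, enum.Enum):
    AD = "AD"        # Alzheimer's disease
    PD = "PD"        # Parkinson's disease
    SCZ = "SCZ"      # Schizophrenia
    CRC = "CRC"      # Colorectal cancer
    LC = "LC"        # Lung cancer
    PC = "PC"        # Prostate cancer
    OTHER = "OTHER"


class Direction(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NA = "NA"


class FastaParseError(ValueError):
    """Raised when a FASTA entry is structurally invalid."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein isoform: accession, parent gene symbol, sequence."""

    id: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid sequence letters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinSet:
    """Named, ordered collection of records for one disease/direction."""

    name: str
    disease: Disease
    direction: Direction
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"protein set {self.name!r} is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(
                    f"protein set {self.name!r}: duplicate record id {rec.id!r}"
                )
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProteinSet):
            return NotImplemented
        # membership is order-independent
        return (
            self.name == other.name
            and self.disease == other.disease
            and self.direction == other.direction
            and sorted(self.records, key=lambda r: r.id)
            == sorted(other.records, key=lambda r: r.id)
        )


def _record_from_seqio(rec) -> ProteinRecord:
    header = rec.description or rec.id
    m = _GN_RE.search(header)
    gene = m.group(1) if m else rec.id
    if len(rec.seq) == 0:
        raise FastaParseError(f"FASTA entry {rec.id!r} has an empty sequence")
    return ProteinRecord(id=rec.id, gene=gene, sequence=str(rec.seq))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace becomes the record id; a
    ``GN=<symbol>`` tag anywhere in the header sets the gene, otherwise the
    gene defaults to the id.  Line wrapping is transparent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FastaParseError(f"{path}: not a FASTA file (no '>' header)")
    records = [_record_from_seqio(r) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaParseError(f"{path}: no FASTA entries found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FastaParseError(f"{path}: duplicate record ids {dupes}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records with normalised ``>id GN=gene`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} GN={rec.gene}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def build_set(
    name: str,
    disease: Disease | str,
    direction: Direction | str,
    ids: Sequence[str],
    records: Iterable[ProteinRecord],
    isoforms: str = "all",
) -> ProteinSet:
    """Resolve a list of gene/protein ids against a record universe.

    Resolution order: exact (case-sensitive) protein id, then
    case-insensitive gene symbol.  A gene symbol pulls all its isoforms
    (``isoforms="all"``) or only the longest one (``isoforms="longest"``).
    Duplicate resolutions are dropped with a warning; unresolvable ids raise
    a ``KeyError`` listing every missing id.
    """
    if isoforms not in ("all", "longest"):
        raise ValueError(f"isoforms must be 'all' or 'longest', got {isoforms!r}")
    if not ids:
        raise ValueError(f"protein set {name!r}: empty id list")
    records = list(records)
    by_id = {r.id: r for r in records}
    by_gene: dict[str, list[ProteinRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene.upper(), []).append(r)

    chosen: list[ProteinRecord] = []
    seen: set[str] = set()
    missing: list[str] = []
    n_dup = 0
    for ident in ids:
        if ident in by_id:
            hits = [by_id[ident]]
        elif ident.upper() in by_gene:
            hits = by_gene[ident.upper()]
            if isoforms == "longest":
                hits = [max(hits, key=lambda r: (len(r.sequence), r.id))]
        else:
            missing.append(ident)
            continue
        for rec in hits:
            if rec.id in seen:
                n_dup += 1
            else:
                seen.add(rec.id)
                chosen.append(rec)
    if missing:
        raise KeyError(
            f"protein set {name!r}: unresolvable ids {missing}"
        )
    if n_dup:
        logger.warning(
            "protein set %r: %d duplicate resolutions deduplicated", name, n_dup
        )
    return ProteinSet(
        name=name,
        disease=Disease(disease),
        direction=Direction(direction),
        records=chosen,
    )


def dedupe_identical_sequences(pset: ProteinSet) -> ProteinSet:
    """Optionally collapse records with byte-identical sequences (off by
    default in the pipeline; first-seen record is kept)."""
    seen: dict[str, ProteinRecord] = {}
    for rec in pset.records:
        seen.setdefault(rec.sequence, rec)
    return ProteinSet(pset.name, pset.disease, pset.direction,
                      list(seen.values()))
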