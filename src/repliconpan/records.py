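"""Core domain records shared by every stage of the pipeline.

Coordinates are 1-based and inclusive everywhere in memory; conversions to
half-open coordinates are confined to format boundaries (GFF3 is already
1-based inclusive, so no conversion is needed there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

_NT = set("ACGTN")
_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class RepliconKind(str, Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"


@dataclass
class Replicon:
    """A chromosome or plasmid: an independently replicating DNA molecule.

    ``host_id`` groups replicons that live in the same cell (strain); it is
    the key used when pairing shared genes "from the same host".
    """

    replicon_id: str
    kind: RepliconKind
    host_id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = RepliconKind(self.kind)
        if not self.replicon_id:
            raise ValueError("replicon_id must be non-empty")
        if not self.host_id:
            raise ValueError("host_id must be non-empty")
        bad = set(self.sequence) - _NT
        if bad:
            raise ValueError(
                f"replicon {self.replicon_id}: illegal nucleotide(s) {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class Gene:
    """An annotated CDS with its nucleotide and (re-translated) protein sequence.

    The protein is always re-derived from ``cds_nt`` (bacterial code, table 11)
    with the terminal stop stripped when encoded, so composition statistics and
    clustering always agree with the nucleotide record.
    """

    gene_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    cds_nt: str
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if len(self.cds_nt) % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: CDS length not divisible by 3")
        if "N" in self.cds_nt:
            raise ValueError(
                f"gene {self.gene_id}: 'N' inside CDS (composition/CAI undefined)"
            )

    @property
    def length_nt(self) -> int:
        return len(self.cds_nt)

    @property
    def protein_length(self) -> int:
        return len(self.protein)


@dataclass
class HitRecord:
    """One row of 12-column tabular pairwise-search output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class Family:
    """A gene family: one MCL cluster, with a per-replicon member census."""

    family_id: str
    members: frozenset[str]
    census: dict[str, int] = field(default_factory=dict)  # replicon_id -> n members

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id}: empty member set")

    @property
    def size(self) -> int:
        return len(self.members)

    def replicons_present(self) -> set[str]:
        return {r for r, n in self.census.items() if n > 0}


def build_census(members: set[str], gene_index: dict[str, Gene]) -> dict[str, int]:
    census: dict[str, int] = {}
    for gid in members:
        rid = gene_index[gid].replicon_id
        census[rid] = census.get(rid, 0) + 1
    return census


def index_genes(genes: list[Gene]) -> dict[str, Gene]:
    idx: dict[str, Gene] = {}
    for g in genes:
        if g.gene_id in idx:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        idx[g.gene_id] = g
    return idx


def index_replicons(replicons: list[Replicon]) -> dict[str, Replicon]:
    idx: dict[str, Replicon] = {}
    for r in replicons:
        if r.replicon_id in idx:
            raise ValueError(f"duplicate replicon_id {r.replicon_id}")
        idx[r.replicon_id] = r
    return idx
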