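"""Readers and writers for the on-disk formats the pipeline touches.

Formats: FASTA (nucleotide and protein), GFF3 (CDS features only), 12-column
tabular pairwise-hit files, OrthoMCL-style groups text, and the replicon
manifest TSV. Readers reject malformed input rather than silently repairing
it; every writer/reader pair is the identity on valid data.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .records import Family, Gene, HitRecord, Replicon, RepliconKind

# ------------------------------------------------------------------ FASTA


def read_fasta(path: str | Path, nucleotide: bool = True) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)``.

    Sequences are uppercased; in nucleotide mode ``U`` is mapped to ``T``.
    Duplicate record ids and empty files are errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    rid: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if rid is None:
            return
        seq = "".join(chunks).upper()
        if nucleotide:
            seq = seq.replace("U", "T")
        records.append((rid, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                rid = line[1:].split()[0] if line[1:].strip() else ""
                if not rid:
                    raise ValueError(f"{path}: empty FASTA record id")
                if rid in seen:
                    raise ValueError(f"{path}: duplicate FASTA id {rid!r}")
                seen.add(rid)
                chunks = []
            else:
                if rid is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    _flush()
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------------ GFF3

BACTERIAL_TABLE = 11


def translate_cds(cds_nt: str) -> str:
    """Translate a CDS with the bacterial code (table 11), stripping the
    terminal stop when one is encoded. Internal stop codons are an error."""
    prot = str(Seq(cds_nt).translate(table=BACTERIAL_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon in CDS")
    return prot


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        attrs[k] = v
    return attrs


def read_gff(path: str | Path, replicons: dict[str, Replicon]) -> list[Gene]:
    """Read CDS features from a GFF3 file and extract their sequences.

    Coordinates are 1-based inclusive per the GFF3 standard. The CDS
    nucleotide sequence is cut from the replicon (reverse-complemented on the
    '-' strand) and the protein re-translated with the bacterial code.
    """
    path = Path(path)
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            if ftype != "CDS":
                continue
            if seqid not in replicons:
                raise ValueError(f"{path}:{lineno}: unknown replicon {seqid!r}")
            rep = replicons[seqid]
            start, end = int(start_s), int(end_s)
            if start < 1 or start > end:
                raise ValueError(f"{path}:{lineno}: bad coordinates {start}..{end}")
            if end > rep.length_bp:
                raise ValueError(
                    f"{path}:{lineno}: CDS end {end} beyond replicon end {rep.length_bp}"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_gff_attributes(attr_s)
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: CDS feature without ID attribute")
            gid = attrs["ID"]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
            seen.add(gid)
            cds = rep.sequence[start - 1 : end]
            if strand == "-":
                cds = reverse_complement(cds)
            genes.append(
                Gene(
                    gene_id=gid,
                    replicon_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    cds_nt=cds,
                    protein=translate_cds(cds),
                )
            )
    return genes


def write_gff(genes: Iterable[Gene], path: str | Path, source: str = "repliconpan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.replicon_id,
                        source,
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ------------------------------------------------------------------ tabular hits

_HIT_COLUMNS = 12


def read_hits_tab(path: str | Path) -> list[HitRecord]:
    """Read 12-column tab-separated pairwise hits (query, subject, pident,
    length, mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore).

    Self-hits are retained; the caller decides what to do with them.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(fields)}"
                )
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


# ------------------------------------------------------------------ groups text


def write_cluster_table(families: Iterable[Family], path: str | Path) -> None:
    """Write families as OrthoMCL-style groups text: ``FAM0001: geneA geneB``.

    Family ids are re-issued zero-padded in order of the sorted smallest
    member, so output is stable under input permutation."""
    fams = sorted(families, key=lambda f: min(f.members))
    seen: set[str] = set()
    for f in fams:
        dup = f.members & seen
        if dup:
            raise ValueError(f"gene(s) {sorted(dup)} listed in two families")
        seen |= f.members
    with open(path, "w") as fh:
        for i, f in enumerate(fams, 1):
            fh.write(f"FAM{i:04d}: " + " ".join(sorted(f.members)) + "\n")


def read_cluster_table(path: str | Path) -> list[Family]:
    families: list[Family] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: missing ':' separator")
            fid, members_s = line.split(":", 1)
            members = frozenset(members_s.split())
            if not members:
                raise ValueError(f"{path}:{lineno}: family {fid} has no members")
            dup = members & seen
            if dup:
                raise ValueError(f"{path}:{lineno}: gene(s) {sorted(dup)} in two families")
            seen |= members
            families.append(Family(family_id=fid.strip(), members=members))
    return families


# ------------------------------------------------------------------ manifest


def read_manifest(path: str | Path) -> list[dict[str, str]]:
    """Read the replicon manifest TSV: replicon_id, kind, host_id, fasta, gff.

    File paths in the manifest are resolved relative to the manifest's own
    directory."""
    path = Path(path)
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"replicon_id", "kind", "host_id", "fasta", "gff"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: manifest must have columns {sorted(required)}")
        for row in reader:
            row["fasta"] = str((path.parent / row["fasta"]).resolve())
            row["gff"] = str((path.parent / row["gff"]).resolve())
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty manifest")
    return rows


def load_dataset(manifest_path: str | Path) -> tuple[list[Replicon], list[Gene]]:
    """Load every replicon + annotation listed in a manifest TSV."""
    replicons: list[Replicon] = []
    genes: list[Gene] = []
    for row in read_manifest(manifest_path):
        recs = read_fasta(row["fasta"])
        seq = dict(recs).get(row["replicon_id"])
        if seq is None:
            raise ValueError(
                f"replicon {row['replicon_id']} not found in {row['fasta']}"
            )
        rep = Replicon(
            replicon_id=row["replicon_id"],
            kind=RepliconKind(row["kind"]),
            host_id=row["host_id"],
            sequence=seq,
            circular=row.get("circular", "true").lower() in ("true", "1", "yes"),
        )
        replicons.append(rep)
        genes.extend(read_gff(row["gff"], {rep.replicon_id: rep}))
    return replicons, genes
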