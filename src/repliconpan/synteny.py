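"""Syntenic shared-gene blocks between a plasmid and a chromosome, and operon
membership of shared genes.

A block is a maximal chain of homologous gene pairs that are consecutive on
BOTH replicons, tolerating up to ``max_gap_genes`` intervening non-shared
genes on either side; order-reversed (inverted) chains are allowed and
flagged. A long high-identity block is the signature of a single recent
transfer event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from .pangenome import SharedPair
from .records import Gene, index_genes


@dataclass
class SyntenyBlock:
    plasmid_id: str
    chromosome_id: str
    gene_pairs: list[tuple[str, str]]  # (plasmid gene, chromosome gene), chr order
    inverted: bool
    chromosome_span: tuple[int, int]
    plasmid_span: tuple[int, int]
    mean_nt_identity: float | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_pairs)


def _gene_ranks(genes: list[Gene], replicon_id: str) -> dict[str, int]:
    ordered = sorted(
        (g for g in genes if g.replicon_id == replicon_id), key=lambda g: (g.start, g.end)
    )
    return {g.gene_id: i for i, g in enumerate(ordered)}


def detect_blocks(
    pairs: list[tuple[str, str]],
    genes: list[Gene],
    plasmid_id: str,
    chromosome_id: str,
    max_gap_genes: int = 1,
    min_block: int = 2,
) -> list[SyntenyBlock]:
    """Chain homologous (plasmid gene, chromosome gene) pairs into blocks.

    ``pairs`` lists genes of the same family, one on each replicon. Two pairs
    chain when, on both replicons, at most ``max_gap_genes`` non-shared genes
    lie between them and the plasmid-side order is consistently parallel or
    consistently inverted relative to the chromosome order.
    """
    gene_index = index_genes(genes)
    chr_rank = _gene_ranks(genes, chromosome_id)
    pls_rank = _gene_ranks(genes, plasmid_id)
    items = sorted(
        ((chr_rank[cg], pls_rank[pg], pg, cg) for pg, cg in pairs),
        key=lambda t: t[0],
    )
    blocks: list[SyntenyBlock] = []
    chain: list[tuple[int, int, str, str]] = []
    direction = 0  # +1 parallel, -1 inverted, 0 undecided

    def flush() -> None:
        nonlocal chain, direction
        if len(chain) >= min_block:
            pgs = [gene_index[t[2]] for t in chain]
            cgs = [gene_index[t[3]] for t in chain]
            block = SyntenyBlock(
                plasmid_id=plasmid_id,
                chromosome_id=chromosome_id,
                gene_pairs=[(t[2], t[3]) for t in chain],
                inverted=(direction == -1),
                chromosome_span=(min(g.start for g in cgs), max(g.end for g in cgs)),
                plasmid_span=(min(g.start for g in pgs), max(g.end for g in pgs)),
            )
            blocks.append(block)
        chain = []
        direction = 0

    for item in items:
        if not chain:
            chain.append(item)
            continue
        prev = chain[-1]
        chr_gap = item[0] - prev[0] - 1
        pls_step = item[1] - prev[1]
        pls_gap = abs(pls_step) - 1
        step_dir = 1 if pls_step > 0 else -1
        ok = (
            chr_gap <= max_gap_genes
            and pls_gap <= max_gap_genes
            and pls_step != 0
            and (direction == 0 or step_dir == direction)
        )
        if ok:
            direction = step_dir if direction == 0 else direction
            chain.append(item)
        else:
            flush()
            chain.append(item)
    flush()
    return blocks


def nt_identity(seq_a: str, seq_b: str) -> float:
    """Global nucleotide identity in percent: 1 - edit distance over the
    longer sequence length."""
    if not seq_a or not seq_b:
        raise ValueError("cannot compute identity of an empty sequence")
    d = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(seq_a), len(seq_b)))


def mean_block_identity(block: SyntenyBlock, genes: list[Gene]) -> float:
    """Arithmetic mean of per-gene-pair global nucleotide identity."""
    gene_index = index_genes(genes)
    idents = [
        nt_identity(gene_index[pg].cds_nt, gene_index[cg].cds_nt)
        for pg, cg in block.gene_pairs
    ]
    return float(sum(idents) / len(idents))


# ------------------------------------------------------------------ operons


@dataclass
class OperonTally:
    n_shared_genes_considered: int
    n_in_operons: int
    n_operons: int
    size_min: int | None
    size_max: int | None

    def __post_init__(self) -> None:
        assert self.n_in_operons <= self.n_shared_genes_considered
        if self.size_min is not None and self.size_max is not None:
            assert self.size_min <= self.size_max


def read_operon_table(path: str | Path) -> dict[str, list[str]]:
    """Read an imported operon prediction TSV (operon_id, gene_id, position)
    into operon_id -> ordered gene list. Operons must partition genes."""
    df = pd.read_csv(path, sep="\t")
    missing = {"operon_id", "gene_id", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"gene {dup} appears in two operons")
    table: dict[str, list[str]] = {}
    for oid, grp in df.sort_values(["operon_id", "position"]).groupby("operon_id"):
        table[str(oid)] = grp["gene_id"].astype(str).tolist()
    return table


def operon_overlap(
    shared_genes: set[str],
    operon_table: dict[str, list[str]],
    exclude_gene_ids: set[str] | None = None,
) -> OperonTally:
    """Tally operon membership of shared genes.

    ``exclude_gene_ids`` removes genes (e.g. a dominating transfer block)
    before counting. An operon counts when at least 2 of its genes are shared;
    sizes are reported over shared members."""
    considered = shared_genes - (exclude_gene_ids or set())
    sizes: list[int] = []
    n_in = 0
    seen: set[str] = set()
    for oid, members in operon_table.items():
        dup = set(members) & seen
        if dup:
            raise ValueError(f"gene(s) {sorted(dup)} in two operons")
        seen |= set(members)
        shared_members = [g for g in members if g in considered]
        if len(shared_members) >= 2:
            sizes.append(len(shared_members))
            n_in += len(shared_members)
    return OperonTally(
        n_shared_genes_considered=len(considered),
        n_in_operons=n_in,
        n_operons=len(sizes),
        size_min=min(sizes) if sizes else None,
        size_max=max(sizes) if sizes else None,
    )


def pairs_between(
    partition, genes: list[Gene], plasmid_id: str, chromosome_id: str
) -> list[tuple[str, str]]:
    """All (plasmid gene, chromosome gene) same-family pairs between one
    plasmid and one chromosome, regardless of host."""
    gene_index = index_genes(genes)
    out: list[tuple[str, str]] = []
    for fid in partition.shared_family_ids():
        fam = partition.families[fid]
        pls = sorted(g for g in fam.members if gene_index[g].replicon_id == plasmid_id)
        chs = sorted(g for g in fam.members if gene_index[g].replicon_id == chromosome_id)
        for pg in pls:
            for cg in chs:
                out.append((pg, cg))
    return out


def blocks_table(blocks: list[SyntenyBlock], genes: list[Gene]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(blocks, 1):
        rows.append(
            {
                "block_id": f"BLK{i:03d}",
                "plasmid_id": b.plasmid_id,
                "chromosome_id": b.chromosome_id,
                "n_genes": b.n_genes,
                "inverted": b.inverted,
                "chromosome_start": b.chromosome_span[0],
                "chromosome_end": b.chromosome_span[1],
                "plasmid_start": b.plasmid_span[0],
                "plasmid_end": b.plasmid_span[1],
                "mean_nt_identity": mean_block_identity(b, genes),
            }
        )
    return pd.DataFrame(rows)
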