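"""Flank (promoter/terminator proxy) comparison of shared gene pairs.

For each plasmid-chromosome shared gene pair from the same host, the 200 bp
upstream and 100 bp downstream of each coding sequence are extracted
strand-aware and compared by local nucleotide alignment. A flank pair is
"similar" when identity exceeds 70% over an aligned span covering more than
50% of the shorter flank; both thresholds are parameters. Divergent upstream
flanks suggest different promoters, divergent downstream flanks different
terminators.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import NUCLEOTIDE_SCORING, align_pair
from .io import reverse_complement
from .pangenome import SharedPair
from .records import Gene, Replicon, index_genes, index_replicons


@dataclass
class FlankPairResult:
    pair_id: str
    up_similar: bool
    down_similar: bool
    up_identity: float
    up_coverage: float
    down_identity: float
    down_coverage: float
    up_truncated: bool = False
    down_truncated: bool = False

    @property
    def category(self) -> str:
        if self.up_similar and self.down_similar:
            return "both_similar"
        if not self.up_similar and self.down_similar:
            return "up_diff_only"
        if self.up_similar and not self.down_similar:
            return "down_diff_only"
        return "both_diff"


def _slice_circular(seq: str, start: int, end: int) -> str:
    """1-based inclusive slice that wraps across the origin of a circular
    sequence (verified against a doubled-sequence oracle in the tests)."""
    L = len(seq)
    start = (start - 1) % L
    end = (end - 1) % L
    if start <= end:
        return seq[start : end + 1]
    return seq[start:] + seq[: end + 1]


def extract_flanks(
    gene: Gene, replicon: Replicon, up_len: int = 200, down_len: int = 100
) -> tuple[str, str, bool, bool]:
    """Strand-aware upstream/downstream flanks of a gene.

    Returns (upstream, downstream, up_truncated, down_truncated). On circular
    replicons flanks wrap across the origin; on linear replicons they are
    truncated at the sequence ends and flagged.
    """
    if gene.end > replicon.length_bp or gene.start < 1:
        raise ValueError(f"gene {gene.gene_id}: coordinates outside replicon")
    seq = replicon.sequence
    L = replicon.length_bp

    def genomic(start: int, end: int) -> tuple[str, bool]:
        if end < start:
            return "", True
        if replicon.circular:
            if end - start + 1 >= L:  # flank longer than the molecule
                return _slice_circular(seq, start, start + L - 1 - 1), True
            return _slice_circular(seq, start, end), False
        trunc = start < 1 or end > L
        return seq[max(start, 1) - 1 : min(end, L)], trunc

    if gene.strand == "+":
        up, up_tr = genomic(gene.start - up_len, gene.start - 1)
        down, down_tr = genomic(gene.end + 1, gene.end + down_len)
    else:
        raw_up, up_tr = genomic(gene.end + 1, gene.end + up_len)
        raw_down, down_tr = genomic(gene.start - down_len, gene.start - 1)
        up = reverse_complement(raw_up)
        down = reverse_complement(raw_down)
    return up, down, up_tr, down_tr


def compare_flank(
    seq_a: str, seq_b: str, min_identity: float = 70.0, min_coverage: float = 50.0
) -> tuple[bool, float, float]:
    """Local nucleotide alignment verdict on one flank pair.

    similar <=> identity > min_identity AND the aligned span covers more than
    min_coverage % of the SHORTER flank. Empty flanks (fully truncated) are
    never similar. Returns (similar, identity, coverage_of_shorter)."""
    if not seq_a or not seq_b:
        return False, 0.0, 0.0
    res = align_pair(seq_a, seq_b, NUCLEOTIDE_SCORING)
    if res.alignment_length == 0:
        return False, 0.0, 0.0
    cov_short = res.coverage_a if len(seq_a) <= len(seq_b) else res.coverage_b
    similar = res.identity > min_identity and cov_short > min_coverage
    return similar, res.identity, cov_short


@dataclass
class FlankTally:
    n_total: int
    n_both_similar: int
    n_up_diff: int  # pairs with different upstream (regardless of downstream)
    n_down_diff: int
    n_both_diff: int

    def __post_init__(self) -> None:
        # inclusion-exclusion over "at least one flank differs"
        assert self.n_both_similar == self.n_total - (
            self.n_up_diff + self.n_down_diff - self.n_both_diff
        ), "flank tally inclusion-exclusion identity violated"

    def as_dict(self) -> dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_both_similar": self.n_both_similar,
            "n_up_diff": self.n_up_diff,
            "n_down_diff": self.n_down_diff,
            "n_both_diff": self.n_both_diff,
        }


def tally_from_counts(
    n_total: int, n_up_diff: int, n_down_diff: int, n_both_diff: int
) -> FlankTally:
    """Build a tally from the three "different" counts, deriving the number of
    fully similar pairs by inclusion-exclusion."""
    return FlankTally(
        n_total=n_total,
        n_both_similar=n_total - (n_up_diff + n_down_diff - n_both_diff),
        n_up_diff=n_up_diff,
        n_down_diff=n_down_diff,
        n_both_diff=n_both_diff,
    )


def classify_pairs(
    pairs: list[SharedPair],
    genes: list[Gene],
    replicons: list[Replicon],
    up_len: int = 200,
    down_len: int = 100,
    min_identity: float = 70.0,
    min_coverage: float = 50.0,
) -> tuple[list[FlankPairResult], FlankTally]:
    """Per-pair flank verdicts plus the aggregate tally.

    Pairs whose two genes sit on the same replicon are excluded (the
    comparison is plasmid vs chromosome by construction of the pair list)."""
    gene_index = index_genes(genes)
    rep_index = index_replicons(replicons)
    results: list[FlankPairResult] = []
    for pair in pairs:
        pg = gene_index[pair.plasmid_gene]
        cg = gene_index[pair.chromosome_gene]
        if pg.replicon_id == cg.replicon_id:
            continue
        up_p, down_p, ptr_u, ptr_d = extract_flanks(pg, rep_index[pg.replicon_id], up_len, down_len)
        up_c, down_c, ctr_u, ctr_d = extract_flanks(cg, rep_index[cg.replicon_id], up_len, down_len)
        up_sim, up_id, up_cov = compare_flank(up_p, up_c, min_identity, min_coverage)
        dn_sim, dn_id, dn_cov = compare_flank(down_p, down_c, min_identity, min_coverage)
        results.append(
            FlankPairResult(
                pair_id=pair.pair_id,
                up_similar=up_sim,
                down_similar=dn_sim,
                up_identity=up_id,
                up_coverage=up_cov,
                down_identity=dn_id,
                down_coverage=dn_cov,
                up_truncated=ptr_u or ctr_u,
                down_truncated=ptr_d or ctr_d,
            )
        )
    n_total = len(results)
    n_up_diff = sum(1 for r in results if not r.up_similar)
    n_down_diff = sum(1 for r in results if not r.down_similar)
    n_both_diff = sum(1 for r in results if not r.up_similar and not r.down_similar)
    tally = tally_from_counts(n_total, n_up_diff, n_down_diff, n_both_diff)
    return results, tally


def results_table(results: list[FlankPairResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": r.pair_id,
                "category": r.category,
                "up_similar": r.up_similar,
                "down_similar": r.down_similar,
                "up_identity": r.up_identity,
                "up_coverage": r.up_coverage,
                "down_identity": r.down_identity,
                "down_coverage": r.down_coverage,
                "up_truncated": r.up_truncated,
                "down_truncated": r.down_truncated,
            }
            for r in results
        ]
    )
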