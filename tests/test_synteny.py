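import numpy as np
import pandas as pd
import pytest

from repliconpan.records import Gene
from repliconpan.synteny import (
    OperonTally,
    detect_blocks,
    mean_block_identity,
    nt_identity,
    operon_overlap,
    read_operon_table,
)


def _gene(gid, rid, rank, strand="+", cds=None):
    start = 1000 * rank + 1
    cds = cds or ("ATG" + "AAA" * 50 + "TAA")
    return Gene(gid, rid, start, start + len(cds) - 1, strand, cds, "M" + "K" * 50)


def _layout(n_chr_genes, n_pls_genes):
    genes = [_gene(f"c{i}", "CHR", i) for i in range(n_chr_genes)]
    genes += [_gene(f"p{i}", "PLS", i) for i in range(n_pls_genes)]
    return genes


class TestDetectBlocks:
    def test_three_adjacent_pairs_one_block(self):
        genes = _layout(5, 5)
        pairs = [("p1", "c1"), ("p2", "c2"), ("p3", "c3")]
        blocks = detect_blocks(pairs, genes, "PLS", "CHR")
        assert len(blocks) == 1
        assert blocks[0].n_genes == 3
        assert not blocks[0].inverted

    def test_gap_beyond_max_splits_blocks(self):
        genes = _layout(10, 10)
        # two non-shared genes between c2 and c5 on the chromosome
        pairs = [("p1", "c1"), ("p2", "c2"), ("p5", "c5"), ("p6", "c6")]
        blocks = detect_blocks(pairs, genes, "PLS", "CHR", max_gap_genes=1)
        assert sorted(b.n_genes for b in blocks) == [2, 2]
        merged = detect_blocks(pairs, genes, "PLS", "CHR", max_gap_genes=2)
        assert [b.n_genes for b in merged] == [4]

    def test_inverted_chain_detected_and_flagged(self):
        genes = _layout(6, 6)
        pairs = [("p5", "c1"), ("p4", "c2"), ("p3", "c3")]
        blocks = detect_blocks(pairs, genes, "PLS", "CHR")
        assert len(blocks) == 1 and blocks[0].inverted

    def test_invariance_under_replicon_order_reversal(self):
        genes = _layout(6, 6)
        pairs = [("p1", "c1"), ("p2", "c2"), ("p3", "c3")]
        fwd = detect_blocks(pairs, genes, "PLS", "CHR")
        # reverse plasmid gene order by inverting coordinates
        flipped = []
        for g in genes:
            if g.replicon_id == "PLS":
                start = 100_000 - g.end
                flipped.append(
                    Gene(g.gene_id, "PLS", start, start + (g.end - g.start), g.strand,
                         g.cds_nt, g.protein)
                )
            else:
                flipped.append(g)
        rev = detect_blocks(pairs, flipped, "PLS", "CHR")
        assert len(rev) == len(fwd) == 1
        assert rev[0].n_genes == fwd[0].n_genes
        assert rev[0].inverted != fwd[0].inverted

    def test_min_block_of_two(self):
        genes = _layout(4, 4)
        blocks = detect_blocks([("p1", "c1"), ("p2", "c2")], genes, "PLS", "CHR")
        assert len(blocks) == 1 and blocks[0].n_genes == 2


class TestBlockIdentity:
    def test_identical_copies_full_identity(self):
        genes = _layout(3, 3)
        blocks = detect_blocks([("p1", "c1"), ("p2", "c2")], genes, "PLS", "CHR")
        assert mean_block_identity(blocks[0], genes) == 100.0

    def test_constructed_mean(self):
        cds_a = "ATG" + "AAA" * 30 + "TAA"
        mutated = list(cds_a)
        # mutate 10% of positions of one copy -> 90% identity
        idx = np.linspace(3, len(cds_a) - 4, round(0.1 * len(cds_a))).astype(int)
        for i in idx:
            mutated[i] = "C" if mutated[i] != "C" else "G"
        cds_b = "".join(mutated)
        genes = [
            _gene("c1", "CHR", 1, cds=cds_a),
            _gene("c2", "CHR", 2, cds=cds_a),
            _gene("p1", "PLS", 1, cds=cds_b),
            _gene("p2", "PLS", 2, cds=cds_a),
        ]
        blocks = detect_blocks([("p1", "c1"), ("p2", "c2")], genes, "PLS", "CHR")
        expected = (nt_identity(cds_a, cds_b) + 100.0) / 2
        assert mean_block_identity(blocks[0], genes) == pytest.approx(expected)

    def test_identity_matches_per_position_count_on_mutated_copies(self):
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list("ACGT"), 300))
        mutated = list(seq)
        muts = 0
        for i in range(len(mutated)):
            if rng.random() < 0.07:
                mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
                muts += 1
        expected = 100.0 * (len(seq) - muts) / len(seq)
        assert nt_identity(seq, "".join(mutated)) == pytest.approx(expected)


class TestOperonOverlap:
    def _table(self):
        return {
            "OP1": ["s1", "s2", "s3", "s4"],
            "OP2": ["s5", "x1", "x2"],
            "OP3": ["x3", "x4"],
        }

    def test_four_shared_genes_one_operon(self):
        tally = operon_overlap({"s1", "s2", "s3", "s4"}, {"OP1": ["s1", "s2", "s3", "s4"]})
        assert tally.n_in_operons == 4
        assert tally.n_operons == 1
        assert tally.size_min == tally.size_max == 4

    def test_single_shared_member_operon_not_counted(self):
        tally = operon_overlap({"s1", "s2", "s3", "s4", "s5", "s9"}, self._table())
        assert tally.n_operons == 1  # only OP1 has >= 2 shared members
        assert tally.n_shared_genes_considered == 6
        assert tally.n_in_operons == 4

    def test_exclusions_applied(self):
        tally = operon_overlap(
            {"s1", "s2", "s3", "s4"}, self._table(), exclude_gene_ids={"s3", "s4"}
        )
        assert tally.n_shared_genes_considered == 2
        assert tally.n_in_operons == 2

    def test_gene_in_two_operons_rejected(self):
        with pytest.raises(ValueError):
            operon_overlap({"s1"}, {"OP1": ["s1", "a"], "OP2": ["a", "b"]})

    def test_planted_quota_recovered(self, small_sim, small_cluster, small_partition):
        family_of = {g: f.family_id for f in small_cluster.families for g in f.members}
        shared = {
            g
            for f in small_cluster.families
            if small_partition.labels[f.family_id].shared
            for g in f.members
        }
        table = {
            oid: grp["gene_id"].tolist()
            for oid, grp in small_sim.truth.operon_table.groupby("operon_id")
        }
        tally = operon_overlap(shared, table)
        planted = small_sim.truth.operon_truth
        assert tally.n_in_operons == planted["n_in_operons"]
        assert tally.n_operons == planted["n_operons"]
        assert tally.size_min == planted["size_min"]
        assert tally.size_max == planted["size_max"]

    def test_read_operon_table_round_trip(self, tmp_path, small_sim):
        p = tmp_path / "op.tsv"
        small_sim.truth.operon_table.to_csv(p, sep="\t", index=False)
        table = read_operon_table(p)
        assert sum(len(v) for v in table.values()) == len(small_sim.truth.operon_table)
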