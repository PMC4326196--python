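import numpy as np
import pytest

from repliconpan.flanks import (
    classify_pairs,
    compare_flank,
    extract_flanks,
    tally_from_counts,
)
from repliconpan.io import reverse_complement
from repliconpan.pangenome import classify_families, shared_pairs_same_host
from repliconpan.records import Gene, Replicon, RepliconKind
from repliconpan.simulate import SimConfig, simulate_pangenome


def _rep(seq, circular=False):
    return Replicon("R1", RepliconKind.CHROMOSOME, "H1", seq, circular=circular)


def _gene(start, end, strand="+"):
    length = end - start + 1
    return Gene("g1", "R1", start, end, strand, "ATG" + "A" * (length - 6) + "TAA", "M")


class TestExtractFlanks:
    def test_plus_strand_upstream_is_preceding_bases(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        rep = _rep(seq)
        gene = _gene(201, 500)
        up, down, _, _ = extract_flanks(gene, rep)
        assert up == seq[:200]
        assert down == seq[500:600]

    def test_minus_strand_upstream_is_revcomp_after_end(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        rep = _rep(seq)
        gene = _gene(201, 500, strand="-")
        up, down, _, _ = extract_flanks(gene, rep)
        assert up == reverse_complement(seq[500:700])
        assert down == reverse_complement(seq[100:200])

    def test_circular_wrap_matches_doubled_sequence_oracle(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 600))
        rep = _rep(seq, circular=True)
        gene = _gene(50, 349)  # upstream of 200 wraps the origin
        up, down, up_tr, _ = extract_flanks(gene, rep)
        doubled = seq + seq
        # positions 50-200 .. 49 on the circle == doubled[len-? ...]
        assert up == doubled[600 + 49 - 200 : 600 + 49]
        assert not up_tr

    def test_linear_truncation_flagged(self):
        rep = _rep("A" * 300)
        gene = _gene(51, 251)
        up, down, up_tr, down_tr = extract_flanks(gene, rep)
        assert len(up) == 50 and up_tr
        assert len(down) == 49 and down_tr

    def test_bad_coordinates_rejected(self):
        rep = _rep("A" * 100)
        with pytest.raises(ValueError):
            extract_flanks(_gene(50, 500), rep)


class TestCompareFlank:
    def test_identical_flanks_similar(self):
        rng = np.random.default_rng(3)
        s = "".join(rng.choice(list("ACGT"), 200))
        similar, ident, cov = compare_flank(s, s)
        assert similar and ident == 100.0 and cov == 100.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 200))
        b = "".join(rng.choice(list("ACGT"), 200))
        assert compare_flank(a, b) == compare_flank(b, a)

    def test_random_pairs_never_called_similar(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), 200))
            b = "".join(rng.choice(list("ACGT"), 200))
            similar, _, _ = compare_flank(a, b)
            assert not similar

    def test_heavily_randomized_copy_not_similar(self):
        rng = np.random.default_rng(6)
        a = list("".join(rng.choice(list("ACGT"), 200)))
        b = list(a)
        idx = rng.choice(200, size=80, replace=False)  # 40% of positions
        for i in idx:
            b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        similar, _, _ = compare_flank("".join(a), "".join(b))
        assert not similar

    def test_empty_flank_verdict_different(self):
        assert compare_flank("", "ACGT")[0] is False


class TestTally:
    def test_inclusion_exclusion_on_printed_fixture(self):
        tally = tally_from_counts(419, 240, 246, 206)
        assert tally.n_both_similar == 139

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(AssertionError):
            from repliconpan.flanks import FlankTally

            FlankTally(n_total=10, n_both_similar=5, n_up_diff=3, n_down_diff=3, n_both_diff=0)


class TestClassifyPairs:
    def test_planted_flank_classes_recovered(self, small_sim, small_partition):
        pairs = shared_pairs_same_host(small_partition, small_sim.genes, small_sim.replicons)
        results, tally = classify_pairs(pairs, small_sim.genes, small_sim.replicons)
        truth = {
            (r.plasmid_gene, r.chromosome_gene): r.flank_class
            for r in small_sim.truth.pairs.itertuples()
        }
        assert len(results) == len(truth)
        for r in results:
            key = tuple(r.pair_id.split("|")[2:4])
            assert r.category == truth[key]
        planted = small_sim.truth.flank_class_counts()
        assert tally.n_both_similar == planted.get("both_similar", 0)
        assert tally.n_both_diff == planted.get("both_diff", 0)

    def test_all_identical_flanks_all_similar(self):
        cfg = SimConfig(
            n_chromosomes=3,
            n_plasmids=2,
            n_chr_core=2,
            n_chr_distributed=0,
            n_chr_unique=2,
            n_pls_distributed=0,
            n_pls_unique=2,
            n_shared=5,
            flank_class_counts=(5, 0, 0, 0),
            seed=21,
        )
        sim = simulate_pangenome(cfg)
        from repliconpan.cluster import cluster_pipeline

        fams = cluster_pipeline(sim.genes).families
        part = classify_families(fams, sim.replicons)
        pairs = shared_pairs_same_host(part, sim.genes, sim.replicons)
        _, tally = classify_pairs(pairs, sim.genes, sim.replicons)
        assert tally.n_both_similar == tally.n_total == 5
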