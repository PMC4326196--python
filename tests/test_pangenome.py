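import numpy as np
import pytest

from repliconpan.pangenome import (
    classify_families,
    extended_core,
    pick_representatives,
    shared_breakdown,
    shared_pairs_same_host,
)
from repliconpan.records import Family, Gene, Replicon, RepliconKind


def _replicons(n_chr=4, n_pls=3):
    reps = []
    for i in range(n_chr):
        reps.append(Replicon(f"C{i}", RepliconKind.CHROMOSOME, f"H{i}", "ACGT"))
    for j in range(n_pls):
        reps.append(Replicon(f"P{j}", RepliconKind.PLASMID, f"H{j}", "ACGT"))
    return reps


def _family(fid, census):
    members = frozenset(f"{fid}_{r}_{k}" for r, n in census.items() for k in range(n))
    return Family(fid, members, census=dict(census))


class TestClassifyFamilies:
    def test_core_distributed_unique_shared_labels(self):
        reps = _replicons()
        fams = [
            _family("core", {"C0": 1, "C1": 1, "C2": 1, "C3": 1}),
            _family("dist", {"C0": 1, "C1": 1}),
            _family("uniq", {"C2": 1}),
            _family("puniq", {"P0": 1}),
            _family("pdist", {"P0": 1, "P2": 1}),
            _family("shared", {"C0": 1, "C1": 1, "P1": 1}),
        ]
        part = classify_families(fams, reps)
        l = part.labels
        assert l["core"].chromosomal == "core" and not l["core"].shared
        assert l["dist"].chromosomal == "distributed"
        assert l["uniq"].chromosomal == "unique"
        assert l["puniq"].plasmid == "unique" and l["puniq"].chromosomal == "absent"
        assert l["pdist"].plasmid == "distributed"
        assert l["shared"].chromosomal == "distributed" and l["shared"].shared

    def test_unknown_replicon_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            classify_families([_family("f", {"NOPE": 1})], _replicons())

    def test_paralogs_do_not_change_presence(self):
        part = classify_families([_family("f", {"C0": 3})], _replicons())
        assert part.labels["f"].chromosomal == "unique"

    def test_plasmid_only_family_never_changes_chromosomal_labels(self):
        reps = _replicons()
        base = [_family("core", {"C0": 1, "C1": 1, "C2": 1, "C3": 1})]
        with_extra = base + [_family("pls", {"P0": 1})]
        a = classify_families(base, reps)
        b = classify_families(with_extra, reps)
        assert a.labels["core"] == b.labels["core"]


class TestExtendedCore:
    def test_default_all_but_one(self):
        reps = _replicons(n_chr=5, n_pls=0)
        fams = [
            _family("on5", {f"C{i}": 1 for i in range(5)}),
            _family("on4", {f"C{i}": 1 for i in range(4)}),
            _family("on3", {f"C{i}": 1 for i in range(3)}),
        ]
        part = classify_families(fams, reps)
        assert extended_core(part) == {"on5", "on4"}

    def test_core_subset_of_extended_core(self, small_partition):
        core = {f for f, l in small_partition.labels.items() if l.chromosomal == "core"}
        assert core <= extended_core(small_partition)

    def test_min_above_dataset_size_rejected(self, small_partition):
        with pytest.raises(ValueError):
            extended_core(small_partition, min_chromosomes=99)


class TestSharedBreakdown:
    def test_planted_rows_match_truth(self, small_sim, small_partition):
        truth = small_sim.truth
        df = shared_breakdown(small_partition)
        genes = truth.genes
        chromosomes = set(genes.loc[genes["replicon_kind"] == "chromosome", "replicon_id"])
        expected = {"core": [0, 0], "distributed": [0, 0], "unique": [0, 0]}
        n_chr = truth.config.n_chromosomes
        for fid, grp in genes.groupby("family_id"):
            reps = set(grp["replicon_id"])
            on_chr = len(reps & chromosomes)
            on_pls = len(reps - chromosomes)
            if on_chr == 0 or on_pls == 0:
                continue
            label = "core" if on_chr == n_chr else ("unique" if on_chr == 1 else "distributed")
            expected[label][0 if on_pls == 1 else 1] += 1
        for _, row in df.iterrows():
            exp = expected[row["chromosomal_label"]]
            assert row["on_one_plasmid"] == exp[0]
            assert row["on_multiple_plasmids"] == exp[1]

    def test_rows_sum_to_total_shared(self, small_partition):
        df = shared_breakdown(small_partition)
        assert int(df["n_shared"].sum()) == small_partition.n_shared


class TestRepresentatives:
    def test_singleton_family_always_its_member(self):
        fam = Family("F1", frozenset({"only"}))
        for seed in (0, 1, 99):
            assert pick_representatives([fam], seed)["F1"] == "only"

    def test_deterministic_per_seed(self, small_cluster):
        assert pick_representatives(small_cluster.families, 7) == pick_representatives(
            small_cluster.families, 7
        )

    def test_two_member_family_picked_uniformly(self):
        fam = Family("F1", frozenset({"a", "b"}))
        picks = [pick_representatives([fam], seed)["F1"] for seed in range(10_000)]
        frac_a = picks.count("a") / len(picks)
        assert abs(frac_a - 0.5) < 0.02


class TestSharedPairsSameHost:
    def test_all_combinations_within_host(self):
        reps = _replicons(n_chr=2, n_pls=2)  # hosts H0, H1
        genes = [
            Gene("p1", "P0", 1, 6, "+", "ATGTAA", "M"),
            Gene("p2", "P0", 10, 15, "+", "ATGTAA", "M"),
            Gene("c1", "C0", 1, 6, "+", "ATGTAA", "M"),
        ]
        fam = Family("F1", frozenset({"p1", "p2", "c1"}), census={"P0": 2, "C0": 1})
        part = classify_families([fam], reps)
        pairs = shared_pairs_same_host(part, genes, reps)
        assert len(pairs) == 2
        assert {p.plasmid_gene for p in pairs} == {"p1", "p2"}

    def test_cross_host_members_give_no_pairs(self):
        reps = _replicons(n_chr=2, n_pls=2)
        genes = [
            Gene("p1", "P1", 1, 6, "+", "ATGTAA", "M"),  # host H1
            Gene("c1", "C0", 1, 6, "+", "ATGTAA", "M"),  # host H0
        ]
        fam = Family("F1", frozenset({"p1", "c1"}), census={"P1": 1, "C0": 1})
        part = classify_families([fam], reps)
        assert shared_pairs_same_host(part, genes, reps) == []
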