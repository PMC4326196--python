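import hashlib
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repliconpan.composition import build_cai_model, cai, gc3
from repliconpan.simulate import (
    OPTIMAL_CODON,
    SimConfig,
    TransferBlockSpec,
    back_translate,
    plant_transfer_block,
    rng_for,
    simulate_pangenome,
    synthesize_cds,
    write_simulation,
)


def _dir_digest(path: Path) -> str:
    digest = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            digest.update(f.name.encode())
            digest.update(f.read_bytes())
    return digest.hexdigest()


class TestSynthesizeCds:
    def test_full_bias_gives_cai_one(self):
        rng = rng_for(0, "t1")
        genes = [synthesize_cds(100, 0.5, 1.0, rng) for _ in range(10)]
        model = build_cai_model(genes)
        for g in genes:
            assert cai(g, model) == pytest.approx(1.0)

    def test_gc3_target_one_forces_gc_third_positions(self):
        rng = rng_for(0, "t2")
        cds = synthesize_cds(200, 1.0, 0.0, rng)
        assert gc3(cds) == 1.0

    def test_gc3_monte_carlo_near_target(self):
        rng = rng_for(0, "gc3")
        vals = [gc3(synthesize_cds(150, 0.35, 0.0, rng)) for _ in range(200)]
        assert abs(float(np.mean(vals)) - 0.35) < 0.03

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            synthesize_cds(10, 1.5, 0.0, rng_for(0, "t3"))

    def test_structure(self):
        cds = synthesize_cds(50, 0.4, 0.3, rng_for(0, "t4"))
        assert cds.startswith("ATG") and cds.endswith("TAA")
        assert len(cds) == 3 * 51


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = dict(
            n_chromosomes=3, n_plasmids=2, n_chr_core=3, n_chr_distributed=4,
            n_chr_unique=5, n_pls_distributed=2, n_pls_unique=3, n_shared=4, seed=17,
        )
        digests = []
        for run in (1, 2):
            sim = simulate_pangenome(SimConfig(**cfg))
            out = tmp_path / f"run{run}"
            write_simulation(sim, out)
            digests.append(_dir_digest(out))
        assert digests[0] == digests[1]

    def test_different_seed_changes_sequences(self):
        cfg = dict(n_chromosomes=3, n_plasmids=2, n_chr_core=3, n_chr_distributed=4,
                   n_chr_unique=5, n_pls_distributed=2, n_pls_unique=3, n_shared=4)
        a = simulate_pangenome(SimConfig(seed=1, **cfg))
        b = simulate_pangenome(SimConfig(seed=2, **cfg))
        assert a.replicons[0].sequence != b.replicons[0].sequence


class TestPlantedStructure:
    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(
        n_core=st.integers(0, 6),
        n_dist=st.integers(0, 6),
        n_uniq=st.integers(0, 6),
        n_pd=st.integers(0, 4),
        n_pu=st.integers(0, 4),
        n_sh=st.integers(0, 5),
        seed=st.integers(0, 100),
    )
    def test_truth_class_counts_equal_config_counts(
        self, n_core, n_dist, n_uniq, n_pd, n_pu, n_sh, seed
    ):
        cfg = SimConfig(
            n_chromosomes=3,
            n_plasmids=2,
            n_chr_core=n_core,
            n_chr_distributed=n_dist,
            n_chr_unique=n_uniq,
            n_pls_distributed=n_pd,
            n_pls_unique=n_pu,
            n_shared=n_sh,
            seed=seed,
        )
        sim = simulate_pangenome(cfg)
        counts = sim.truth.class_counts()
        assert counts.get("chr_core", 0) == n_core
        assert counts.get("chr_distributed", 0) == n_dist
        assert counts.get("chr_unique", 0) == n_uniq
        assert counts.get("pls_distributed", 0) == n_pd
        assert counts.get("pls_unique", 0) == n_pu
        assert counts.get("shared", 0) == n_sh
        assert len(sim.truth.pairs) == n_sh

    def test_core_families_on_every_chromosome(self, small_sim):
        genes = small_sim.truth.genes
        core = genes[genes["class_label"] == "chr_core"]
        n_chr = small_sim.truth.config.n_chromosomes
        for fid, grp in core.groupby("family_id"):
            assert grp["replicon_id"].nunique() == n_chr

    def test_each_gene_appears_once(self, small_sim):
        assert small_sim.truth.genes["gene_id"].is_unique

    def test_intergaps_leave_room_for_flanks(self, small_sim):
        for rep in small_sim.replicons:
            spans = sorted(
                (g.start, g.end)
                for g in small_sim.genes
                if g.replicon_id == rep.replicon_id
            )
            prev_end = 0
            for start, end in spans:
                assert start - prev_end - 1 >= 300
                prev_end = end

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=2, n_chr_distributed=5)
        with pytest.raises(ValueError):
            SimConfig(n_plasmids=1, n_pls_distributed=2)
        with pytest.raises(ValueError):
            SimConfig(within_divergence=0.5)


class TestTransferBlock:
    def _base(self, seed=7, **kw):
        return SimConfig(
            n_chromosomes=2, n_plasmids=1, n_chr_core=4, n_chr_distributed=0,
            n_chr_unique=4, n_pls_distributed=0, n_pls_unique=4, n_shared=0,
            seed=seed, **kw,
        )

    def test_full_identity_copies_byte_identical(self):
        cfg = self._base(transfer_block=TransferBlockSpec(n_genes=3, mean_nt_identity=1.0))
        sim = simulate_pangenome(cfg)
        truth = sim.truth.block
        idx = {g.gene_id: g for g in sim.genes}
        for row in truth.itertuples():
            assert idx[row.plasmid_gene].cds_nt == idx[row.chromosome_gene].cds_nt

    def test_mutated_copies_stay_translatable(self):
        cfg = self._base(transfer_block=TransferBlockSpec(n_genes=5, mean_nt_identity=0.9))
        sim = simulate_pangenome(cfg)
        for g in sim.genes:
            assert "*" not in g.protein

    def test_minimal_block_of_two(self):
        cfg = self._base(transfer_block=TransferBlockSpec(n_genes=2, mean_nt_identity=0.97))
        sim = simulate_pangenome(cfg)
        assert len(sim.truth.block) == 2

    def test_block_needs_two_genes(self):
        sim = simulate_pangenome(self._base())
        with pytest.raises(ValueError):
            plant_transfer_block(sim, "PLS01", "CHR01", 1, 0.95, rng_for(0, "x"))
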