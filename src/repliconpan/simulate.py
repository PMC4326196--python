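"""Synthetic replicon sets with planted pan-genome structure.

The generator emits chromosomes and plasmids whose gene families have
controlled prevalence (core / distributed / unique / shared), class-specific
base composition (synonymous GC3) and codon bias, planted flank classes for
the shared plasmid-chromosome pairs, optional clustered gene placement, an
optional multi-gene transfer block, planted functional-category labels and an
operon table — together with a machine-readable truth table so every
downstream stage has exact expected outputs.

Within-family divergence is applied at the protein level and back-translated,
so the protein-identity clustering gate and the nucleotide identity of
transfer blocks are controlled independently. All randomness flows from a
single seed through named sub-streams (stable CRC32 hashing of stream names),
so adding a replicon does not perturb the sequences of existing ones and the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .composition import SYNONYMOUS, EXCLUDED_CODONS, STOP_CODONS, _CODON_TABLE
from .io import reverse_complement, write_fasta, write_gff
from .records import Gene, Replicon, RepliconKind

AA20 = "ACDEFGHIKLMNPQRSTVWY"
FLANK_CLASSES = ("both_similar", "up_diff_only", "down_diff_only", "both_diff")

# one designated "optimal" codon per amino acid: the alphabetically first
# G/C-ending codon (every amino acid has one)
OPTIMAL_CODON: dict[str, str] = {
    aa: sorted(c for c in codons if c[2] in "GC")[0] for aa, codons in SYNONYMOUS.items()
}

DEFAULT_GC3 = {
    "chr_core": 0.45,
    "chr_distributed": 0.36,
    "chr_unique": 0.36,
    "pls_distributed": 0.30,
    "pls_unique": 0.30,
    "shared": 0.33,
    "block": 0.35,
}
DEFAULT_BIAS = {
    "chr_core": 0.55,
    "chr_distributed": 0.15,
    "chr_unique": 0.15,
    "pls_distributed": 0.10,
    "pls_unique": 0.10,
    "shared": 0.20,
    "block": 0.20,
}

# class-specific functional-category pools (single-letter COG classes);
# plasmid-like classes lean on replication/transcription/trafficking,
# chromosomal core on metabolism and translation
CATEGORY_POOLS = {
    "chr_core": "CEFGHIJPQ",
    "chr_distributed": "CEGKMPRS",
    "chr_unique": "LKRSV",
    "pls_distributed": "KLOU",
    "pls_unique": "KLRS",
    "shared": "EKLP",
    "block": "KLM",
}


def rng_for(seed: int, *keys) -> np.random.Generator:
    """A named RNG sub-stream: deterministic in (seed, keys), independent
    across distinct key tuples."""
    spawn = tuple(zlib.crc32(str(k).encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn))


# ------------------------------------------------------------------ sequence synthesis


def _codon_weights(aa: str, gc3_target: float, bias_strength: float) -> tuple[list[str], np.ndarray]:
    codons = SYNONYMOUS[aa]
    gc = [c for c in codons if c[2] in "GC"]
    at = [c for c in codons if c[2] not in "GC"]
    base = np.zeros(len(codons))
    for i, c in enumerate(codons):
        if gc and at:
            base[i] = gc3_target / len(gc) if c in gc else (1 - gc3_target) / len(at)
        else:
            base[i] = 1.0 / len(codons)
    base /= base.sum()
    onehot = np.array([1.0 if c == OPTIMAL_CODON[aa] else 0.0 for c in codons])
    w = (1 - bias_strength) * base + bias_strength * onehot
    return codons, w / w.sum()


def back_translate(
    protein: str, gc3_target: float, bias_strength: float, rng: np.random.Generator
) -> str:
    """Encode a protein as a CDS whose synonymous-codon choice is tilted
    toward the GC3 target and, with ``bias_strength``, toward each amino
    acid's designated optimal codon. Appends a TAA stop."""
    if not 0.0 <= gc3_target <= 1.0:
        raise ValueError(f"GC3 target {gc3_target} unreachable (must be in [0, 1])")
    if not 0.0 <= bias_strength <= 1.0:
        raise ValueError("bias_strength must be in [0, 1]")
    parts = []
    for aa in protein:
        codons, w = _codon_weights(aa, gc3_target, bias_strength)
        parts.append(codons[int(rng.choice(len(codons), p=w))])
    return "".join(parts) + "TAA"


def synthesize_cds(
    aa_length: int, gc3_target: float, bias_strength: float, rng: np.random.Generator
) -> str:
    """A random CDS of ``aa_length`` residues (leading Met, trailing TAA stop)
    with the requested composition."""
    if aa_length < 1:
        raise ValueError("aa_length must be >= 1")
    protein = "M" + "".join(rng.choice(list(AA20), size=aa_length - 1))
    return back_translate(protein, gc3_target, bias_strength, rng)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "M" + "".join(rng.choice(list(AA20), size=length - 1))


def mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each non-initial residue with probability ``rate``."""
    chars = list(protein)
    for i in range(1, len(chars)):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != chars[i]]
            chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.35) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)


# ------------------------------------------------------------------ configuration


@dataclass
class TransferBlockSpec:
    n_genes: int = 57
    mean_nt_identity: float = 0.95
    plasmid_index: int = 0  # which plasmid receives the copy
    chromosome_index: int = 0


@dataclass
class OperonSpec:
    n_shared_operons: int = 10  # operons with >= 2 shared genes
    size_range: tuple[int, int] = (2, 5)
    n_single_shared: int = 4  # operons with exactly one shared gene (not counted)
    n_unshared: int = 4


@dataclass
class SimConfig:
    """Study conditions for one synthetic pan-genome."""

    n_chromosomes: int = 5
    n_plasmids: int = 4
    n_chr_core: int = 50
    n_chr_distributed: int = 120
    n_chr_unique: int = 200
    n_pls_distributed: int = 40
    n_pls_unique: int = 80
    n_shared: int = 30
    # how the shared families sit on the chromosome side (core, distributed,
    # unique); None derives a split echoing the real-data proportions
    shared_chr_profile: Optional[tuple[int, int, int]] = None
    gc3_targets: dict = field(default_factory=lambda: dict(DEFAULT_GC3))
    codon_bias: dict = field(default_factory=lambda: dict(DEFAULT_BIAS))
    within_divergence: float = 0.05  # protein substitutions/site within a family
    protein_len_range: tuple[int, int] = (80, 260)
    # realized flank-class counts; None derives them from flank_fractions
    flank_class_counts: Optional[tuple[int, int, int, int]] = None
    flank_fractions: tuple[float, float, float, float] = (0.332, 0.081, 0.095, 0.492)
    flank_similar_divergence: float = 0.02
    placement: str = "uniform"  # or "clustered"
    clustered_span: float = 0.2
    min_intergap: int = 350  # > up_len + down_len so flanks never overlap a CDS
    mean_extra_gap: int = 150
    background_gc: float = 0.35
    max_replicon_length: Optional[int] = None
    transfer_block: Optional[TransferBlockSpec] = None
    operons: Optional[OperonSpec] = None
    plant_categories: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_chr_core,
            self.n_chr_distributed,
            self.n_chr_unique,
            self.n_pls_distributed,
            self.n_pls_unique,
            self.n_shared,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("family counts must be >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.n_chr_distributed > 0 and self.n_chromosomes < 3:
            raise ValueError("chromosomal distributed families need >= 3 chromosomes")
        if self.n_pls_distributed > 0 and self.n_plasmids < 2:
            raise ValueError("plasmid distributed families need >= 2 plasmids")
        if self.n_shared > 0 and self.n_plasmids < 1:
            raise ValueError("shared families need >= 1 plasmid")
        if not 0 < self.within_divergence < 0.3:
            raise ValueError(
                "within-family divergence must stay well below the 70% identity gate"
            )

    def resolved_shared_profile(self) -> tuple[int, int, int]:
        if self.shared_chr_profile is not None:
            core, dist, uniq = self.shared_chr_profile
            if core + dist + uniq != self.n_shared:
                raise ValueError("shared_chr_profile must sum to n_shared")
            if dist > 0 and self.n_chromosomes < 3:
                raise ValueError("distributed-shared families need >= 3 chromosomes")
            return core, dist, uniq
        core = round(0.067 * self.n_shared)
        uniq = round(0.361 * self.n_shared)
        if self.n_chromosomes < 3:
            return core, 0, self.n_shared - core
        return core, self.n_shared - core - uniq, uniq

    def resolved_flank_counts(self) -> tuple[int, int, int, int]:
        if self.flank_class_counts is not None:
            if sum(self.flank_class_counts) != self.n_shared:
                raise ValueError("flank_class_counts must sum to n_shared")
            return self.flank_class_counts
        return _largest_remainder(self.flank_fractions, self.n_shared)


def _largest_remainder(fractions, total: int) -> tuple[int, ...]:
    raw = [f * total for f in fractions]
    counts = [int(x) for x in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return tuple(counts)


# ------------------------------------------------------------------ truth table


@dataclass
class TruthTable:
    genes: pd.DataFrame  # gene_id, family_id, class_label, replicon_id, host_id, start, end, strand, categories
    pairs: pd.DataFrame  # family_id, host_id, plasmid_gene, chromosome_gene, flank_class
    block: pd.DataFrame  # family_id, plasmid_gene, chromosome_gene
    operon_table: pd.DataFrame  # operon_id, gene_id, position
    operon_truth: dict  # planted tally
    config: SimConfig

    def class_counts(self) -> dict[str, int]:
        fam = self.genes.drop_duplicates("family_id")
        return fam["class_label"].value_counts().to_dict()

    def expected_set_counts(self) -> dict[str, int]:
        """Partition counts implied by the planted gene->replicon assignment
        (shared families contribute to the chromosomal labels they land in)."""
        genes = self.genes
        chromosomes = set(
            genes.loc[genes["replicon_kind"] == "chromosome", "replicon_id"]
        )
        n_chr_total = self.config.n_chromosomes
        counts = {
            "chromosomal_core": 0,
            "chromosomal_distributed": 0,
            "chromosomal_unique": 0,
            "plasmid_distributed": 0,
            "plasmid_unique": 0,
            "shared": 0,
        }
        for _, grp in genes.groupby("family_id"):
            reps = set(grp["replicon_id"])
            on_chr = len(reps & chromosomes)
            on_pls = len(reps - chromosomes)
            if on_chr == n_chr_total and n_chr_total > 0:
                counts["chromosomal_core"] += 1
            elif on_chr == 1:
                counts["chromosomal_unique"] += 1
            elif on_chr > 1:
                counts["chromosomal_distributed"] += 1
            if on_pls == 1:
                counts["plasmid_unique"] += 1
            elif on_pls > 1:
                counts["plasmid_distributed"] += 1
            if on_chr >= 1 and on_pls >= 1:
                counts["shared"] += 1
        return counts

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["family_id"]))

    def flank_class_counts(self) -> dict[str, int]:
        return self.pairs["flank_class"].value_counts().to_dict()


@dataclass
class Simulation:
    replicons: list[Replicon]
    genes: list[Gene]
    truth: TruthTable


# ------------------------------------------------------------------ planning


@dataclass
class _FamilyPlan:
    family_id: str
    class_label: str
    replicons: list[str]
    pair: Optional[tuple[str, str]] = None  # (plasmid_id, chromosome_id) same-host pair
    host: Optional[str] = None
    flank_class: Optional[str] = None
    categories: tuple[str, ...] = ()


@dataclass
class _GeneSpec:
    family_id: str
    class_label: str
    cds: str
    planted_up: Optional[str] = None
    planted_down: Optional[str] = None
    categories: tuple[str, ...] = ()


def _plan_families(config: SimConfig) -> tuple[list[_FamilyPlan], dict[str, str], dict[str, str]]:
    """Assign every family to replicons; returns plans plus the replicon->host
    and plasmid->host maps."""
    n_chr, n_pls = config.n_chromosomes, config.n_plasmids
    chr_ids = [f"CHR{i + 1:02d}" for i in range(n_chr)]
    pls_ids = [f"PLS{i + 1:02d}" for i in range(n_pls)]
    host_of = {cid: f"H{i + 1:02d}" for i, cid in enumerate(chr_ids)}
    for j, pid in enumerate(pls_ids):
        host_of[pid] = f"H{(j % n_chr) + 1:02d}"
    chr_of_host = {host_of[cid]: cid for cid in chr_ids}

    rng = rng_for(config.seed, "plan")
    plans: list[_FamilyPlan] = []

    def add(prefix: str, idx: int, label: str, reps: list[str], **kw) -> None:
        plans.append(_FamilyPlan(f"{prefix}{idx:04d}", label, reps, **kw))

    for i in range(config.n_chr_core):
        add("FC", i, "chr_core", list(chr_ids))
    for i in range(config.n_chr_distributed):
        k = int(rng.integers(2, n_chr))  # 2 .. n_chr-1
        reps = sorted(rng.choice(chr_ids, size=k, replace=False).tolist())
        add("FD", i, "chr_distributed", reps)
    for i in range(config.n_chr_unique):
        add("FU", i, "chr_unique", [chr_ids[int(rng.integers(n_chr))]])
    for i in range(config.n_pls_distributed):
        k = int(rng.integers(2, n_pls + 1))  # 2 .. n_pls
        reps = sorted(rng.choice(pls_ids, size=k, replace=False).tolist())
        add("PD", i, "pls_distributed", reps)
    for i in range(config.n_pls_unique):
        add("PU", i, "pls_unique", [pls_ids[int(rng.integers(n_pls))]])

    # shared families: one same-host (plasmid, chromosome) pair each
    n_core_sh, n_dist_sh, n_uniq_sh = config.resolved_shared_profile()
    flank_counts = config.resolved_flank_counts()
    flank_labels = [
        cls for cls, cnt in zip(FLANK_CLASSES, flank_counts) for _ in range(cnt)
    ]
    rng.shuffle(flank_labels)

    multi_dist = n_dist_sh // 2 if n_pls >= 2 else 0
    multi_uniq = n_uniq_sh // 3 if n_pls >= 2 else 0

    idx = 0
    specs = (
        [("core", None) for _ in range(n_core_sh)]
        + [("distributed", i < multi_dist) for i in range(n_dist_sh)]
        + [("unique", i < multi_uniq) for i in range(n_uniq_sh)]
    )
    for kind, multi in specs:
        p = pls_ids[int(rng.integers(n_pls))]
        h = host_of[p]
        anchor_chr = chr_of_host[h]
        second: Optional[str] = None
        if multi:
            cands = [q for q in pls_ids if q != p and host_of[q] != h]
            if cands:
                second = cands[int(rng.integers(len(cands)))]
        if kind == "core":
            chrs = list(chr_ids)
            second = None  # a second plasmid would create a second same-host pair
        elif kind == "unique":
            chrs = [anchor_chr]
        else:
            k = int(rng.integers(2, n_chr))
            pool = [c for c in chr_ids if c != anchor_chr]
            if second is not None:
                pool = [c for c in pool if c != chr_of_host[host_of[second]]]
            extra = sorted(rng.choice(pool, size=min(k - 1, len(pool)), replace=False).tolist())
            chrs = sorted([anchor_chr] + extra)
        reps = chrs + [p] + ([second] if second else [])
        plans.append(
            _FamilyPlan(
                family_id=f"FS{idx:04d}",
                class_label="shared",
                replicons=reps,
                pair=(p, anchor_chr),
                host=h,
                flank_class=flank_labels[idx],
            )
        )
        idx += 1

    if config.plant_categories:
        for plan in plans:
            pool = CATEGORY_POOLS[plan.class_label]
            k = 1 + int(rng.random() < 0.35)  # one or two categories
            plan.categories = tuple(
                sorted(rng.choice(list(pool), size=min(k, len(pool)), replace=False))
            )
    return plans, host_of, chr_of_host


# ------------------------------------------------------------------ assembly


def _assemble_replicon(
    replicon_id: str,
    kind: RepliconKind,
    host_id: str,
    gene_specs: list[_GeneSpec],
    config: SimConfig,
) -> tuple[Replicon, list[Gene], list[tuple[str, _GeneSpec]]]:
    """Lay genes onto a fresh replicon sequence; returns the replicon, the
    Gene records (genomic order) and (gene_id, spec) links."""
    rng = rng_for(config.seed, "replicon", replicon_id)
    order = list(rng.permutation(len(gene_specs))) if gene_specs else []
    clustered = config.placement == "clustered"

    def spacer_len(head: int, tail: int) -> int:
        base = config.min_intergap + int(rng.geometric(1.0 / config.mean_extra_gap))
        return max(base, head + tail + 50)

    parts: list[str] = []
    pos = 0
    genes: list[Gene] = []
    links: list[tuple[str, _GeneSpec]] = []
    pending_head = ""  # planted flank owed to the next spacer's start

    for n_placed, oi in enumerate(order):
        spec = gene_specs[oi]
        strand = "+" if rng.random() < 0.5 else "-"
        up = spec.planted_up or ""
        down = spec.planted_down or ""
        # genomic-left flank piece and genomic-right flank piece for this gene
        left = up if strand == "+" else reverse_complement(down)
        right = down if strand == "+" else reverse_complement(up)

        slen = spacer_len(len(pending_head), len(left))
        mid = random_dna(slen - len(pending_head) - len(left), rng, config.background_gc)
        parts.append(pending_head + mid + left)
        pos += slen

        cds_genomic = spec.cds if strand == "+" else reverse_complement(spec.cds)
        start = pos + 1
        end = pos + len(cds_genomic)
        parts.append(cds_genomic)
        pos = end
        gid = f"{replicon_id}_g{n_placed + 1:04d}"
        genes.append(
            Gene(
                gene_id=gid,
                replicon_id=replicon_id,
                start=start,
                end=end,
                strand=strand,
                cds_nt=spec.cds,
                protein=_protein_of(spec.cds),
            )
        )
        links.append((gid, spec))
        pending_head = right

    tail = spacer_len(len(pending_head), 0)
    parts.append(pending_head + random_dna(tail - len(pending_head), rng, config.background_gc))
    pos += tail

    if clustered and genes:
        total = int(pos / config.clustered_span)
        parts.append(random_dna(total - pos, rng, config.background_gc))
        pos = total

    sequence = "".join(parts)
    if config.max_replicon_length is not None and len(sequence) > config.max_replicon_length:
        raise ValueError(
            f"{replicon_id}: requested genes need {len(sequence)} bp, exceeding the "
            f"replicon capacity {config.max_replicon_length}; increase max_replicon_length"
        )
    rep = Replicon(
        replicon_id=replicon_id,
        kind=kind,
        host_id=host_id,
        sequence=sequence,
        circular=True,
    )
    return rep, genes, links


def _protein_of(cds: str) -> str:
    prot = []
    for i in range(0, len(cds) - 3, 3):
        prot.append(_CODON_TABLE[cds[i : i + 3]])
    return "".join(prot)


# ------------------------------------------------------------------ top level


def simulate_pangenome(config: SimConfig) -> Simulation:
    """Generate replicons, genes and the truth table for one configuration."""
    plans, host_of, chr_of_host = _plan_families(config)

    # per-family member sequences
    per_replicon: dict[str, list[_GeneSpec]] = {}
    lo, hi = config.protein_len_range

    for plan in plans:
        frng = rng_for(config.seed, "family", plan.family_id)
        length = int(frng.integers(lo, hi + 1))
        ancestor = random_protein(length, frng)
        gc3_t = config.gc3_targets[plan.class_label]
        bias = config.codon_bias[plan.class_label]

        flank_up_shared = flank_down_shared = None
        if plan.flank_class is not None:
            if plan.flank_class in ("both_similar", "down_diff_only"):
                flank_up_shared = random_dna(200, frng, config.background_gc)
            if plan.flank_class in ("both_similar", "up_diff_only"):
                flank_down_shared = random_dna(100, frng, config.background_gc)

        for rid in plan.replicons:
            mrng = rng_for(config.seed, "member", plan.family_id, rid)
            protein = mutate_protein(ancestor, config.within_divergence, mrng)
            cds = back_translate(protein, gc3_t, bias, mrng)
            spec = _GeneSpec(
                family_id=plan.family_id,
                class_label=plan.class_label,
                cds=cds,
                categories=plan.categories,
            )
            if plan.pair is not None and rid in plan.pair:
                up = flank_up_shared
                down = flank_down_shared
                if up is not None:
                    spec.planted_up = (
                        up
                        if config.flank_similar_divergence == 0
                        else mutate_dna(up, config.flank_similar_divergence / 2, mrng)
                    )
                if down is not None:
                    spec.planted_down = (
                        down
                        if config.flank_similar_divergence == 0
                        else mutate_dna(down, config.flank_similar_divergence / 2, mrng)
                    )
            per_replicon.setdefault(rid, []).append(spec)

    # assemble replicons in a stable id order
    n_chr, n_pls = config.n_chromosomes, config.n_plasmids
    chr_ids = [f"CHR{i + 1:02d}" for i in range(n_chr)]
    pls_ids = [f"PLS{i + 1:02d}" for i in range(n_pls)]
    replicons: list[Replicon] = []
    genes: list[Gene] = []
    gene_rows: list[dict] = []
    spec_of_gene: dict[str, _GeneSpec] = {}
    for rid in chr_ids + pls_ids:
        kind = RepliconKind.CHROMOSOME if rid.startswith("CHR") else RepliconKind.PLASMID
        rep, rep_genes, links = _assemble_replicon(
            rid, kind, host_of[rid], per_replicon.get(rid, []), config
        )
        replicons.append(rep)
        genes.extend(rep_genes)
        for gid, spec in links:
            spec_of_gene[gid] = spec
            g = next(x for x in rep_genes if x.gene_id == gid)
            gene_rows.append(
                {
                    "gene_id": gid,
                    "family_id": spec.family_id,
                    "class_label": spec.class_label,
                    "replicon_id": rid,
                    "replicon_kind": kind.value,
                    "host_id": host_of[rid],
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "categories": ",".join(spec.categories),
                }
            )

    genes_df = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id",
            "family_id",
            "class_label",
            "replicon_id",
            "replicon_kind",
            "host_id",
            "start",
            "end",
            "strand",
            "categories",
        ],
    )

    # same-host pair truth
    pair_rows: list[dict] = []
    for plan in plans:
        if plan.pair is None:
            continue
        p_rid, c_rid = plan.pair
        pg = genes_df[(genes_df["family_id"] == plan.family_id) & (genes_df["replicon_id"] == p_rid)]
        cg = genes_df[(genes_df["family_id"] == plan.family_id) & (genes_df["replicon_id"] == c_rid)]
        pair_rows.append(
            {
                "family_id": plan.family_id,
                "host_id": plan.host,
                "plasmid_gene": pg["gene_id"].iloc[0],
                "chromosome_gene": cg["gene_id"].iloc[0],
                "flank_class": plan.flank_class,
            }
        )
    pairs_df = pd.DataFrame(
        pair_rows,
        columns=["family_id", "host_id", "plasmid_gene", "chromosome_gene", "flank_class"],
    )

    block_df = pd.DataFrame(columns=["family_id", "plasmid_gene", "chromosome_gene"])
    truth = TruthTable(
        genes=genes_df,
        pairs=pairs_df,
        block=block_df,
        operon_table=pd.DataFrame(columns=["operon_id", "gene_id", "position"]),
        operon_truth={},
        config=config,
    )
    sim = Simulation(replicons=replicons, genes=genes, truth=truth)

    if config.transfer_block is not None:
        tb = config.transfer_block
        plant_transfer_block(
            sim,
            plasmid_id=pls_ids[tb.plasmid_index],
            chromosome_id=chr_ids[tb.chromosome_index],
            n_genes=tb.n_genes,
            identity=tb.mean_nt_identity,
            rng=rng_for(config.seed, "block"),
        )
    if config.operons is not None:
        _plant_operons(sim, config.operons, rng_for(config.seed, "operons"))
    return sim


# ------------------------------------------------------------------ transfer block


def _mutate_block_region(
    region: str,
    gene_intervals: list[tuple[int, int, str]],  # 0-based inclusive, strand
    rate: float,
    rng: np.random.Generator,
) -> str:
    """Per-base substitution at ``rate``, constrained so no CDS gains an
    internal stop and every start/stop codon stays intact (the first and last
    codon of each CDS are never touched)."""
    chars = list(region)
    protected: set[int] = set()
    in_gene: dict[int, tuple[int, int, str]] = {}
    for gs, ge, strand in gene_intervals:
        for p in list(range(gs, gs + 3)) + list(range(ge - 2, ge + 1)):
            protected.add(p)
        for p in range(gs, ge + 1):
            in_gene[p] = (gs, ge, strand)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for p in range(len(chars)):
        if p in protected or rng.random() >= rate:
            continue
        candidates = [b for b in "ACGT" if b != chars[p]]
        rng.shuffle(candidates)
        if p not in in_gene:
            chars[p] = candidates[0]
            continue
        gs, ge, strand = in_gene[p]
        q = p - gs if strand == "+" else ge - p
        cstart_q = 3 * (q // 3)
        for cand in candidates:
            old = chars[p]
            chars[p] = cand
            if strand == "+":
                codon = "".join(chars[gs + cstart_q : gs + cstart_q + 3])
            else:
                codon = "".join(comp[chars[ge - (cstart_q + k)]] for k in range(3))
            if codon not in STOP_CODONS:
                break
            chars[p] = old
    return "".join(chars)


def plant_transfer_block(
    sim: Simulation,
    plasmid_id: str,
    chromosome_id: str,
    n_genes: int,
    identity: float,
    rng: np.random.Generator,
) -> None:
    """Append a contiguous run of ``n_genes`` new genes to the chromosome and
    copy the whole region to the plasmid with per-base substitution rate
    1 - identity (CDS-aware, so copies stay translatable). Updates replicons,
    genes and the truth table in place."""
    if n_genes < 2:
        raise ValueError("a transfer block needs at least 2 genes")
    config = sim.truth.config
    reps = {r.replicon_id: r for r in sim.replicons}
    chrom = reps[chromosome_id]
    plasmid = reps[plasmid_id]

    lo, hi = config.protein_len_range
    parts: list[str] = []
    intervals: list[tuple[int, int, str]] = []  # 0-based in region
    pos = 0
    specs: list[tuple[str, str, int, int]] = []  # family, strand, rel start/end
    for i in range(n_genes):
        gap = config.min_intergap + int(rng.geometric(1.0 / config.mean_extra_gap))
        parts.append(random_dna(gap, rng, config.background_gc))
        pos += gap
        length = int(rng.integers(lo, hi + 1))
        cds = synthesize_cds(length, config.gc3_targets["block"], config.codon_bias["block"], rng)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = cds if strand == "+" else reverse_complement(cds)
        parts.append(genomic)
        intervals.append((pos, pos + len(genomic) - 1, strand))
        specs.append((f"FB{i:04d}", strand, pos, pos + len(genomic) - 1))
        pos += len(genomic)
    parts.append(random_dna(config.min_intergap, rng, config.background_gc))
    region = "".join(parts)
    if config.max_replicon_length is not None and (
        plasmid.length_bp + len(region) > config.max_replicon_length
        or chrom.length_bp + len(region) > config.max_replicon_length
    ):
        raise ValueError("block longer than target replicon capacity")

    mutated = _mutate_block_region(region, intervals, 1.0 - identity, rng)

    new_rows: list[dict] = []
    block_rows: list[dict] = []

    def _append(rep: Replicon, reg: str, tag: str) -> list[Gene]:
        offset = rep.length_bp
        rep.sequence = rep.sequence + reg
        out: list[Gene] = []
        existing = sum(1 for g in sim.genes if g.replicon_id == rep.replicon_id)
        for k, (fam, strand, rs, re_) in enumerate(specs):
            start, end = offset + rs + 1, offset + re_ + 1
            genomic = reg[rs : re_ + 1]
            cds = genomic if strand == "+" else reverse_complement(genomic)
            gid = f"{rep.replicon_id}_g{existing + k + 1:04d}"
            g = Gene(
                gene_id=gid,
                replicon_id=rep.replicon_id,
                start=start,
                end=end,
                strand=strand,
                cds_nt=cds,
                protein=_protein_of(cds),
            )
            out.append(g)
            new_rows.append(
                {
                    "gene_id": gid,
                    "family_id": fam,
                    "class_label": "block",
                    "replicon_id": rep.replicon_id,
                    "replicon_kind": rep.kind.value,
                    "host_id": rep.host_id,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "categories": "",
                }
            )
        return out

    chr_genes = _append(chrom, region, "chr")
    pls_genes = _append(plasmid, mutated, "pls")
    sim.genes.extend(chr_genes)
    sim.genes.extend(pls_genes)
    for cg, pg, (fam, *_rest) in zip(chr_genes, pls_genes, specs):
        block_rows.append(
            {"family_id": fam, "plasmid_gene": pg.gene_id, "chromosome_gene": cg.gene_id}
        )
    sim.truth.genes = pd.concat([sim.truth.genes, pd.DataFrame(new_rows)], ignore_index=True)
    sim.truth.block = pd.DataFrame(block_rows)


# ------------------------------------------------------------------ operons


def _plant_operons(sim: Simulation, spec: OperonSpec, rng: np.random.Generator) -> None:
    """Emit an operon-prediction table over planted genes with a known tally."""
    truth = sim.truth
    genes = truth.genes
    shared_fams = set(
        truth.genes.loc[truth.genes["class_label"].isin(["shared", "block"]), "family_id"]
    )
    shared_gene_ids = genes.loc[genes["family_id"].isin(shared_fams), "gene_id"].tolist()
    other_gene_ids = genes.loc[~genes["family_id"].isin(shared_fams), "gene_id"].tolist()
    rng.shuffle(shared_gene_ids)
    rng.shuffle(other_gene_ids)

    rows: list[dict] = []
    oid = 0
    n_in = 0
    sizes: list[int] = []

    def take(pool: list[str], n: int) -> list[str]:
        picked = pool[:n]
        del pool[:n]
        return picked

    for _ in range(spec.n_shared_operons):
        size = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
        members = take(shared_gene_ids, size)
        if len(members) < 2:
            break
        oid += 1
        sizes.append(len(members))
        n_in += len(members)
        for pos, gid in enumerate(members, 1):
            rows.append({"operon_id": f"OP{oid:03d}", "gene_id": gid, "position": pos})
    for _ in range(spec.n_single_shared):
        if not shared_gene_ids or len(other_gene_ids) < 2:
            break
        oid += 1
        members = take(shared_gene_ids, 1) + take(other_gene_ids, 2)
        for pos, gid in enumerate(members, 1):
            rows.append({"operon_id": f"OP{oid:03d}", "gene_id": gid, "position": pos})
    for _ in range(spec.n_unshared):
        if len(other_gene_ids) < 3:
            break
        oid += 1
        members = take(other_gene_ids, 3)
        for pos, gid in enumerate(members, 1):
            rows.append({"operon_id": f"OP{oid:03d}", "gene_id": gid, "position": pos})

    truth.operon_table = pd.DataFrame(rows, columns=["operon_id", "gene_id", "position"])
    truth.operon_truth = {
        "n_shared_genes_considered": len(
            genes.loc[genes["family_id"].isin(shared_fams), "gene_id"]
        ),
        "n_in_operons": n_in,
        "n_operons": len(sizes),
        "size_min": min(sizes) if sizes else None,
        "size_max": max(sizes) if sizes else None,
    }


# ------------------------------------------------------------------ COG hit table


def cog_hit_table(sim: Simulation, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Tabular functional-category hits realizing each family's planted
    categories, with decoy hits beyond the top three and beyond the e-value
    cutoff to exercise the selection rules."""
    if rng is None:
        rng = rng_for(sim.truth.config.seed, "cog")
    rows: list[dict] = []
    for _, r in sim.truth.genes.iterrows():
        cats = [c for c in str(r["categories"]).split(",") if c]
        if not cats:
            continue
        hits = list(cats)
        while len(hits) < 3:  # pad to exactly 3 top hits (repeat categories)
            hits.append(cats[int(rng.integers(len(cats)))])
        for rank, c in enumerate(hits[:3]):
            rows.append(
                {
                    "gene_id": r["gene_id"],
                    "cog_id": f"COG{rank:04d}",
                    "categories": c,
                    "evalue": 10.0 ** (-10 + rank),
                    "bitscore": 200.0 - 10 * rank,
                }
            )
        decoy = "Z" if "Z" not in cats else "A"
        rows.append(  # rank 4: inside the cutoff but beyond the top three
            {
                "gene_id": r["gene_id"],
                "cog_id": "COG9998",
                "categories": decoy,
                "evalue": 1e-4,
                "bitscore": 50.0,
            }
        )
        rows.append(  # fails the e-value cutoff
            {
                "gene_id": r["gene_id"],
                "cog_id": "COG9999",
                "categories": decoy,
                "evalue": 0.01,
                "bitscore": 40.0,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ output


def write_simulation(sim: Simulation, outdir: str | Path) -> Path:
    """Write FASTA + GFF3 per replicon, the manifest, truth tables, the operon
    and category tables, and the echoed configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for rep in sim.replicons:
        write_fasta([(rep.replicon_id, rep.sequence)], outdir / f"{rep.replicon_id}.fasta")
        write_gff(
            sorted(
                (g for g in sim.genes if g.replicon_id == rep.replicon_id),
                key=lambda g: g.start,
            ),
            outdir / f"{rep.replicon_id}.gff3",
        )
        manifest_rows.append(
            {
                "replicon_id": rep.replicon_id,
                "kind": rep.kind.value,
                "host_id": rep.host_id,
                "fasta": f"{rep.replicon_id}.fasta",
                "gff": f"{rep.replicon_id}.gff3",
                "circular": str(rep.circular).lower(),
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    sim.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    sim.truth.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    sim.truth.block.to_csv(outdir / "truth_block.tsv", sep="\t", index=False)
    sim.truth.operon_table.to_csv(outdir / "operons.tsv", sep="\t", index=False)
    if sim.truth.config.plant_categories:
        cog_hit_table(sim).to_csv(outdir / "cog_hits.tsv", sep="\t", index=False)
    cfg = asdict(sim.truth.config)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir
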