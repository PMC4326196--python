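"""Partition gene families into pan-genome sets and derive shared-family
breakdowns.

Definitions (over the replicons of a dataset):

* chromosomal core      — family present on every chromosome;
* chromosomal distributed — present on more than one but not all chromosomes;
* chromosomal unique    — present on exactly one chromosome;
* plasmid distributed / unique — the same, over plasmids (a plasmid "core"
  is not a separate label: a family on all plasmids counts as distributed);
* shared                — at least one member on a chromosome AND one on a
  plasmid, independent of the labels above.

"Presence" is binary per replicon: within-replicon paralogs appear in the
census but do not change presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import Family, Gene, Replicon, RepliconKind, index_genes, index_replicons


@dataclass
class FamilyLabels:
    chromosomal: str  # core | distributed | unique | absent
    plasmid: str  # distributed | unique | absent
    shared: bool
    n_chromosomes_present: int
    n_plasmids_present: int


@dataclass
class PanGenomePartition:
    labels: dict[str, FamilyLabels]  # family_id -> labels
    n_chromosomes: int
    n_plasmids: int
    families: dict[str, Family] = field(default_factory=dict)

    def count(self, side: str, label: str) -> int:
        return sum(1 for l in self.labels.values() if getattr(l, side) == label)

    @property
    def n_shared(self) -> int:
        return sum(1 for l in self.labels.values() if l.shared)

    def set_counts(self) -> dict[str, int]:
        return {
            "chromosomal_core": self.count("chromosomal", "core"),
            "chromosomal_distributed": self.count("chromosomal", "distributed"),
            "chromosomal_unique": self.count("chromosomal", "unique"),
            "plasmid_distributed": self.count("plasmid", "distributed"),
            "plasmid_unique": self.count("plasmid", "unique"),
            "shared": self.n_shared,
        }

    def shared_family_ids(self) -> list[str]:
        return sorted(f for f, l in self.labels.items() if l.shared)


def classify_families(families: list[Family], replicons: list[Replicon]) -> PanGenomePartition:
    """Label every family with its chromosomal and plasmid set membership."""
    rep_index = index_replicons(replicons)
    chromosomes = {r.replicon_id for r in replicons if r.kind == RepliconKind.CHROMOSOME}
    plasmids = {r.replicon_id for r in replicons if r.kind == RepliconKind.PLASMID}
    n_chr, n_pls = len(chromosomes), len(plasmids)

    labels: dict[str, FamilyLabels] = {}
    for fam in families:
        present = fam.replicons_present()
        unknown = present - set(rep_index)
        if unknown:
            raise ValueError(
                f"family {fam.family_id} references unknown replicon(s) {sorted(unknown)}"
            )
        on_chr = len(present & chromosomes)
        on_pls = len(present & plasmids)

        if on_chr == 0:
            chr_label = "absent"
        elif on_chr == n_chr:
            chr_label = "core"
        elif on_chr == 1:
            chr_label = "unique"
        else:
            chr_label = "distributed"
        # with a single chromosome in the dataset, "all" wins over "one"
        if n_chr == 1 and on_chr == 1:
            chr_label = "core"

        if on_pls == 0:
            pls_label = "absent"
        elif on_pls == 1:
            pls_label = "unique"
        else:
            pls_label = "distributed"

        labels[fam.family_id] = FamilyLabels(
            chromosomal=chr_label,
            plasmid=pls_label,
            shared=(on_chr >= 1 and on_pls >= 1),
            n_chromosomes_present=on_chr,
            n_plasmids_present=on_pls,
        )
    return PanGenomePartition(
        labels=labels,
        n_chromosomes=n_chr,
        n_plasmids=n_pls,
        families={f.family_id: f for f in families},
    )


def extended_core(partition: PanGenomePartition, min_chromosomes: int | None = None) -> set[str]:
    """Families present on at least ``min_chromosomes`` chromosomes
    (default: all but one). Always a superset of the core."""
    if min_chromosomes is None:
        min_chromosomes = partition.n_chromosomes - 1
    if min_chromosomes > partition.n_chromosomes:
        raise ValueError("min_chromosomes exceeds the number of chromosomes in the dataset")
    return {
        fid
        for fid, l in partition.labels.items()
        if l.n_chromosomes_present >= min_chromosomes
    }


def shared_breakdown(partition: PanGenomePartition) -> pd.DataFrame:
    """Cross-tabulate shared families by chromosomal label and by plasmid
    multiplicity (on exactly one plasmid vs on more than one)."""
    rows = []
    for chr_label in ("core", "distributed", "unique"):
        fams = [
            fid
            for fid, l in partition.labels.items()
            if l.shared and l.chromosomal == chr_label
        ]
        one = sum(1 for f in fams if partition.labels[f].n_plasmids_present == 1)
        multi = len(fams) - one
        rows.append(
            {
                "chromosomal_label": chr_label,
                "n_shared": len(fams),
                "on_one_plasmid": one,
                "on_multiple_plasmids": multi,
            }
        )
    df = pd.DataFrame(rows)
    assert int(df["n_shared"].sum()) == partition.n_shared
    return df


def pick_representatives(
    families: list[Family], seed: int = 0
) -> dict[str, str]:
    """One uniformly random member gene per family, deterministic per seed."""
    rng = np.random.default_rng(seed)
    reps: dict[str, str] = {}
    for fam in sorted(families, key=lambda f: f.family_id):
        members = sorted(fam.members)
        reps[fam.family_id] = members[int(rng.integers(len(members)))]
    return reps


@dataclass(frozen=True)
class SharedPair:
    pair_id: str
    family_id: str
    host_id: str
    plasmid_gene: str
    chromosome_gene: str


def shared_pairs_same_host(
    partition: PanGenomePartition,
    genes: list[Gene],
    replicons: list[Replicon],
) -> list[SharedPair]:
    """All (plasmid gene, chromosome gene) combinations of each shared family
    within each host. Pair ids are stable across runs."""
    gene_index = index_genes(genes)
    rep_index = index_replicons(replicons)
    pairs: list[SharedPair] = []
    for fid in partition.shared_family_ids():
        fam = partition.families[fid]
        by_host: dict[str, dict[str, list[str]]] = {}
        for gid in sorted(fam.members):
            g = gene_index[gid]
            rep = rep_index[g.replicon_id]
            side = "plasmid" if rep.kind == RepliconKind.PLASMID else "chromosome"
            by_host.setdefault(rep.host_id, {"plasmid": [], "chromosome": []})[side].append(gid)
        for host in sorted(by_host):
            for pg in by_host[host]["plasmid"]:
                for cg in by_host[host]["chromosome"]:
                    pairs.append(
                        SharedPair(
                            pair_id=f"{fid}|{host}|{pg}|{cg}",
                            family_id=fid,
                            host_id=host,
                            plasmid_gene=pg,
                            chromosome_gene=cg,
                        )
                    )
    return pairs


def labels_table(partition: PanGenomePartition) -> pd.DataFrame:
    rows = [
        {
            "family_id": fid,
            "chromosomal_label": l.chromosomal,
            "plasmid_label": l.plasmid,
            "shared": l.shared,
            "n_chromosomes_present": l.n_chromosomes_present,
            "n_plasmids_present": l.n_plasmids_present,
        }
        for fid, l in sorted(partition.labels.items())
    ]
    return pd.DataFrame(rows)
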