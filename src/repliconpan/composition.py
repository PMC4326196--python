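"""Base composition (GC, synonymous GC3) and codon adaptation index (CAI),
with Mann-Whitney comparisons between gene sets.

CAI follows the classical definition: per-codon relative adaptiveness
w_c = f_c / max_{c' synonymous with c} f_{c'} tallied over a reference gene
set, and the CAI of a gene is the geometric mean of w over its codons,
excluding ATG, TGG and stop codons (codons with no synonymous choice).
The default reference set downstream is the chromosomal core gene set of the
analyzed data itself.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import Gene

_BASES = "TCAG"
STOP_CODONS = {"TAA", "TAG", "TGA"}

# standard genetic code (table 11 coincides with table 1 on codon->aa)
_CODON_TABLE: dict[str, str] = {}
_AA_ORDER = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    _CODON_TABLE[_b1 + _b2 + _b3] = _AA_ORDER[_i]

SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    if _aa != "*":
        SYNONYMOUS.setdefault(_aa, []).append(_codon)

# codons excluded from CAI products: single-codon amino acids and stops
EXCLUDED_CODONS = {"ATG", "TGG"} | STOP_CODONS


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def gc_content(seq: str) -> float:
    """Fraction of G+C bases; rejects empty or N-containing sequences."""
    if not seq:
        raise ValueError("empty sequence")
    if "N" in seq:
        raise ValueError("sequence contains N; GC content undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc3(seq: str) -> float:
    """Synonymous third-position GC: fraction of G/C at the third position of
    codons that have a synonymous alternative (ATG, TGG and stops excluded)."""
    counted = 0
    gc = 0
    for codon in codons_of(seq):
        if codon in EXCLUDED_CODONS:
            continue
        counted += 1
        if codon[2] in "GC":
            gc += 1
    if counted == 0:
        raise ValueError("no synonymously variable codons in sequence")
    return gc / counted


@dataclass
class CAIModel:
    """Relative adaptiveness w per codon, from a reference gene set."""

    w: dict[str, float]
    reference: str = "unspecified"
    pseudo_count: float = 0.5

    def __post_init__(self) -> None:
        for aa, codons in SYNONYMOUS.items():
            if len(codons) < 2:
                continue
            wmax = max(self.w[c] for c in codons)
            if not math.isclose(wmax, 1.0):
                raise ValueError(f"max w over synonyms of {aa} must be 1, got {wmax}")
        if any(v <= 0 for v in self.w.values()):
            raise ValueError("all w must be positive")


def build_cai_model(
    reference_genes: list[Gene] | list[str],
    reference: str = "user reference",
    pseudo_count: float = 0.5,
) -> CAIModel:
    """Tally codon frequencies over the reference and compute w per
    synonymous family; zero counts get a pseudo-count before the ratio."""
    if not reference_genes:
        raise ValueError("empty CAI reference set")
    counts: dict[str, float] = {c: 0.0 for c in _CODON_TABLE}
    for item in reference_genes:
        seq = item.cds_nt if isinstance(item, Gene) else item
        for codon in codons_of(seq):
            counts[codon] += 1.0
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS.items():
        cts = [counts[c] if counts[c] > 0 else pseudo_count for c in codons]
        m = max(cts)
        for c, ct in zip(codons, cts):
            w[c] = ct / m
    for c in STOP_CODONS:
        w[c] = 1.0  # never used in products; placeholder
    return CAIModel(w=w, reference=reference, pseudo_count=pseudo_count)


def cai(gene: Gene | str, model: CAIModel) -> float:
    """Geometric mean of w over the gene's codons, excluding ATG/TGG/stops."""
    seq = gene.cds_nt if isinstance(gene, Gene) else gene
    logs = [
        math.log(model.w[c]) for c in codons_of(seq) if c not in EXCLUDED_CODONS
    ]
    if not logs:
        raise ValueError("no countable codons in gene (all excluded)")
    return math.exp(sum(logs) / len(logs))


# ------------------------------------------------------------------ tests


@dataclass
class SetComparison:
    name_a: str
    name_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    test: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def _mwu_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a, with ties counted half."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(values_a, values_b, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over all C(n_a+n_b, n_a) group assignments of the pooled
    values when the pooled size is at most ``exact_max_n`` (ties handled by
    half-counting); tie-corrected normal approximation otherwise. Returns
    (U of sample a, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _mwu_statistic(a, b)
    n_a, n_b = a.size, b.size
    if n_a + n_b <= exact_max_n:
        pooled = np.concatenate([a, b])
        idx = range(n_a + n_b)
        lo = hi = 0
        total = 0
        for combo in itertools.combinations(idx, n_a):
            total += 1
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(combo)] = True
            u = _mwu_statistic(pooled[mask], pooled[~mask])
            if u <= u_obs:
                lo += 1
            if u >= u_obs:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(min(1.0, p))
    return u_obs, p


def compare_sets(values_a, values_b, name_a: str = "A", name_b: str = "B") -> SetComparison:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    u, p = mann_whitney(a, b)
    return SetComparison(
        name_a=name_a,
        name_b=name_b,
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        test="mann-whitney",
        statistic=u,
        p_value=p,
    )


# ------------------------------------------------------------------ report


@dataclass
class CompositionReport:
    per_gene: pd.DataFrame  # gene_id, set, gc, gc3, cai
    comparisons: list[SetComparison] = field(default_factory=list)


def composition_report(
    genes: list[Gene],
    partition,
    cai_model: CAIModel | None = None,
    representatives: dict[str, str] | None = None,
    seed: int = 0,
) -> CompositionReport:
    """Per-set GC and CAI with pairwise Mann-Whitney comparisons.

    Sets compared: all plasmid genes vs the chromosomal unique, distributed
    and core sets. One representative gene per family is used (matching the
    one-gene-per-family sampling of the sets) unless ``representatives`` is
    passed explicitly as an empty dict, which switches to per-gene mode.
    """
    from .pangenome import pick_representatives

    gene_index = {g.gene_id: g for g in genes}
    families = list(partition.families.values())
    if representatives is None:
        representatives = pick_representatives(families, seed=seed)

    if cai_model is None:
        core_fams = [
            fid for fid, l in partition.labels.items() if l.chromosomal == "core"
        ]
        ref = [gene_index[representatives[f]] for f in core_fams if f in representatives]
        if not ref:
            raise ValueError("no chromosomal core families available as CAI reference")
        cai_model = build_cai_model(ref, reference="chromosomal core (self)")

    rows = []
    set_of_family = {}
    for fid, l in partition.labels.items():
        if l.plasmid != "absent":
            set_of_family.setdefault(fid, []).append("plasmid")
        if l.chromosomal != "absent":
            set_of_family.setdefault(fid, []).append(f"chromosomal_{l.chromosomal}")
    for fid, sets in sorted(set_of_family.items()):
        gids = (
            [representatives[fid]]
            if representatives
            else sorted(partition.families[fid].members)
        )
        for gid in gids:
            g = gene_index[gid]
            for s in sets:
                rows.append(
                    {
                        "gene_id": gid,
                        "family_id": fid,
                        "set": s,
                        "gc": gc_content(g.cds_nt),
                        "gc3": gc3(g.cds_nt),
                        "cai": cai(g, cai_model),
                    }
                )
    per_gene = pd.DataFrame(rows)

    comparisons: list[SetComparison] = []
    for other in ("chromosomal_unique", "chromosomal_distributed", "chromosomal_core"):
        for metric in ("gc", "cai"):
            va = per_gene.loc[per_gene["set"] == "plasmid", metric].to_numpy()
            vb = per_gene.loc[per_gene["set"] == other, metric].to_numpy()
            if va.size == 0 or vb.size == 0:
                warnings.warn(f"empty set in comparison plasmid vs {other}; skipped")
                continue
            comparisons.append(
                compare_sets(va, vb, name_a=f"plasmid:{metric}", name_b=f"{other}:{metric}")
            )
    return CompositionReport(per_gene=per_gene, comparisons=comparisons)
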