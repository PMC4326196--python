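"""Functional-category (COG) profiles per gene set.

The category search itself (RPSBLAST against a COG profile database) is an
external step; this module consumes its tabular output — one row per hit with
gene_id, cog_id, single-letter categories, evalue, bitscore — keeps hits at or
below an e-value cutoff, reads the distinct categories of the top three hits
per gene, counts families per category per gene set, and tests plasmid vs
chromosome proportions with one-sided exact binomial tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

COG_CATEGORIES = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

HIT_TABLE_COLUMNS = ["gene_id", "cog_id", "categories", "evalue", "bitscore"]


@dataclass
class CategoryAssignment:
    """gene_id -> up to three category letters."""

    categories: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for gid, cats in self.categories.items():
            if len(cats) > 3:
                raise ValueError(f"gene {gid}: more than 3 categories")
            bad = set(cats) - COG_CATEGORIES
            if bad:
                raise ValueError(f"gene {gid}: unknown categories {sorted(bad)}")


def read_cog_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def assign_categories(
    hit_table: pd.DataFrame, evalue_max: float = 0.001, top_n: int = 3
) -> CategoryAssignment:
    """Filter hits at evalue <= cutoff, sort by (evalue asc, bitscore desc,
    cog_id asc), and record the distinct categories of the top ``top_n`` hits
    per gene. Genes without passing hits stay unassigned."""
    passing = hit_table[hit_table["evalue"] <= evalue_max].copy()
    passing = passing.sort_values(
        ["gene_id", "evalue", "bitscore", "cog_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out: dict[str, tuple[str, ...]] = {}
    for gid, grp in passing.groupby("gene_id", sort=True):
        cats: list[str] = []
        for cat_field in grp["categories"].head(top_n):
            for c in str(cat_field):
                if c in COG_CATEGORIES and c not in cats:
                    cats.append(c)
        out[gid] = tuple(cats[:3])
    return CategoryAssignment(categories=out)


@dataclass
class CategoryProfile:
    counts: pd.DataFrame  # set, category, family_count, proportion
    totals: dict[str, int]  # set -> annotated families
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)


def proportion_binomial_test(
    k_a: int, n_a: int, k_b: int, n_b: int, direction: str = "greater"
) -> float:
    """One-sided exact binomial test of sample A's count against the null
    proportion p0 = k_b / n_b (exact tail sum)."""
    if n_b == 0:
        raise ValueError("reference sample size n_b is zero")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    p0 = k_b / n_b
    return float(stats.binomtest(k_a, n_a, p0, alternative=direction).pvalue)


def category_proportions(
    assignment: CategoryAssignment,
    partition,
    representatives: dict[str, str],
    sets: tuple[str, ...] = ("plasmid", "chromosomal_core", "chromosomal_distributed", "chromosomal_unique"),
    test_pair: tuple[str, str] = ("plasmid", "chromosome"),
) -> CategoryProfile:
    """Count families per category per set, using each family's representative
    gene; a family carrying k categories (k <= 3) counts toward all k.

    Proportions are over annotated families of the set. The test block
    compares the pooled plasmid sets against the pooled chromosomal sets per
    category, in both directions, with one-sided binomial tests.
    """
    fam_sets: dict[str, list[str]] = {s: [] for s in sets}
    for fid, l in partition.labels.items():
        if "plasmid" in fam_sets and l.plasmid != "absent":
            fam_sets["plasmid"].append(fid)
        key = f"chromosomal_{l.chromosomal}"
        if key in fam_sets:
            fam_sets[key].append(fid)

    rows = []
    totals: dict[str, int] = {}
    annotated: dict[str, dict[str, int]] = {}
    for s, fams in fam_sets.items():
        counts: dict[str, int] = {}
        n_annot = 0
        for fid in fams:
            rep = representatives.get(fid)
            cats = assignment.categories.get(rep, ()) if rep else ()
            if not cats:
                continue
            n_annot += 1
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
        totals[s] = n_annot
        annotated[s] = counts
        for c in sorted(counts):
            rows.append(
                {
                    "set": s,
                    "category": c,
                    "family_count": counts[c],
                    "proportion": counts[c] / n_annot if n_annot else float("nan"),
                }
            )
    counts_df = pd.DataFrame(rows)

    # plasmid vs chromosome tests, pooling the chromosomal sets
    pls_counts: dict[str, int] = dict(annotated.get("plasmid", {}))
    n_pls = totals.get("plasmid", 0)
    chr_counts: dict[str, int] = {}
    n_chr = 0
    for s in fam_sets:
        if s.startswith("chromosomal_"):
            n_chr += totals[s]
            for c, k in annotated[s].items():
                chr_counts[c] = chr_counts.get(c, 0) + k
    test_rows = []
    if n_pls and n_chr:
        all_cats = sorted(set(pls_counts) | set(chr_counts))
        m = len(all_cats)
        for c in all_cats:
            k_a = pls_counts.get(c, 0)
            k_b = chr_counts.get(c, 0)
            p_enr = proportion_binomial_test(k_a, n_pls, k_b, n_chr, "greater")
            p_dep = proportion_binomial_test(k_a, n_pls, k_b, n_chr, "less")
            direction = "enriched" if k_a / n_pls >= k_b / n_chr else "depleted"
            p = p_enr if direction == "enriched" else p_dep
            test_rows.append(
                {
                    "category": c,
                    "plasmid_count": k_a,
                    "plasmid_total": n_pls,
                    "chromosome_count": k_b,
                    "chromosome_total": n_chr,
                    "direction": direction,
                    "p_one_sided": p,
                    "p_bonferroni": min(1.0, p * m),
                }
            )
    return CategoryProfile(
        counts=counts_df, totals=totals, tests=pd.DataFrame(test_rows)
    )
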