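"""One-call orchestration of the full analysis with a deterministic report.

Stages run in dependency order: cluster -> classify -> composition /
category profile / uniformity / flanks / blocks / operons. Optional inputs
(category hit table, operon table) mark their stage "skipped" when absent.
Rerunning with the same inputs and seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cog as cog_mod
from . import composition as comp_mod
from . import flanks as flank_mod
from . import pangenome as pan_mod
from . import synteny as syn_mod
from . import uniformity as uni_mod
from .cluster import cluster_pipeline
from .io import load_dataset, write_cluster_table
from .records import Gene, Replicon, RepliconKind

REPORT_SCHEMA = {
    "required": {
        "seed": int,
        "parameters": dict,
        "n_replicons": int,
        "n_genes": int,
        "n_families": int,
        "set_counts": dict,
        "shared_breakdown": list,
        "flank_tally": dict,
        "stages": dict,
    }
}


def validate_report(report: dict) -> None:
    """Check the report against the shipped structural schema."""
    for key, typ in REPORT_SCHEMA["required"].items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}, "
                             f"expected {typ.__name__}")


@dataclass
class RunConfig:
    manifest: str
    outdir: str
    seed: int = 0
    min_protein_len: int = 50
    min_identity: float = 70.0
    min_coverage: float = 70.0
    inflation: float = 2.0
    up_len: int = 200
    down_len: int = 100
    flank_min_identity: float = 70.0
    flank_min_coverage: float = 50.0
    uniformity_method: str = "averaged_resample"
    uniformity_resamples: int = 200
    max_gap_genes: int = 1
    min_block: int = 2
    cog_table: Optional[str] = None
    operon_table: Optional[str] = None
    log_level: str = "INFO"


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write TSV outputs plus a JSON + Markdown report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    replicons, genes = load_dataset(config.manifest)
    return run_all_in_memory(config, replicons, genes, outdir)


def run_all_in_memory(
    config: RunConfig,
    replicons: list[Replicon],
    genes: list[Gene],
    outdir: Path | None = None,
) -> dict:
    stages: dict[str, str] = {}

    # --- clustering
    cluster_res = cluster_pipeline(
        genes,
        min_len=config.min_protein_len,
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
        inflation=config.inflation,
    )
    families = cluster_res.families
    stages["cluster"] = "ok"

    # --- partition
    partition = pan_mod.classify_families(families, replicons)
    breakdown = pan_mod.shared_breakdown(partition)
    pairs = pan_mod.shared_pairs_same_host(partition, genes, replicons)
    representatives = pan_mod.pick_representatives(families, seed=config.seed)
    stages["classify"] = "ok"

    # --- composition
    comp = comp_mod.composition_report(
        genes, partition, representatives=representatives, seed=config.seed
    )
    stages["composition"] = "ok"

    # --- functional categories (optional input)
    profile = None
    if config.cog_table:
        hit_table = cog_mod.read_cog_hits(config.cog_table)
        assignment = cog_mod.assign_categories(hit_table)
        profile = cog_mod.category_proportions(assignment, partition, representatives)
        stages["cogstats"] = "ok"
    else:
        stages["cogstats"] = "skipped"

    # --- positional uniformity
    family_of = {g: f.family_id for f in families for g in f.members}
    uniformity_rows = []
    for rep in replicons:
        positions = uni_mod.shared_positions(rep, genes, partition, family_of)
        if not positions:
            continue
        res = uni_mod.uniformity_test(
            positions,
            rep.length_bp,
            method=config.uniformity_method,
            n_resamples=config.uniformity_resamples,
            seed=config.seed,
            replicon_id=rep.replicon_id,
        )
        uniformity_rows.append(
            {
                "replicon_id": rep.replicon_id,
                "n": res.n_positions,
                "method": res.method,
                "statistic": res.statistic,
                "p": res.p_value,
                "rejection_fraction": res.rejection_fraction,
            }
        )
    stages["uniformity"] = "ok"

    # --- flanks
    flank_results, tally = flank_mod.classify_pairs(
        pairs,
        genes,
        replicons,
        up_len=config.up_len,
        down_len=config.down_len,
        min_identity=config.flank_min_identity,
        min_coverage=config.flank_min_coverage,
    )
    stages["flanks"] = "ok"

    # --- synteny blocks over every plasmid/chromosome couple
    block_rows = []
    plasmid_ids = [r.replicon_id for r in replicons if r.kind == RepliconKind.PLASMID]
    chromosome_ids = [r.replicon_id for r in replicons if r.kind == RepliconKind.CHROMOSOME]
    all_blocks = []
    for pid in plasmid_ids:
        for cid in chromosome_ids:
            bp = syn_mod.pairs_between(partition, genes, pid, cid)
            if len(bp) < config.min_block:
                continue
            blocks = syn_mod.detect_blocks(
                bp, genes, pid, cid, max_gap_genes=config.max_gap_genes, min_block=config.min_block
            )
            all_blocks.extend(blocks)
    if all_blocks:
        block_rows = syn_mod.blocks_table(all_blocks, genes).to_dict("records")
    stages["blocks"] = "ok"

    # --- operons (optional input)
    operon_tally = None
    if config.operon_table:
        table = syn_mod.read_operon_table(config.operon_table)
        shared_gene_ids = {
            g
            for f in families
            if partition.labels[f.family_id].shared
            for g in f.members
        }
        operon_tally = syn_mod.operon_overlap(shared_gene_ids, table)
        stages["operons"] = "ok"
    else:
        stages["operons"] = "skipped"

    report = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k not in ("outdir",)
        },
        "n_replicons": len(replicons),
        "n_genes": len(genes),
        "n_families": len(families),
        "set_counts": partition.set_counts(),
        "shared_breakdown": breakdown.to_dict("records"),
        "flank_tally": tally.as_dict(),
        "uniformity": uniformity_rows,
        "blocks": block_rows,
        "composition_comparisons": [dataclasses.asdict(c) for c in comp.comparisons],
        "category_tests": profile.tests.to_dict("records") if profile is not None else [],
        "operon_tally": dataclasses.asdict(operon_tally) if operon_tally else None,
        "stages": stages,
    }
    validate_report(report)

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_cluster_table(families, outdir / "groups.txt")
        pan_mod.labels_table(partition).to_csv(outdir / "family_labels.tsv", sep="\t", index=False)
        pd.DataFrame([partition.set_counts()]).to_csv(outdir / "set_counts.tsv", sep="\t", index=False)
        breakdown.to_csv(outdir / "shared_breakdown.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "pair_id": p.pair_id,
                    "family_id": p.family_id,
                    "host_id": p.host_id,
                    "plasmid_gene": p.plasmid_gene,
                    "chromosome_gene": p.chromosome_gene,
                }
                for p in pairs
            ]
        ).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        comp.per_gene.to_csv(outdir / "composition_per_gene.tsv", sep="\t", index=False)
        flank_mod.results_table(flank_results).to_csv(outdir / "flank_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(uniformity_rows).to_csv(outdir / "uniformity.tsv", sep="\t", index=False)
        pd.DataFrame(block_rows).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        if profile is not None:
            profile.counts.to_csv(outdir / "category_counts.tsv", sep="\t", index=False)
            profile.tests.to_csv(outdir / "category_tests.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _write_markdown(report, outdir / "report.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = [
        "# Replicon pan-genome report",
        "",
        f"Seed: {report['seed']}",
        f"Replicons: {report['n_replicons']}  Genes: {report['n_genes']}  "
        f"Families: {report['n_families']}",
        "",
        "## Set counts",
        "",
    ]
    for k, v in sorted(report["set_counts"].items()):
        lines.append(f"- {k}: {v}")
    lines += ["", "## Flank tally", ""]
    for k, v in sorted(report["flank_tally"].items()):
        lines.append(f"- {k}: {v}")
    lines += ["", "## Stages", ""]
    for k, v in sorted(report["stages"].items()):
        lines.append(f"- {k}: {v}")
    path.write_text("\n".join(lines) + "\n")
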