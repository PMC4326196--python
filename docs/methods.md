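# Methods

## The pipeline

`repliconpan` treats a dataset as a set of replicons (chromosomes and
plasmids, each tagged with the host strain it lives in) with annotated CDS
features. All coordinates are 1-based inclusive in memory; proteins are
always re-translated from the nucleotide record with the bacterial genetic
code (table 11, terminal stop stripped) so that clustering and composition
statistics can never disagree with the sequence on disk. `N` is allowed in
intergenic sequence but rejected inside a CDS, where GC and CAI would be
undefined.

### Gene families

Proteins strictly longer than 50 residues enter an all-vs-all local
alignment (Smith–Waterman with the Gotoh affine-gap recursion; BLOSUM62, gap
open 11, extend 1 — the BLASTP defaults; `X` scores 0 against everything).
Tie-breaking is fully deterministic (best cell at smallest row-major index;
diagonal over vertical over horizontal moves; open over extend), which is
what makes exact agreement with an independently written dynamic program
testable. An exact edit-distance screen (edlib, global mode, threshold 0.65
of the longer length) skips pairs that provably cannot reach the similarity
gate; it can be disabled.

An edge survives iff identity > 70% **and** the alignment covers > 70% of
*both* proteins (all strict). The coverage requirement is applied on both
sides because a symmetric graph needs a symmetric gate. When hits are
imported from 12-column tabular output instead, coverage is
alignment_length / protein length per side and reciprocal asymmetric hits
keep the better-scoring direction; only the single best HSP per pair is
used.

MCL runs per connected component on the column-stochastic matrix with
self-loops set to each node's maximum incident edge weight, inflation 2,
pruning threshold 1e-5 and convergence tolerance 1e-8 (at most 100
iterations, with a warning on non-convergence). Clusters are read from the
attractor rows; a node attracted to two clusters goes to the one with the
larger intra-cluster weight, ties to the cluster holding the
lexicographically smallest node. Edge weights are raw alignment scores
(bitscores when imported): MCL needs positive weights and is invariant to
uniform scaling, which the tests assert. Family ids are re-issued
zero-padded in order of each family's smallest member, so output is
invariant to input order.

Open choices resolved here: whether the 70% gate applies to the local HSP or
globally is unstated in the source analyses; the local-alignment reading is
adopted. Multiple HSPs per pair are not summed.

### Pan-genome sets

Presence is binary per replicon (paralogs count in the census, not in
presence). With `n` chromosomes: core ⇔ on all `n`; unique ⇔ on exactly 1;
distributed ⇔ 2..n−1; the plasmid side uses distributed (≥ 2) and unique
(1) only. Shared ⇔ at least one member on each class, independent of the
labels. The extended core defaults to ≥ n−1 chromosomes: "more than n−1"
with exactly n chromosomes would collapse onto the core, and the reference
tallies include families at n−1, so ≥ n−1 is the documented default rather
than a silent guess. Same-host pairing emits every (plasmid member,
chromosome member) combination within a family and host; how the reference
analysis deduplicated its pairs is not decomposable from its totals, so the
all-combinations rule is the default and is kept stable by construction in
the generator (exactly one pair per planted shared family).

### Composition

Per-gene GC is the headline metric; synonymous GC3 (third positions of
codons with a synonymous alternative — ATG, TGG and stops excluded) is
emitted for diagnostics and is the quantity the generator targets. CAI uses
the classical relative-adaptiveness table: codon counts over a reference
set, `w = count / max(count over synonyms)`, zero counts floored by a 0.5
pseudo-count before the ratio; the CAI of a gene is the geometric mean of
`w` over codons, excluding ATG/TGG/stops. The default reference is the
chromosomal core set of the analyzed data itself (one representative gene
per family): an external-organism reference would be biologically wrong
here, and the self-referenced core is reproducible from the input alone. A
user FASTA can override it. Set comparisons default to one representative
gene per family (seeded uniform draw), matching how the gene sets are
assembled in the first place; a per-gene mode exists.

The Mann–Whitney test enumerates all group assignments exactly when the
pooled sample is ≤ 12 (ties half-counted, two-sided p = 2·min(tails), capped
at 1) and otherwise uses the tie-corrected normal approximation.

### Functional categories

The profile search itself (RPSBLAST against a COG database) is an external
step; the module consumes its tabular output. Hits pass at e ≤ 0.001, are
ordered by (evalue, −bitscore, cog_id) and the distinct letters of the top
three hits label the gene. Families are counted per category via their
representative; a family with k ≤ 3 letters counts toward all k, so
proportions may sum above 1 (documented). The binomial test treats the
plasmid family count of a category as the observation against the pooled
chromosomal proportion as the null, one-sided in the direction of the
observed deviation; raw p-values are reported with a Bonferroni column
alongside, no correction applied by default.

### Positional uniformity

The sample is the pooled start and end coordinates of shared genes on one
replicon (always twice the gene count). The single-draw Mann–Whitney
construction is kept as `paper_single_draw` for fidelity, but it carries
resampling noise from its one random reference draw, so the default
averages the p-value over many seeded draws and reports the rejection
fraction, and a one-sample KS test against Uniform(1, L) is offered as the
principled check. The Mann–Whitney construction is location-sensitive only:
symmetric clustering at both replicon ends can evade it; that is a property
of the method being reproduced, not a defect of the implementation, and the
KS method is the remedy. Circular replicons are used as given (no origin
rotation).

### Flanks

200 bp upstream and 100 bp downstream per gene, strand-aware; flanks wrap
the origin on circular replicons and truncate with a flag on linear ones.
"Similar" is not defined by the source analysis, so the default is the
documented choice: local nucleotide alignment (match +2 / mismatch −3, gap
open 5 / extend 2), similar ⇔ identity > 70% over > 50% of the shorter
flank; both thresholds are exposed. No coding-sequence masking is applied.
Pairs on the same replicon are excluded. Random 200-bp pairs essentially
never pass this gate (asserted over 100 random pairs in the tests), which
is what makes the planted flank classes exactly recoverable.

### Blocks and operons

Blocks chain homologous gene pairs by gene-order adjacency, not base-pair
distance: two pairs chain when at most `max_gap_genes` (default 1)
non-shared genes intervene on *each* replicon and the plasmid-side order is
consistently parallel or consistently inverted. Gap 0 recovers an
uninterrupted run; 1 tolerates single annotation discrepancies. Per-pair
nucleotide identity is global: 1 − edit distance / longer length (edlib),
averaged over the block. Operon predictions are imported (the prediction
itself is an external tool's job); an operon is counted when at least two
of its genes are shared, matching the smallest reported operon size of 2.

## The synthetic-data generator

The generator is the pipeline's measuring instrument: it plants a known
pan-genome and emits the truth table the tests compare against. Per family
it draws an ancestor protein (uniform over the 20 residues, length uniform
on 80–260 aa), mutates it per member at the within-family divergence
(default 0.05 substitutions/site — pairwise identity ≈ 90%, comfortably
above the 70% gate, while independent ancestors sit near ≈ 6% identity,
far below it), and back-translates each member with a class-specific
synonymous-codon model: third-position G/C mass equals the class GC3 target
and a bias parameter tilts mass toward one designated optimal codon per
amino acid (bias 1 forces CAI = 1 against a matching reference). Default
GC3 targets (core 0.45, chromosomal variable 0.36, plasmid 0.30, shared
0.33) reproduce the qualitative core-vs-plasmid composition contrast of
real data.

Family placement follows the set definitions: core on every chromosome,
distributed on 2..n−1 (prevalence uniform), unique on one replicon, shared
on ≥ 1 chromosome and ≥ 1 plasmid with exactly one same-host pair each
(second-plasmid copies are placed in hosts whose chromosome lacks the
family, so the pair count stays exactly one per family). The shared
families' chromosome-side profile defaults to roughly the proportions seen
in real data (≈ 7% core, 57% distributed, 36% unique) and half of the
distributed-shared / a third of the unique-shared families get a second
plasmid copy. Flank classes are planted at the approximate real-data
fractions (0.33 / 0.08 / 0.10 / 0.49) as exact largest-remainder counts:
"similar" flanks are copied between the pair (2% divergence), "different"
flanks are left as independent random sequence.

Genes are laid in random order and strand with intergaps of at least 350 bp
(geometric tail, mean +150 bp) so the 200+100 bp flank windows can never
overlap a neighboring CDS; clustered placement packs the genes into a
configurable fraction of the replicon instead. Replicon lengths are sized
to fit their genes (an optional capacity cap turns overflow into an error).
A transfer block is planted by appending a contiguous run of new genes to
the chromosome and copying the whole region to the plasmid with per-base
substitution at 1 − identity, constrained so no CDS gains an internal stop
and start/stop codons stay intact (first and last codons untouched); at 57
genes the realized mean identity lands within a few hundredths of a point
of the target. Operon tables and functional-category hit tables (top-three
hits realizing the planted letters plus decoys beyond the rank and e-value
cutoffs) are emitted with their own planted tallies.

All randomness flows from one seed through named sub-streams (CRC32-hashed
stream names as spawn keys), so the same seed is byte-reproducible and
adding a replicon does not perturb existing sequences.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: realistic amino-acid composition (uniform residue
usage pushes coding GC above real *Bacillus* values; only the *contrasts*
between classes are meaningful), promoter/terminator motifs, rRNA/tRNA
genes, pseudogenes, annotation errors, domain-level homology and gene
fusions, and genome-scale gene counts. The planted families are cleanly
separable by construction; real pan-genomes contain borderline families
that no threshold choice resolves cleanly.

## Problem sizes and numerical choices

The reference synthetic study used throughout testing is 5 chromosomes and
4 plasmids with 50/120/200/40/80/30 planted families (~1100 genes), a size
at which the complete all-vs-all alignment, clustering and downstream
stages run in seconds while still exercising every code path; the block
study plants 57 genes at 95% identity on a 2-chromosome / 1-plasmid
background. Calibration uses 500 uniform position sets of 100 points on a
1-Mb replicon.

Numerical details worth knowing: alignment scores are integer arithmetic
(no floating-point drift); MCL convergence is measured as the max absolute
matrix change; degenerate MCL components (all mass pruned) fall back to
strongest-column assignment; Mann–Whitney switches to enumeration at pooled
n ≤ 12; binomial tests are exact tail sums; report JSON is written with
sorted keys and no timestamps so determinism is byte-level.

## Known limitations

* O(n²) all-vs-all alignment is intended for desk-scale datasets (up to a
  few thousand proteins); for larger inputs precompute hits with BLAST and
  use the tabular importer.
* Stages always recompute; there is no up-to-date skipping of stage outputs.
* Flank similarity thresholds are a documented convention, not an inference
  of any published criterion; conclusions sensitive to them should use the
  threshold sweep.
* The uniformity Mann–Whitney method inherits the one-draw construction's
  blindness to dispersion-only departures; prefer the KS method for
  inference.
* Operon and functional-category inputs are trusted as given; no validation
  of their biological plausibility is attempted.
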