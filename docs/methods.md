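# Methods

This note documents the models behind `mtxworkbench`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions adopted where the design was genuinely open.

## The problem being modelled

In mucosal-tissue metatranscriptomics the ratio of microbial to host cells
is very low; after removal of host, rRNA and viral reads, only a small
fraction of a deeply sequenced library is informative about the microbiome.
The workbench reproduces this regime *in silico*: a mock community of known
composition is mixed with a host background either at the **cell** level
(SS-style synthetic samples) or at the **read** level (SD-style simulated
datasets), and every read carries a hidden truth label so that classifier
precision/recall can be measured exactly.

## Synthetic data generator

**Reference universe.**  Species genomes are i.i.d. uniform DNA
(default 10 kb).  Congeneric species share one identical 62 bp block
(2 × k for the default k = 31), implanted mid-genome, so a controlled subset
of k-mers resolves only to genus rank and exercises LCA labelling and
species reestimation.  Eight non-overlapping 900 bp genes per genome form
the species' transcript pool and pangenome; their translations populate the
peptide database (one gene family per gene — a stand-in for protein-level
clustering, which is not performed).  Host (30 × 3 kb), rRNA (5 × 1.5 kb) and
viral (5 × 5 kb) references are independent random pools.  Three
"contaminant" species in their own genera exist in the reference universe
but not in the community, mimicking reagent organisms that a classifier can
genuinely detect.

**Cell ratio vs read ratio.**  Sequencing samples transcripts, not cells.
Each host cell contributes `h` transcript units against
`cell_fraction × activity` units per bacterial species, giving an expected
host read share of

```
hf·h / (hf·h + (1 − hf)·Σ_s cf_s·a_s)
```

The default host transcript weight is **h = 15**: with an even 20-species
community this makes a 97 %-host-cell sample yield ≈ 0.2 % microbial reads,
the surviving-read fraction observed for the most host-rich synthetic
standards that motivated this design.  The weight is configurable; it is the
one deliberately calibrated constant of the generator.  Species with
`activity = 0` are transcriptionally silent and contribute no reads for any
seed — the mechanism behind the "19 of 20 species" scenario.

**Nuisance and noise.**  1 % rRNA and 0.2 % viral reads per library;
independent per-base substitution errors (default 0.5 %, no indels); 5 % of
reads receive a sub-Q20 quality tail starting between 55 % and 95 % of the
read so that sliding-window trimming shortens but does not discard them.
Base quality is otherwise constant (Q37); errors are drawn independently of
the quality string.

**Read-fraction mixtures** subsample a microbial and a host pool without
replacement (subsampler semantics) to exactly `round(hf·depth)` host reads
at fixed depth, deterministically per seed.  **Contaminant injection** adds
`Poisson(mass / concentration)` reads per contaminant taxon and sample
(constant contaminant mass), so contaminant frequency decays as
1/concentration across a dilution panel.

**What is not emulated:** rRNA-depletion chemistry, library PCR bias,
paired-end reads, indels, quality-dependent error rates, strain-level
variation, and real inter-genome homology beyond the planted blocks.
Passing benchmarks here therefore demonstrate the *logic* of the workflow
(thresholds, redistribution, decontamination, tier hand-off), not its
performance on real genomes, where k-mer uniqueness is far messier.

## Preprocessing

Trimming cuts at the *start* of the first failing window (the common
tool-internal alternative — cutting at the first failing base — differs by
at most window−1 bases); a read is discarded when the kept prefix is ≤ half
the original length.  Depletion replaces an aligner with canonical k-mer
containment (k = 31): a read is removed when ≥ 50 % of its k-mers occur in
the reference set.  Reads carrying ≥ 2 errors can drop below this fraction,
so a small percentage of true host reads survives; they remain unclassified
downstream and inflate no taxon.  The stage order host → virus → rRNA is
fixed to make per-stage accounting well defined; the three k-mer sets are
disjoint up to negligible random collisions, so a single labelled-table
lookup implements the sequential contract in one pass.

## k-mer LCA classification

Index: canonical (strand-minimum) k-mer → LCA over all source genomes.
Classification: direct hit counts per taxon; the candidate maximizes the
summed counts along its root path, ties broken to the deepest node and then
the lowest taxon id (determinism).  Confidence of node `t` is the fraction
of the read's k-mers (denominator: all k-mers over ACGT) that hit taxa in
the clade rooted at `t`; below-threshold candidates ascend one ancestor at a
time, re-testing the threshold at each step, and reads that fail at the root
are unclassified (their reported confidence is the sub-threshold root-clade
fraction).  Because clade confidence is monotone toward the root, a read is
classified iff its total hit fraction meets the threshold — which is why
raising the threshold can only move assignments rootward or to
unclassified, never create new species-level false positives.

Reestimation distributes every internal node's count over its descendant
species proportionally to their direct counts, falling back to per-species
distinct-k-mer totals when no descendant species has direct evidence.  This
is a deliberate simplification of Bayesian abundance reestimation that
preserves its two observable properties: exact count conservation and
species-level output.

## Marker profiling

Markers are windows (default 10 × 300 bp per species) drawn from the
*transcribed* gene pool — as real clade markers are genes — and verified
unique: any window sharing a k-mer with another species' genome (e.g. the
congeneric block) is rejected.  A read hits a marker when ≥ half its k-mers
occur in it; species detection requires `g_min` distinct hit markers
(default 3); quantification is the quantile-trimmed mean of marker coverages
(`floor(stat_q·m)` values dropped from each end of the sorted vector,
default `stat_q = 0.2`), normalized over detected species.  Because markers
tile only ~40 % of the transcript pool, marker sensitivity collapses as the
microbial read budget shrinks — reproducing the characteristic
marker-vs-k-mer contrast at high host fractions.

## Decontamination

For each taxon with ≥ 4 samples of nonzero frequency and known
concentration, two slope-fixed regressions of log frequency on log
concentration are compared: slope −1 (constant contaminant mass) and
slope 0 (resident taxon).  The score is `F_cdf(RSS₋₁/RSS₀; n−1, n−1)`;
scores below the threshold (default **0.1**, a conventional default for
frequency-based decontamination — the choice is a package decision, not an
empirically fitted value) flag the taxon unless it is whitelisted by id or
display name.  Zero frequencies are excluded from the fit rather than
pseudo-counted; taxa with insufficient data are retained and flagged as
such.  Name-based "unclassified" filtering removes taxa whose display name
contains a configurable marker substring.

## Functional profiling

The prescreen threshold (0.001) is applied to the *decontaminated,
renormalized* species profile (the natural reading of a pipeline that
decontaminates before functional analysis).  Nucleotide-tier assignment is
best k-mer containment with ties to the longest gene then smallest gene id;
"subject coverage" is the percentage of gene positions covered by ≥ 1
matched k-mer of its assigned reads, compared as ≥ 25 %.  Genes failing
coverage are dropped and their reads rerouted to the translated tier, which
translates reads in six frames, splits at stop codons, and votes by shared
peptide 8-mers; its contributions are community-level ("unclassified"
contributor).  RPK uses the gene's family length (median source-gene length
— identical to the gene length in the 1:1 toy pangenome); CPM sum-normalizes
RPK to 10⁶.  Reads are conserved exactly:
nucleotide-assigned + translated-assigned + unmapped = input.

## Evaluation conventions

Detection is `rel_abundance > 0` on the cleaned profile (profiles are scored
*after* decontamination).  Precision is defined as 0 for an empty detection
set so F1 is always computable.  Profile correlations use Spearman rank
correlation with average-rank ties over the union of taxa present in at
least one profile; pairs involving a constant profile are reported as
undefined (NaN), never as a number.

## Problem sizes and determinism

The bundled test suite and `scripts/acceptance.py` run the full pipeline at
depths of 2 × 10⁵ (pure mock) and 5 × 10⁵ reads (high-host designs), with
read pools of 1.2 × 10⁵ microbial / 5.2 × 10⁵ host reads and three
replicates per design — sizes chosen so each design finishes in minutes on
a single CPU while keeping ≥ 50 expected reads per species in the most
host-rich condition, comfortably above the detection boundary.  All
randomness flows through seeded NumPy generators; replicate streams are
derived with `SeedSequence([seed, key])`, so runs are exactly reproducible
per seed.

## Known limitations

Random toy genomes make species separation easier than in real clades
(k-mer uniqueness is near-total outside the planted blocks); the
contaminant model is pure 1/concentration with Poisson noise, with no
batch structure or cross-talk; the translated tier uses exact peptide
k-mer voting rather than gapped alignment, so it is blind to distant
homology; and mapping-quality-based filtering is out of scope because no
aligner is involved.
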