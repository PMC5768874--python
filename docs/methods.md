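# Methods

This note documents the models behind `osseq`, the parameters that matter,
and what the synthetic-data tests do and do not demonstrate.

## Assay geometry and coordinate conventions

All coordinates are 0-based half-open (BED convention). A probe's
`anchor_pos` is the first template position copied by polymerase
extension: a `+` probe occupies `[anchor − L, anchor)` and extends
rightward, a `−` probe occupies `[anchor + 1, anchor + 1 + L)` and extends
leftward. Read 1 is primed by the probe and therefore begins at a fixed
genomic position; Read 2 is primed from the universal adapter and begins
at the fragment's adapter-ligated end.

**Insert size** is defined as the distance from the probe anchor to the
adapter-ligated fragment end. The FASTQ Read 1 carries the probe sequence
as a prefix (and Read 2 may read through the extension into the probe
footprint when the molecule is shorter than the read length), but the
truth alignments the simulator writes are *probe-trimmed*: synthetic probe
bases are removed before analysis, mirroring how such pipelines eliminate
the probe's reference alleles from variant evidence. With that convention
the QC module's R1-start-to-R2-end distance equals the truth insert
exactly, and pileups over truth alignments see only genomic bases — this
is what makes the simulator's variant allele fractions recoverable without
bias (Read 2 read-through over the synthetic probe would otherwise dilute
every VAF by roughly L_probe/(insert + L_probe) ≈ 20%).

## Panel design

Candidates are enumerated per tiling window (one window per
`target_spacing_per_strand` = 100 bp, per strand) over anchor positions
and probe lengths (default 23–27 nt), and scored as a weighted sum of
components each normalized to [0, 1]:

| component | default rule |
|---|---|
| gc | 1 inside [0.35, 0.65], linear falloff over 0.15 |
| tm | 1 inside [58, 68] °C, falloff over 5 °C |
| homopolymer | 1 up to run of 5, linear to 0 at 2x |
| hairpin / self_dimer | longest self-complementary run vs. thresholds 5 / 8 |
| snp | 0 if the footprint overlaps a masked SNP, else 1 |
| specificity | 1 / (genome-wide occurrences of the 3' 16-mer) |
| position | fraction of the 150 nt extension window inside the ROI |
| coverage_gain | fraction of that window not already covered |

Melting temperature is the nearest-neighbor estimate (SantaLucia unified
dinucleotide table, configurable monovalent/divalent salt correction) via
Biopython. Selection is greedy per window — highest score at or above the
threshold (default 5.0 of a maximum 9.0), tie-broken by leftmost anchor
then `+` strand, so a design is bit-reproducible. Windows with no passing
candidate become explicit coverage-gap records. Candidates whose extension
window contains N are rejected (an all-N ROI yields gaps, not probes).
Pool cross-dimer screening flags pairs whose 3'-terminal tail of one probe
can anneal to a stretch of the other at or above a configurable run length
(default 6 bp).

The spacing target follows the assay's design density of one probe per
100 bp on each strand; the achieved per-strand spacing on non-degenerate
sequence stays within ±20% of the target.

## Library simulation

Each read pair is generated from a chosen probe (probabilities
proportional to the gene's copy ratio, so copy-number events scale depth),
a fragment length ~ Normal(550, 50) truncated at 100 bp, and a capture
insert

    insert = U + k * spacing,  U ~ Uniform{1..spacing},  k ~ Geometric(p),

truncated to fit the fragment, with spacing = 100 and p = 2/3. The
geometric term models the observation that the probe site nearest the
adapter is not always the one used; with these defaults the mean truth
insert is ~100 nt and the maximum ~600 nt. The p = 2/3 default is the
calibration that reproduces the 100 nt mean; the distributional form
(uniform offset + geometric skip) is this package's model choice, since
only the resulting insert statistics are observable.

Variants are applied per *molecule* (one Bernoulli(VAF) draw per variant
per fragment, shared by both reads), so observed alt fractions converge
binomially to the specified VAF. Only SNVs are supported at the read
level; insertion/deletion specs are carried in truth VCFs and exercised at
the callset-normalization level instead (read-level indel CIGARs would add
plumbing no downstream consumer here needs).

FFPE damage deaminates template cytosines per strand with probability
`deamination_rate`. With repair off, the polymerase inserts A opposite the
uracil: a `+`-probe read shows G>A, a `−`-probe read C>T — together the
C>T/A>G signature. With excision repair on, the lesion is removed without
corrective repair, so the template breaks and synthesis terminates at the
lesion: no transition base is ever emitted, and inserts shorten instead.
This matches a repair chemistry that excises damaged bases only — excision
cannot restore sequence, so modeling it as base correction would be wrong.
Deamination rates in clinical FFPE are poorly quantified, so the
defaults are illustrative: the demo uses 0.02/strand, at which excision
repair visibly shortens inserts (~100 → ~68 nt) while leaving libraries
analyzable. PCR duplicates re-emit a pair with the same fragment
coordinates at a configured rate; sequencing errors are uniform
substitutions at 10⁻³ per base with constant Q30 qualities.

`depth_target` is converted to a pair count through the expected aligned
bases per pair (both reads cover the extension, whose analytic mean length
follows from the capture model), so requested and realized on-target
coverage agree for undamaged libraries; excision repair lowers realized
coverage below target by shortening molecules, which is faithful to the
assay.

The direct per-ROI coverage simulator draws negative binomial depths
(default dispersion 400, i.e. ~5% CV beyond Poisson) around
`mean_depth` x copy_ratio x a lognormal per-ROI capture bias (sd 0.3)
shared between test and control. The shared bias is the region-specific
effect the control-ratio step is designed to cancel; the sample-specific
dispersion is kept small because capture efficiency per region is highly
reproducible between libraries of the same panel. Defaults
(16 ROIs/gene, 2000X) mirror a 130-gene panel of ~2100 ROIs sequenced to
thousands-fold coverage.

## Read QC

Quality pre-processing masks bases below Phred 28 as N rather than
trimming, preserving pair coordinates. A pair is on-target iff its probe
is identified from the Read 1 prefix, the mate orientation matches the
probe strand, the alignment overlaps the probe's ROI ± flank, and the
insert is ≤ 1.5 kb; the recorded reason is the first failed criterion.
The on-target denominator includes ambiguous-probe pairs. Duplicates are
keyed on (probe id, fragment-end position, orientation) — Read 1's start
is fixed by the probe, so a both-end key would over-collapse these
libraries — retaining the highest summed base quality.

Coverage metrics are computed over ROI bases from on-target, non-duplicate
pairs. The fold 80 base penalty is mean(non-zero coverage) divided by its
20th percentile, with the percentile taken as the value at rank
⌈0.2·n⌉ of the ascending non-zero values (the convention is stated here
because several interpolation conventions exist); uniform coverage gives
exactly 1, and all-zero coverage is an error, not a zero.

## Variant calling and benchmarking

The caller is deliberately minimal and is **not** a numerical stand-in for
production callers. Germline genotyping compares binomial likelihoods of
the alt count under per-read alt probabilities e, 1/2, 1−e (e = sequencing
error, default 10⁻³) with Hardy-Weinberg priors from a per-site germline
allele frequency (default 10⁻³). Somatic calling is a two-node network:
the normal genotype posterior (observed from a normal pileup, or imputed
from the germline prior alone in tumor-only mode) feeds a tumor node that
either inherits the germline allele, carries a de novo somatic event
(prior default 10⁻⁶, tumor VAF marginalized uniformly, giving the
1/(depth+1) marginal), or is explained as error. Sites are labelled
germline/somatic/artifact by maximum posterior. The reporting filter
keeps somatic calls with ≥ 2 supporting reads at ≥ 40X total depth.

This calibration produces the assay's characteristic sensitivity cliff: a
5% VAF variant at 200X yields ~10 alt reads, decisively beating the error
explanation, while at 100X (~5 alt reads) the artifact posterior wins —
hence the recommended 200X floor.

Benchmarking matches variants after normalization (trim shared trailing
bases, extending left from the reference when an allele would empty; then
trim shared leading bases — verified against `bcftools norm` on mixed
indel representations) by (chrom, pos, ref, alt) within ROI ± flank,
ignoring genotypes (allele matching). Sensitivity = TP/(TP+FN),
PPV = TP/(TP+FP), both as percentages to one decimal. The true-negative
universe is the count of callable ROI bases minus truth positions, and
specificity defaults to TN/(TN+FN) — the definition as the assay states
it — with conventional TN/(TN+FP) available, since the stated form is
plausibly a transcription slip; both choices are logged in the result.

## Copy-number calling

Per sample, ROI depths are divided by the sample median (making the output
median 1 and the ratios invariant to total sequencing depth); log2 ratios
of test over control are taken per ROI, then aggregated per gene by the
median of the gene's ROI ratios (robust to a single aberrant ROI; mean
aggregation is trivially obtainable from the ratio table). Outliers among
gene ratios are flagged by the modified Thompson Tau test applied
iteratively: compute mean and sample SD of unflagged values, flag the most
deviant value if |x − mean|/SD exceeds

    tau = t · (n − 1) / (sqrt(n) · sqrt(n − 2 + t²)),

remove it and repeat. t is the two-tailed Student-t quantile at α (default
0.01) with df = n − 1 recomputed each iteration; a fixed df and an
explicit `t_critical` override are provided because published critical
values for this test do not always match a standard inverse-t (2.629 vs
2.614 at α = 0.01, df = 129 — the override lets users reproduce either).
Iteration is essential: a 1.32x event (log2 0.40) is masked in a single
pass by the SD inflation a 4.90x event causes, and emerges only after the
larger outliers are removed. Amplifications and deletions are treated
symmetrically (two-tailed). Testing runs on gene aggregates by default;
ROI-level testing is available behind `level="roi"`.

Expected null behaviour: with ~130 genes at α = 0.01 the iterative
procedure flags on the order of one noise gene per run; these alpha-level
false flags are reported, never suppressed. At 16 ROIs/gene and 2000X the
back-transformed estimate of a spiked gene lands within 10% of truth; at
the demo's read-level scale (2 ROIs/gene, ~100X) the 1.32x event sits at
the detection limit, which is a faithful property of the method, not an
implementation artifact.

## ddPCR arithmetic

Copies↔mass conversion uses 30 ng per 10,000 genome equivalents
(linear, invertible). Ligation efficiency is (2 x ligation)/control — the
ligation assay only amplifies the adapter-bearing strand while the control
amplifies both; values above 1 are flagged as measurement inconsistency
with a warning rather than an error. Copy ratios are normalized first to a
reference gene within each sample, then across samples to a diploid
control. Pooling volumes are computed from fragments/µL measured on a
configured dilution (default 10⁻⁶) toward a configured total load
(default 1.2x10⁹ fragments). Droplet-level Poisson correction is out of
scope; inputs are instrument-reported concentrations.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic
fixtures: reference genomes of 2–8 ROIs (panel/simulator unit tests), a
130-gene/260-ROI genome for the end-to-end demo, 130-gene/2080-ROI
coverage matrices for copy-number recovery, and 10⁵ read pairs for the
insert-size estimate — sizes chosen so each check isolates one property at
a precision where failure would be meaningful. Every stochastic step takes
an explicit seed; repeated runs are byte-identical (including gzip
outputs, written with a fixed timestamp).

## What the synthetic tests do not show

The simulator draws fragments independently, has no GC- or
length-dependent capture bias, no optical/index artifacts, no real
SNP/repeat structure, and applies damage uniformly per strand. Passing
recovery tests therefore demonstrates the *internal consistency* of the
methods — that the CNA caller recovers the ratios the coverage model
encodes, that VAF estimation is unbiased under the stated geometry — not
performance on real FFPE libraries. The Bayesian caller has no indel
model, no strand-bias or mapping-quality features, and a fixed error rate;
it exists so the toolkit is testable end to end, and its absolute
sensitivity figures should not be compared against production callers.
Specificity computed over a TN universe of callable bases is
panel-size-dependent by construction.
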