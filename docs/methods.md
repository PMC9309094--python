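# Methods

## Data model and coordinates

The unit of input is a per-sample table of copy-number segment calls, as
exported after TAPS/Rawcopy segmentation of CytoScan HD arrays: one row per
contiguous segment with chromosome, coordinates, probe support, an absolute
(integer) copy number and an allelic-imbalance/LOH flag. Internally all
coordinates are 0-based half-open so that length arithmetic is unambiguous;
the on-disk `seg_tsv` dialect is declared 1-based inclusive (the ChAS/Rawcopy
convention) and converted on read and write. Chromosome labels are
normalized (`chr12` → `12`), and the bundled hg19 chromosome-length,
centromere and gene-locus tables (MDM2, CDK4, JUN, MYOCD, KIT, NF1, CDKN2A,
DMD, ATRX, TP53) define the coordinate frame; locus coordinates follow the
standard UCSC hg19 gene annotation.

Overlapping segments within one sample (possible when upstream tools export
CN and LOH tracks separately) are resolved on construction: the segment with
more probe support wins and the other is truncated, with a logged warning.
Clean segmentation output is unaffected.

## Filtering

Segments are kept when length ≥ 100 kb **and** probe count ≥ 50 (closed
comparisons), restricted to autosomes by default. This is the standard
guard against constitutional CNVs and technical noise in diagnostic SNP-array
review. Sex chromosomes can be retained by flag for classifier evidence
(e.g. an Xq deletion), but never enter the similarity computation. After the
size filter, the ploidy baseline is estimated and segments that are neutral
non-LOH relative to it are dropped: only aberrations participate in
similarity, burden and classification. Filtering is idempotent, and an empty
result is valid — it means "no CNAs".

## Ploidy baseline

Visual ploidy assessment is replaced by a deterministic rule: the baseline
is the genome-length-weighted modal copy number over the autosomes, with
unsegmented territory counted as copy number 2. Ties break toward the copy
number closest to 2, then toward the lower value, so an all-neutral genome
is always diploid. The baseline is attached to the profile at filter time
and reused downstream, which keeps the aberration states of a profile stable
even after neutral segments are removed. Aberration state is a pure function
of (copy number, LOH flag, baseline): gain above, loss below, copy-neutral
LOH at baseline with the flag set.

## Genomic Jaccard similarity

For two filtered profiles the score is the number of base pairs aberrant in
both divided by the base-pair length of the union of their aberrant
territory. The default `directional` mode counts a base toward the
intersection only when the aberration state matches (gain with gain, loss
with loss, cnLOH with cnLOH); the union is state-agnostic territory in both
modes. An `any_aberration` mode (state-blind intersection) is provided for
sensitivity analysis, and `directional ≤ any_aberration` always. Copy-number
magnitude is deliberately ignored: a CN-3 and a CN-8 gain cover the same
base pairs. Two profiles with no aberrant bases score 1 (identical absence
of aberrations) but the result is flagged `both_empty`, and the pipeline
excludes empty profiles from clustering altogether.

All interval arithmetic is exact integer sweep-line algebra
(`cnaprofiler.intervals`); the test suite checks it against per-base
membership counting on a 10 kb-per-chromosome toy genome to 1e−12, and
checks the triangle inequality of 1 − J to 1e−9 in both modes.

## Clustering and matched-pair adjacency

Agglomerative clustering runs on distance 1 − J via scipy's linkage;
complete linkage is the default (`hclust`'s default, and the most
conservative choice for tight clusters), with average and single available.
Flat k-group views are produced by removing the k−1 highest merges with a
union-find pass, which is exact even with tied or zero merge heights (a
duplicated sample merges at height 0 and still yields n singletons at k=n).

"Clustered next to each other" for a matched CNB/surgical pair is
operationalized as the **cherry** criterion: the two leaves' first merge is
with each other. This is stricter than adjacency in some plotted leaf order,
which depends on arbitrary subtree rotations and is not used.

## CNA burden and the group comparison

Burden per sample is the number of copy-number shifts (aberrant segments
after coalescing touching same-state neighbours, so segmentation
granularity does not inflate counts; `coalesce=False` counts raw segments)
and the number of distinct autosomes with at least one aberration.

The benign/malignant comparison is a two-sided Wilcoxon rank-sum test with
a backend-independent contract: exact null distribution when both groups
have ≤ 12 observations and the pooled values contain no ties, otherwise the
normal approximation with tie and continuity corrections. The exact path is
verified against full enumeration of label assignments for all group sizes
up to 7. Group medians and quartiles are reported alongside the p-value.

## Rule-based classification

Features extracted per profile (all deterministic): ploidy baseline;
structural vs numerical change counts, where a coalesced segment covering
≥ 95% of its chromosome counts as numerical (a trisomy/monosomy-like call);
autosomes with structural/any aberrations; amplicons at CN ≥ baseline + 3
(≥ 5 in a diploid context — the conventional cytogenomic amplification
cut-off); gene-level amplification/deletion/LOH by ≥ 1 bp locus overlap;
autosomal LOH fraction; chromosomes retaining heterozygosity (LOH coverage
< 20%); and arm-level losses assigned by centromere position.

Rules are evaluated in fixed priority order. All firing *specific* rules are
co-reported (differential indications are normal practice); *broad*
fallbacks apply only when no specific rule fires, first match wins; an
empty profile yields exactly the no-support indication with its sampling
caveats, and an aberrant profile matching nothing is reported as
unclassified rather than forced into a tier. Numeric anchors: "more than
half of the chromosomes" is fixed at ≥ 12 of 22 autosomes; "near-diploidy"
is integer baseline exactly 2; haploidization requires LOH over ≥ 70% of the
autosomal genome (accommodating isodisomy that spares several chromosomes)
with chromosomes 5 **and** 22 among those retaining heterozygosity; MFS/UPS
requires a non-diploid baseline with > 50 structural changes across ≥ 12
autosomes; high-grade osteosarcoma > 30 structural changes in an aneuploid
bone lesion; GIST requires the intraabdominal context plus 1p loss and
14q and/or 22q loss. Anatomical context is always an input, never inferred
from the profile. Every threshold lives in `ClassifierConfig` and can be
overridden from a YAML thresholds file.

The LMS rule (complex structural profile plus *MYOCD* amplification or
*ATRX*/*TP53*/*DMD* deletion) is the one place where published practice is
under-specified; requiring gene-level evidence is this package's
operationalization, and profiles lacking it fall to MFS/UPS or broad tiers.

## Synthetic cohorts

The generator replaces non-deposited patient data with archetypes that
reproduce the qualitative structure the analysis depends on:

- `normal` — no segments;
- `benign_low_complexity` — a recurrent 13q14 deletion anchor plus 0–3
  lesions from a fixed low-complexity pool (1–4 CNAs, diploid baseline);
- `complex_gain` / `complex_loss` — a triploid stem line with 60 structural
  lesions (CN 4–5 gains, or CN 1 losses) across 15 autosomes; the remainder
  of each chromosome is filled with CN-3 carrier segments so the
  length-weighted modal copy number is robustly 3 regardless of how many
  structural lesions survive noise;
- `amplicon_wdls` / `amplicon_ddls` — 12q amplicons (CN 10–14) covering
  *CDK4* and *MDM2*; the DDLS variant adds a *JUN* amplicon and a modest
  structural background;
- `haploid_ilms` — copy-neutral LOH over ~97% of every autosome except
  5, 18, 20, 21 and 22 (genome-wide isodisomy sparing those chromosomes);
- `gist_like` — CN-1 losses over 1p, 14q and 22q, intraabdominal context.

Each archetype draws around a fixed genomic template (deterministic in the
archetype name and a `template_seed`), then applies per-sample endpoint
jitter (truncated normal, sd 100 kb). Shared templates are what make
within-archetype Jaccard similarity high; distinct `template_seed` values
give independent tumors of the same complexity class, which the matched-pair
tests use. Random templates avoid the bundled gene loci (±1 Mb) so that
gene-level rules stay archetype-specific. Probe counts follow CytoScan-HD
density (≈ 1 probe / 1.1 kb, uniform — real arrays vary regionally, which is
irrelevant to downstream arithmetic), so every generated segment passes the
default filter by construction; sub-threshold decoys are available by flag
for filter tests.

Matched pairs derive a CNB and a surgical profile independently from one
base: each **aberrant** segment is kept with probability 1 − dropout,
endpoints are jittered (truncated normal, default sd 10 kb), and
Poisson-distributed private segments are added. Dropout models the failure
to call an aberration against the stem line — normal-cell contamination
washes out focal calls first — so stem-line (neutral) segments are inherited
by both samples; dropping them instead would randomly flip the inferred
ploidy baseline within a pair and make similarity non-monotone in the
contamination level (the real-data analogue is a ploidy-assumption
discrepancy between two samples of one tumor, which is a known failure mode
of visual review, not of contamination).

What the generator does **not** emulate: allele-intensity (BAF/LRR) noise,
regionally varying probe density, subclonal fractions, tumor phylogenies, or
realistic per-entity lesion-length distributions. Passing tests therefore
demonstrate the correctness and stability of the analysis pipeline on
segment calls with the assumed structure, not clinical performance on
patient data.

## Problem sizes and determinism

The test suite uses desk-scale designs chosen as the smallest cohorts that
exercise each claim: 36-sample cohorts (3 × 12) over 20 seeds for cluster
recovery; 10 matched pairs × 20 seeds across a 0–0.9 dropout grid for
adjacency degradation; 100 seeded draws per archetype for label recovery
(≥ 95% required); 100 replicates of n = 20 Poisson burden draws for the
group comparison. Per-base oracle checks run on a 10 kb-per-chromosome toy
genome where brute force is exact and fast. All randomness flows through
`numpy.random.default_rng` seeded per call; the analysis path itself is
fully deterministic, and rerunning the pipeline on identical inputs
reproduces byte-identical non-log outputs.

## Known limitations

- Rule thresholds quantify qualitative diagnostic practice; they are
  configurable but not clinically validated, and no claim of diagnostic
  accuracy on real cohorts is made.
- The ploidy baseline is a single integer; genuinely mosaic or subclonal
  ploidies are out of scope, and a wrong baseline propagates to all state
  calls (mitigated by the diploid tie-break).
- LOH segments are assumed disjoint from CN segments after overlap
  resolution; upstream exports that interleave them heavily will lose
  information in the truncation step.
- The benign/malignant comparison assumes independent samples; matched
  pairs should be reduced to one sample per case before testing.
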