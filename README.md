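# cnaprofiler

Copy-number-profile analysis for SNP-array segment calls from soft tissue
and bone tumors (STBTs). Diagnostic laboratories increasingly run SNP arrays
on preoperative core needle biopsies (CNBs); the copy-number aberration
(CNA) profile of the biopsy can support, sharpen, or contradict the
morphologic diagnosis. `cnaprofiler` turns that workflow into a tested,
reproducible pipeline:

- **Segment filtering** — seg-table I/O (1-based inclusive on disk, 0-based
  half-open in memory), the standard noise filter (autosomal segments
  ≥ 100 kb with ≥ 50 probes), and a deterministic ploidy-baseline estimate.
- **Genomic Jaccard similarity** — for samples *A*, *B* with aberrant
  base-pair sets *S_A*, *S_B*,

  *J(A, B) = |S_A ∩ S_B| / |S_A ∪ S_B|* ∈ [0, 1],

  where a base matches in the intersection only if its aberration state
  matches (gain/loss/copy-neutral LOH); 1 means complete overlap.
- **Hierarchical clustering** on distance 1 − J, with dendrogram cherry
  ("clustered next to each other") queries for matched CNB/surgical pairs
  and flat cuts of the tree.
- **CNA burden statistics** — copy-number shifts and aberrant chromosomes
  per sample, compared between benign and malignant samples with a
  two-sided Wilcoxon rank-sum test (exact null for small untied groups).
- **Rule-based classification** — an ordered, evidence-reporting rule engine
  mapping profile features plus anatomical context to diagnostic
  indications: *MDM2*/*CDK4* 12q amplicons (ALT/WDLS vs DDLS vs parosteal
  osteosarcoma by context and *JUN* status), genome haploidization with
  retained heterozygosity for chromosomes 5 and 22 (inflammatory
  leiomyosarcoma), complex aneuploid profiles (MFS/UPS, high-grade
  osteosarcoma), 1p/14q/22q losses in intraabdominal tumors (GIST), and
  broad fallbacks (high-grade sarcoma NOS, sarcoma NOS, neoplasia NOS).
- **Synthetic cohorts** — a seeded generator of archetype profiles and
  matched CNB/surgical pairs (boundary jitter, segment dropout, private
  segments) standing in for patient segment files, which are not publicly
  deposited.

## Worked example

Two tumors with 10 Mb gains at chr1:10–20 Mb and chr1:15–25 Mb share 5 Mb
of a 15 Mb union (`examples/01_jaccard_similarity.py`):

```
shared aberrant bases : 5,000,000
union of aberrations  : 15,000,000
Jaccard similarity    : 0.3333
```

Classifying one generated profile per archetype
(`examples/05_classify_profiles.py`) closes the generator/classifier loop:

```
amplicon_wdls            -> [specific] ALT/WDLS
                            - 12q amplicon including MDM2
                            - CDK4 co-amplified
                            - no JUN amplification or genome-wide changes
haploid_ilms             -> [specific] ILMS
                            - LOH over 85% of the autosomal genome (haploidization/genome-wide isodisomy)
                            - retained heterozygosity for chromosomes 5, 18, 20, 21, 22
gist_like                -> [specific] GIST
                            - intraabdominal location
                            - deletion of 1p
                            - loss of 14q and 22q
```

An amplicon profile is read as ALT/WDLS in soft tissue but as parosteal
osteosarcoma on a bone surface: context is an input, never inferred.

The other examples cluster a 36-sample cohort into its three generating
archetypes (`02`), track matched-pair adjacency as contamination-style
dropout grows (`03`), and compare CNA burden between benign and malignant
samples (`04`).

## Command line

```
cnaprofiler simulate examples/cohort_design.yaml cohort/ --seed 1
cnaprofiler run cohort/segments.tsv results/ --metadata cohort/metadata.tsv
```

`run` writes the similarity matrix (TSV), dendrogram (Newick), pair
adjacency, quantification and classification reports, and a manifest with
input checksums; reruns on identical inputs reproduce identical outputs.
`filter`, `cluster`, `classify` and `quantify` expose the individual steps.

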