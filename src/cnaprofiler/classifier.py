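"""Rule-based mapping from copy-number profiles to diagnostic indications.

Recurrent genomic patterns in soft tissue and bone tumors allow a
copy-number profile, together with the anatomical context, to indicate a
specific tumor entity (e.g. 12q amplicons containing *MDM2* and *CDK4* in
well/dedifferentiated liposarcoma, genome haploidization with retained
heterozygosity for chromosomes 5 and 22 in inflammatory leiomyosarcoma) or a
broad group (high-grade sarcoma NOS, sarcoma NOS, neoplasia NOS). This
module makes that interpretation explicit and reproducible: profile features
are extracted deterministically and evaluated against an ordered rule set;
every firing specific rule is reported with the facts that triggered it, and
broad fallbacks apply only when no specific rule fires.

The rules operationalize qualitative thresholds; where a numerical cut-off
had to be fixed (amplification = CN at least baseline + 3, "more than half
of the chromosomes" = at least 12 of 22 autosomes, whole-chromosome change =
a single state covering at least 95% of the chromosome), the value lives in
:class:`ClassifierConfig` and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

from . import intervals as iv
from .segio import (
    AUTOSOMES,
    ConfigurationError,
    LocusTable,
    SegmentProfile,
    centromeres,
    estimate_ploidy_baseline,
)
from .quantify import coalesced_segments


@dataclass(frozen=True)
class ClassifierConfig:
    """Numeric thresholds behind the diagnostic rules.

    whole_chrom_fraction: single-state coverage of a chromosome at or above
        which the change counts as numerical (trisomy/monosomy-like) rather
        than structural.
    amplification_offset: CN >= baseline + offset defines an amplicon
        (>= 5 in a diploid context).
    haploid_loh_fraction: minimum fraction of the autosomal genome under LOH
        to call haploidization/genome-wide isodisomy.
    retained_het_loh_max: a chromosome with LOH coverage below this fraction
        counts as retaining heterozygosity.
    half_genome_autosomes: autosome count standing in for "more than half of
        the chromosomes".
    min_arm_loss_bases: minimum lost bases on an arm before the arm counts
        as lost (1 = any filtered loss segment).
    """

    whole_chrom_fraction: float = 0.95
    amplification_offset: int = 3
    haploid_loh_fraction: float = 0.70
    retained_het_loh_max: float = 0.20
    half_genome_autosomes: int = 12
    min_arm_loss_bases: int = 1
    complex_structural_gt: int = 50
    osteosarcoma_structural_gt: int = 30
    hgs_nos_structural_gt: int = 20
    sarcoma_nos_structural_lt: int = 20
    sarcoma_nos_chrom_min: int = 3
    sarcoma_nos_chrom_max: int = 9
    sarcoma_nos_min_total: int = 5
    neoplasia_nos_max_total: int = 4

    def replace(self, **kwargs) -> "ClassifierConfig":
        from dataclasses import replace as _r

        return _r(self, **kwargs)


@dataclass(frozen=True)
class ProfileFeatures:
    """Deterministic descriptors a profile is classified from."""

    sample_id: str
    ploidy_baseline: int
    n_structural: int
    n_numerical: int
    total_cna: int
    n_chrom_structural: int
    n_chrom_aberrant: int
    genome_wide_changes: bool
    amplicons: tuple[tuple[str, tuple[int, int], int], ...]
    genes_amplified: frozenset[str]
    genes_deleted: frozenset[str]
    genes_loh: frozenset[str]
    loh_genome_fraction: float
    retained_het_chroms: frozenset[str]
    arms_lost: frozenset[str]

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("genes_amplified", "genes_deleted", "genes_loh",
                  "retained_het_chroms", "arms_lost"):
            d[k] = sorted(d[k])
        d["amplicons"] = [
            {"chrom": c, "start": s, "end": e, "copy_number": cn}
            for c, (s, e), cn in self.amplicons
        ]
        return d


def extract_features(
    profile: SegmentProfile,
    loci: Optional[LocusTable] = None,
    config: Optional[ClassifierConfig] = None,
) -> ProfileFeatures:
    """Compute classification features from a filtered profile.

    A gene counts as amplified/deleted/LOH as soon as one base of its locus
    lies in a qualifying segment. Counts of structural vs numerical changes
    use coalesced same-state segments, so segmentation granularity does not
    inflate complexity.
    """
    if loci is None:
        raise ConfigurationError("a LocusTable is required for feature extraction")
    cfg = config or ClassifierConfig()
    genome = profile.genome
    baseline = (
        profile.ploidy_baseline
        if profile.ploidy_baseline is not None
        else estimate_ploidy_baseline(profile)
    )

    coalesced = coalesced_segments(profile)
    n_structural = n_numerical = 0
    chrom_structural: set[str] = set()
    chrom_aberrant: set[str] = set()
    loss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, state in coalesced:
        if chrom in AUTOSOMES:
            chrom_aberrant.add(chrom)
        if (end - start) >= cfg.whole_chrom_fraction * genome[chrom]:
            n_numerical += 1
        else:
            n_structural += 1
            if chrom in AUTOSOMES:
                chrom_structural.add(chrom)
        if state == "loss":
            loss_by_chrom.setdefault(chrom, []).append((start, end))

    amp_threshold = baseline + cfg.amplification_offset
    amplicons = tuple(
        (s.chrom, s.interval, s.copy_number)
        for s in profile.segments
        if s.copy_number >= amp_threshold
    )

    genes_amp, genes_del, genes_loh = set(), set(), set()
    loss_raw = [
        (s.chrom, s.interval) for s in profile.segments if s.state(baseline) == "loss"
    ]
    loh_raw = [(s.chrom, s.interval) for s in profile.segments if s.loh]
    for gene, (gchrom, gstart, gend) in loci.items():
        glocus = [(gstart, gend)]
        if any(c == gchrom and iv.intersect([span], glocus) for c, span, _ in amplicons):
            genes_amp.add(gene)
        if any(c == gchrom and iv.intersect([span], glocus) for c, span in loss_raw):
            genes_del.add(gene)
        if any(c == gchrom and iv.intersect([span], glocus) for c, span in loh_raw):
            genes_loh.add(gene)

    loh_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in profile.segments:
        if s.loh and s.chrom in AUTOSOMES:
            loh_by_chrom.setdefault(s.chrom, []).append(s.interval)
    loh_bases = sum(
        iv.total_length(iv.merge(ivs)) for ivs in loh_by_chrom.values()
    )
    loh_fraction = loh_bases / genome.autosomal_length
    retained_het = frozenset(
        c for c in AUTOSOMES
        if iv.total_length(iv.merge(loh_by_chrom.get(c, []) or []))
        < cfg.retained_het_loh_max * genome[c]
        or not loh_by_chrom.get(c)
    )

    cen = centromeres(genome.assembly)
    arms_lost: set[str] = set()
    for chrom, losses in loss_by_chrom.items():
        if chrom not in AUTOSOMES:
            continue
        cs, ce = cen[chrom]
        merged = iv.merge(losses)
        if iv.coverage_within(merged, 0, cs) >= cfg.min_arm_loss_bases:
            arms_lost.add(f"{chrom}p")
        if iv.coverage_within(merged, ce, genome[chrom]) >= cfg.min_arm_loss_bases:
            arms_lost.add(f"{chrom}q")

    return ProfileFeatures(
        sample_id=profile.sample_id,
        ploidy_baseline=baseline,
        n_structural=n_structural,
        n_numerical=n_numerical,
        total_cna=n_structural + n_numerical,
        n_chrom_structural=len(chrom_structural),
        n_chrom_aberrant=len(chrom_aberrant),
        genome_wide_changes=len(chrom_aberrant) >= cfg.half_genome_autosomes,
        amplicons=amplicons,
        genes_amplified=frozenset(genes_amp),
        genes_deleted=frozenset(genes_del),
        genes_loh=frozenset(genes_loh),
        loh_genome_fraction=loh_fraction,
        retained_het_chroms=retained_het,
        arms_lost=frozenset(arms_lost),
    )


@dataclass(frozen=True)
class Indication:
    label: str
    tier: str  # specific | broad | none
    evidence: tuple[str, ...]


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    indications: tuple[Indication, ...]
    profile_normal: bool

    @property
    def top(self) -> Indication:
        return self.indications[0]


NO_SUPPORT_LABEL = "no support for a neoplastic lesion"
UNCLASSIFIED_LABEL = "aberrant profile, unclassified"


def classify(
    features: ProfileFeatures,
    context: str = "unknown",
    profile_empty: bool = False,
    config: Optional[ClassifierConfig] = None,
) -> ClassificationResult:
    """Evaluate the diagnostic rules on extracted features.

    Specific rules are evaluated in a fixed priority order and all firing
    rules are reported (differential indications are expected); broad tiers
    apply only when no specific rule fires, and only the highest-priority
    broad rule is reported. An empty profile yields the single no-support
    indication with its sampling caveats.
    """
    cfg = config or ClassifierConfig()
    f = features
    if profile_empty:
        return ClassificationResult(
            sample_id=f.sample_id,
            indications=(
                Indication(
                    label=NO_SUPPORT_LABEL,
                    tier="none",
                    evidence=(
                        "no CNAs after filtering",
                        "caveat: sample might be nonrepresentative",
                        "caveat: lesion might be a neoplasm without CNAs",
                    ),
                ),
            ),
            profile_normal=True,
        )

    specific: list[Indication] = []

    # R1 inflammatory leiomyosarcoma: genome haploidization sparing chr5/22
    if (
        f.loh_genome_fraction >= cfg.haploid_loh_fraction
        and {"5", "22"} <= set(f.retained_het_chroms)
    ):
        specific.append(Indication(
            "ILMS", "specific",
            (
                f"LOH over {f.loh_genome_fraction:.0%} of the autosomal genome "
                "(haploidization/genome-wide isodisomy)",
                "retained heterozygosity for chromosomes "
                + ", ".join(sorted(f.retained_het_chroms, key=int)),
            ),
        ))

    # R2/R3 12q amplicon logic (mutually exclusive by construction)
    mdm2_cdk4 = {"MDM2", "CDK4"} <= set(f.genes_amplified)
    ddls = mdm2_cdk4 and ("JUN" in f.genes_amplified or f.genome_wide_changes)
    if ddls:
        ev = ["12q amplicon including MDM2 and CDK4"]
        if "JUN" in f.genes_amplified:
            ev.append("JUN amplification in 1p")
        if f.genome_wide_changes:
            ev.append(
                f"genome-wide copy number changes ({f.n_chrom_aberrant} autosomes affected)"
            )
        specific.append(Indication("DDLS", "specific", tuple(ev)))
    elif "MDM2" in f.genes_amplified:
        if context == "bone_surface":
            label = "parosteal osteosarcoma"
        elif context == "bone":
            label = "ALT or parosteal osteosarcoma"
        else:
            label = "ALT/WDLS"
        ev = ["12q amplicon including MDM2"]
        if "CDK4" in f.genes_amplified:
            ev.append("CDK4 co-amplified")
        ev.append("no JUN amplification or genome-wide changes")
        specific.append(Indication(label, "specific", tuple(ev)))

    # R4 MFS/UPS: non-diploid stem line with highly complex structural profile
    if (
        f.ploidy_baseline != 2
        and f.n_structural > cfg.complex_structural_gt
        and f.n_chrom_structural >= cfg.half_genome_autosomes
    ):
        specific.append(Indication(
            "MFS/UPS", "specific",
            (
                f"non-diploid stem line (baseline CN {f.ploidy_baseline})",
                f"{f.n_structural} structural rearrangements",
                f"structural changes on {f.n_chrom_structural} of 22 autosomes",
            ),
        ))

    # R5 high-grade osteosarcoma: extremely complex profile in a bone lesion
    if (
        context in ("bone", "bone_surface")
        and f.ploidy_baseline != 2
        and f.n_structural > cfg.osteosarcoma_structural_gt
    ):
        specific.append(Indication(
            "high-grade osteosarcoma", "specific",
            (
                f"bone lesion with aneuploidy (baseline CN {f.ploidy_baseline})",
                f"{f.n_structural} structural rearrangements",
            ),
        ))

    # R6 conventional LMS: complex structural profile plus gene-level evidence
    lms_genes = {"ATRX", "TP53", "DMD"} & set(f.genes_deleted)
    if f.n_chrom_structural >= cfg.half_genome_autosomes and (
        "MYOCD" in f.genes_amplified or lms_genes
    ):
        ev = [f"structural changes on {f.n_chrom_structural} of 22 autosomes"]
        if "MYOCD" in f.genes_amplified:
            ev.append("MYOCD amplification")
        if lms_genes:
            ev.append("deletion of " + ", ".join(sorted(lms_genes)))
        specific.append(Indication("LMS", "specific", tuple(ev)))

    # R7 GIST: intraabdominal tumor with 1p loss plus 14q and/or 22q loss
    if context == "intraabdominal" and "1p" in f.arms_lost and (
        {"14q", "22q"} & set(f.arms_lost)
    ):
        specific.append(Indication(
            "GIST", "specific",
            ("intraabdominal location",
             "deletion of 1p",
             "loss of " + " and ".join(sorted({"14q", "22q"} & set(f.arms_lost)))),
        ))

    # R8 chondrosarcoma: aneuploid bone lesion with mostly numerical changes
    if (
        context == "bone"
        and f.ploidy_baseline != 2
        and f.n_numerical > f.n_structural
    ):
        specific.append(Indication(
            "chondrosarcoma", "specific",
            (
                f"bone lesion with aneuploidy (baseline CN {f.ploidy_baseline})",
                f"mostly numerical changes ({f.n_numerical} numerical vs "
                f"{f.n_structural} structural)",
            ),
        ))

    if specific:
        return ClassificationResult(
            sample_id=f.sample_id, indications=tuple(specific), profile_normal=False
        )

    # broad fallbacks, first match wins
    broad: Optional[Indication] = None
    if (
        f.ploidy_baseline == 2
        and 1 <= f.n_chrom_structural <= cfg.half_genome_autosomes - 1
        and (f.n_structural > cfg.hgs_nos_structural_gt or f.amplicons)
    ):
        ev = [
            "near-diploid baseline",
            f"structural changes on {f.n_chrom_structural} of 22 autosomes "
            "(less than half)",
        ]
        if f.n_structural > cfg.hgs_nos_structural_gt:
            ev.append(f"{f.n_structural} structural rearrangements")
        if f.amplicons:
            ev.append(f"{len(f.amplicons)} amplicon(s) present")
        broad = Indication("high-grade sarcoma NOS", "broad", tuple(ev))
    elif (
        f.n_structural < cfg.sarcoma_nos_structural_lt
        and cfg.sarcoma_nos_chrom_min <= f.n_chrom_aberrant <= cfg.sarcoma_nos_chrom_max
        and f.total_cna >= cfg.sarcoma_nos_min_total
    ):
        broad = Indication(
            "sarcoma NOS", "broad",
            (
                f"{f.n_structural} structural copy number changes",
                f"aberrations on {f.n_chrom_aberrant} chromosomes",
            ),
        )
    elif f.ploidy_baseline == 2 and 1 <= f.total_cna <= cfg.neoplasia_nos_max_total:
        broad = Indication(
            "neoplasia NOS", "broad",
            (
                f"{f.total_cna} CNA(s) in a near-diploid context",
                "clonal CNA supports a neoplastic rather than reactive lesion",
            ),
        )
    if broad is not None:
        return ClassificationResult(
            sample_id=f.sample_id, indications=(broad,), profile_normal=False
        )
    return ClassificationResult(
        sample_id=f.sample_id,
        indications=(
            Indication(UNCLASSIFIED_LABEL, "none",
                       ("aberrant profile matching no rule",)),
        ),
        profile_normal=False,
    )


def classify_profile(
    profile: SegmentProfile,
    loci: Optional[LocusTable] = None,
    config: Optional[ClassifierConfig] = None,
    context: Optional[str] = None,
) -> ClassificationResult:
    """Extract features from a filtered profile and classify them."""
    loci = loci if loci is not None else LocusTable.hg19()
    features = extract_features(profile, loci=loci, config=config)
    return classify(
        features,
        context=context if context is not None else profile.context,
        profile_empty=profile.is_empty,
        config=config,
    )
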