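"""Seeded synthetic segment profiles and matched biopsy/resection pairs.

Diagnostic SNP-array segment files from patient cohorts are rarely
deposited, so this module generates cohorts with the qualitative structure
such data shows: near-diploid low-complexity profiles, complex aneuploid
gain- or loss-dominated profiles, 12q-amplicon profiles with or without
*JUN* co-amplification, genome-haploidized profiles sparing chromosomes 5
and 22, and GIST-like 1p/14q/22q loss profiles. Matched core-needle-biopsy
(CNB) and surgical pairs are derived from a common base profile with
boundary jitter, segment dropout (a proxy for normal-cell contamination,
since the pipeline consumes discrete segment calls rather than intensities)
and private segments.

Each archetype is built around a fixed genomic template (deterministic in
the archetype name and ``template_seed``) plus per-sample jitter, so samples
of one archetype are mutually similar while different archetypes occupy
disjoint territory or opposite states. Probe counts follow CytoScan-HD-like
density (about one probe per 1.1 kb), so generated segments pass the default
100 kb / 50 probe filter by construction unless sub-threshold decoys are
requested explicitly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .segio import (
    AUTOSOMES,
    ChromosomeTable,
    GenomicSegment,
    LocusTable,
    SegmentProfile,
)

PROBE_SPACING = 1100  # bases per probe, CytoScan-HD-like

ARCHETYPES = (
    "normal",
    "benign_low_complexity",
    "complex_gain",
    "complex_loss",
    "amplicon_wdls",
    "amplicon_ddls",
    "haploid_ilms",
    "gist_like",
)

#: intended top diagnostic indication per archetype (closes the
#: generator/classifier loop in tests)
INTENDED_LABEL = {
    "normal": "no support for a neoplastic lesion",
    "benign_low_complexity": "neoplasia NOS",
    "complex_gain": "MFS/UPS",
    "complex_loss": "MFS/UPS",
    "amplicon_wdls": "ALT/WDLS",
    "amplicon_ddls": "DDLS",
    "haploid_ilms": "ILMS",
    "gist_like": "GIST",
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one profile archetype.

    ``template_seed`` fixes the archetype's genomic template; two specs with
    the same name and template_seed share recurrent lesions, which is what
    makes within-archetype Jaccard similarity high. ``jitter_sd`` is the
    per-sample truncated-normal endpoint noise. ``sample_dropout`` thins the
    template per sample. ``decoy_count`` adds sub-threshold segments
    (<100 kb or <50 probes) for filter tests.
    """

    name: str
    context: str = "soft_tissue"
    template_seed: int = 0
    n_segments: int = 60              # structural segments for complex types
    length_bounds: tuple[int, int] = (2_000_000, 8_000_000)  # log-uniform
    jitter_sd: int = 100_000
    sample_dropout: float = 0.0
    decoy_count: int = 0

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.name!r}")


def default_spec(name: str, template_seed: int = 0) -> ArchetypeSpec:
    """Archetype spec with the study-condition defaults."""
    ctx = "intraabdominal" if name == "gist_like" else (
        "unknown" if name == "normal" else "soft_tissue"
    )
    return ArchetypeSpec(name=name, context=ctx, template_seed=template_seed)


@dataclass(frozen=True)
class PairNoiseSpec:
    """Noise separating a CNB from its matched surgical sample.

    dropout_rate: probability a base segment is absent from one counterpart
        (normal-cell contamination proxy). private_rate: expected count of
        extra segments unique to one sample. boundary_jitter_sd: segment
        endpoint jitter in bases, truncated so no segment inverts.
    """

    boundary_jitter_sd: int = 10_000
    dropout_rate: float = 0.0
    private_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if not 0.0 <= self.private_rate <= 1.0:
            raise ValueError("private_rate must be in [0, 1]")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

# (chrom, start, end, copy_number, loh): the recurrent low-complexity lesions
# the benign archetype draws from; the 13q14 deletion anchor is always present
_BENIGN_ANCHOR = ("13", 46_000_000, 51_000_000, 1, False)
_BENIGN_POOL = (
    ("3", 60_000_000, 68_000_000, 3, False),
    ("6", 75_000_000, 85_000_000, 1, False),
    ("5", 90_000_000, 97_000_000, 3, False),
    ("10", 88_000_000, 95_000_000, 1, False),
    ("4", 100_000_000, 107_000_000, 3, False),
    ("2", 150_000_000, 158_000_000, 1, False),
)

_COMPLEX_STRUCT_CHROMS = tuple(str(i) for i in range(8, 23))   # 15 autosomes
_COMPLEX_CARRIER_CHROMS = tuple(str(i) for i in range(1, 8))   # baseline carriers
_ILMS_SPARED = ("5", "18", "20", "21", "22")

Template = list[tuple[str, int, int, int, bool]]


def _name_hash(name: str) -> int:
    return zlib.crc32(name.encode())


def _forbidden_intervals(loci: LocusTable, margin: int = 1_000_000):
    """Gene loci (plus the benign anchor pool) widened by a margin; random
    complex templates avoid these so gene-level rules stay archetype-specific."""
    forb: dict[str, list[tuple[int, int]]] = {}
    for _, (chrom, s, e) in loci.items():
        forb.setdefault(chrom, []).append((max(0, s - margin), e + margin))
    for chrom, s, e, _, _ in (_BENIGN_ANCHOR,) + _BENIGN_POOL:
        forb.setdefault(chrom, []).append((max(0, s - margin), e + margin))
    return {c: iv.merge(v) for c, v in forb.items()}


def _place_segments(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    n: int,
    length_bounds: tuple[int, int],
    forbidden: list[tuple[int, int]],
    gap: int = 3_000_000,
) -> list[tuple[int, int]]:
    """Place n disjoint intervals on one chromosome, away from forbidden
    regions and separated by at least ``gap`` bases."""
    placed: list[tuple[int, int]] = []
    lo, hi = length_bounds
    attempts = 0
    while len(placed) < n and attempts < 1000:
        attempts += 1
        length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        start = int(rng.integers(1_000_000, max(1_000_001, chrom_len - length - 1_000_000)))
        cand = (start, start + length)
        widened = (max(0, start - gap), start + length + gap)
        if iv.intersect([widened], forbidden):
            continue
        if any(iv.intersect([widened], [p]) for p in placed):
            continue
        placed.append(cand)
    if len(placed) < n:
        raise RuntimeError(f"could not place {n} segments on chromosome {chrom}")
    return sorted(placed)


def _complex_template(
    spec: ArchetypeSpec, genome: ChromosomeTable, loci: LocusTable
) -> Template:
    rng = np.random.default_rng([spec.template_seed, _name_hash(spec.name)])
    forb = _forbidden_intervals(loci)
    per_chrom = spec.n_segments // len(_COMPLEX_STRUCT_CHROMS)
    extra = spec.n_segments - per_chrom * len(_COMPLEX_STRUCT_CHROMS)
    template: Template = []
    for i, chrom in enumerate(_COMPLEX_STRUCT_CHROMS):
        n = per_chrom + (1 if i < extra else 0)
        spans = _place_segments(
            rng, chrom, genome[chrom], n, spec.length_bounds, forb.get(chrom, [])
        )
        for s, e in spans:
            if spec.name == "complex_gain":
                cn = int(rng.choice([4, 5]))
            else:
                cn = 1
            template.append((chrom, s, e, cn, False))
        # CN-3 carrier segments fill the rest of the chromosome: the triploid
        # stem line is triploid everywhere, structural lesions deviate from it.
        # Carriers are neutral at baseline 3 and vanish at filter time.
        for cs, ce in iv.subtract([(0, genome[chrom])], iv.merge(spans)):
            if ce - cs >= 200_000:
                template.append((chrom, cs, ce, 3, False))
    for chrom in _COMPLEX_CARRIER_CHROMS:
        template.append((chrom, 1_000_000, genome[chrom] - 1_000_000, 3, False))
    return template


def _benign_template(spec: ArchetypeSpec, rng: np.random.Generator) -> Template:
    k = int(rng.integers(0, 4))  # 0..3 extras -> 1..4 CNAs in total
    idx = rng.choice(len(_BENIGN_POOL), size=k, replace=False)
    return [_BENIGN_ANCHOR] + [_BENIGN_POOL[i] for i in sorted(idx)]


def _amplicon_template(spec: ArchetypeSpec, genome: ChromosomeTable) -> Template:
    template: Template = [
        ("12", 57_800_000, 59_000_000, 10, False),   # CDK4 amplicon
        ("12", 68_500_000, 70_500_000, 14, False),   # MDM2 amplicon
        ("12", 64_000_000, 66_000_000, 3, False),    # co-gained 12q material
    ]
    if spec.name == "amplicon_ddls":
        template.append(("1", 59_000_000, 59_500_000, 8, False))  # JUN amplicon
        # a modest structural background, well short of genome-wide change
        template += [
            ("6", 50_000_000, 58_000_000, 1, False),
            ("11", 80_000_000, 88_000_000, 3, False),
            ("20", 30_000_000, 36_000_000, 1, False),
        ]
    return template


def _ilms_template(genome: ChromosomeTable) -> Template:
    template: Template = []
    for chrom in AUTOSOMES:
        if chrom in _ILMS_SPARED:
            continue
        template.append((chrom, 500_000, genome[chrom] - 500_000, 2, True))
    return template


def _gist_template() -> Template:
    return [
        ("1", 3_000_000, 28_000_000, 1, False),     # 1p deletion
        ("14", 20_000_000, 106_000_000, 1, False),  # 14q loss
        ("22", 17_000_000, 50_000_000, 1, False),   # 22q loss
    ]


def _build_template(
    spec: ArchetypeSpec,
    genome: ChromosomeTable,
    loci: LocusTable,
    sample_rng: np.random.Generator,
) -> Template:
    if spec.name == "normal":
        return []
    if spec.name == "benign_low_complexity":
        return _benign_template(spec, sample_rng)  # per-sample lesion subset
    if spec.name in ("complex_gain", "complex_loss"):
        return _complex_template(spec, genome, loci)
    if spec.name in ("amplicon_wdls", "amplicon_ddls"):
        return _amplicon_template(spec, genome)
    if spec.name == "haploid_ilms":
        return _ilms_template(genome)
    if spec.name == "gist_like":
        return _gist_template()
    raise AssertionError(spec.name)


# ---------------------------------------------------------------------------
# profile generation
# ---------------------------------------------------------------------------

def _probes_for(length: int, rng: np.random.Generator) -> int:
    return max(1, int(round(length / PROBE_SPACING * rng.uniform(0.9, 1.1))))


def _jitter_segments(
    rows: Template,
    genome: ChromosomeTable,
    rng: np.random.Generator,
    sd: int,
) -> list[GenomicSegment]:
    """Apply truncated-normal endpoint jitter, keep segments valid and
    non-overlapping, and draw probe counts at CytoScan-like density."""
    by_chrom: dict[str, Template] = {}
    for row in rows:
        by_chrom.setdefault(row[0], []).append(row)
    segs: list[GenomicSegment] = []
    for chrom in sorted(by_chrom, key=lambda c: (c not in AUTOSOMES, c.zfill(2))):
        prev_end = 0
        for chrom_, s, e, cn, loh in sorted(by_chrom[chrom], key=lambda r: r[1]):
            if sd > 0:
                s = s + int(np.clip(rng.normal(0, sd), -3 * sd, 3 * sd))
                e = e + int(np.clip(rng.normal(0, sd), -3 * sd, 3 * sd))
            s = max(prev_end, max(0, s))
            e = min(genome[chrom], e)
            if e - s < 1:
                continue
            prev_end = e
            segs.append(GenomicSegment(chrom, s, e, _probes_for(e - s, rng), cn, loh))
    return segs


def generate_profile(
    spec: ArchetypeSpec,
    genome: Optional[ChromosomeTable] = None,
    seed: int = 0,
    loci: Optional[LocusTable] = None,
    sample_id: Optional[str] = None,
) -> SegmentProfile:
    """Draw one profile of the given archetype, reproducibly in ``seed``."""
    genome = genome or ChromosomeTable.hg19()
    loci = loci or LocusTable.hg19()
    rng = np.random.default_rng([int(seed), spec.template_seed, _name_hash(spec.name)])
    template = _build_template(spec, genome, loci, rng)
    if spec.sample_dropout > 0 and template:
        keep = rng.random(len(template)) >= spec.sample_dropout
        kept = [row for row, k in zip(template, keep) if k]
        template = kept if kept else [template[int(rng.integers(len(template)))]]
    segs = _jitter_segments(template, genome, rng, spec.jitter_sd)
    for _ in range(spec.decoy_count):
        chrom = str(rng.choice(AUTOSOMES))
        length = int(rng.integers(10_000, 99_000))
        start = int(rng.integers(0, genome[chrom] - length))
        segs.append(
            GenomicSegment(chrom, start, start + length,
                           max(1, length // PROBE_SPACING), 3, False)
        )
    return SegmentProfile(
        sample_id=sample_id or f"{spec.name}_s{seed}",
        genome=genome,
        segments=tuple(segs),
        context=spec.context,
    )


def apply_noise(
    base: SegmentProfile, noise: PairNoiseSpec, rng: np.random.Generator
) -> tuple[GenomicSegment, ...]:
    """Dropout, jitter and private segments applied to one derived sample.

    Dropout models the failure to call an aberration against the stem line
    (normal-cell contamination washes out focal calls first), so it applies
    only to aberrant segments; segments that are neutral at the base
    profile's ploidy baseline — the stem line itself — are inherited by both
    samples of a pair.
    """
    from .segio import estimate_ploidy_baseline

    genome = base.genome
    baseline = (
        base.ploidy_baseline
        if base.ploidy_baseline is not None
        else estimate_ploidy_baseline(base)
    )
    rows: list[tuple[str, int, int, int, bool, int]] = []
    for s in base.segments:
        if (
            noise.dropout_rate > 0
            and s.state(baseline) != "neutral"
            and rng.random() < noise.dropout_rate
        ):
            continue
        rows.append((s.chrom, s.start, s.end, s.copy_number, s.loh, s.n_probes))
    n_private = int(rng.poisson(noise.private_rate))
    for _ in range(n_private):
        chrom = str(rng.choice(AUTOSOMES))
        length = int(np.exp(rng.uniform(np.log(1_000_000), np.log(10_000_000))))
        start = int(rng.integers(1_000_000, max(1_000_001, genome[chrom] - length)))
        occupied = [(r[1], r[2]) for r in rows if r[0] == chrom]
        if iv.intersect(iv.merge(occupied) if occupied else [], [(start, start + length)]):
            continue
        cn = baseline + 1 if rng.random() < 0.5 else max(0, baseline - 1)
        rows.append((chrom, start, start + length, cn, False,
                     _probes_for(length, rng)))
    # jitter endpoints, keep segments valid and disjoint, rescale probe
    # support with segment length so a zero-noise pair reproduces the base
    sd = noise.boundary_jitter_sd
    by_chrom: dict[str, list[tuple[str, int, int, int, bool, int]]] = {}
    for row in rows:
        by_chrom.setdefault(row[0], []).append(row)
    segs: list[GenomicSegment] = []
    for chrom in sorted(by_chrom, key=lambda c: (c not in AUTOSOMES, c.zfill(2))):
        prev_end = 0
        for chrom_, s, e, cn, loh, probes in sorted(by_chrom[chrom], key=lambda r: r[1]):
            orig_len = e - s
            if sd > 0:
                s = s + int(np.clip(rng.normal(0, sd), -3 * sd, 3 * sd))
                e = e + int(np.clip(rng.normal(0, sd), -3 * sd, 3 * sd))
            s = max(prev_end, max(0, s))
            e = min(genome[chrom], e)
            if e - s < 1:
                continue
            prev_end = e
            probes = max(1, int(round(probes * (e - s) / orig_len)))
            segs.append(GenomicSegment(chrom, s, e, probes, cn, loh))
    return tuple(segs)


def generate_matched_pair(
    base: SegmentProfile,
    noise: PairNoiseSpec,
    seed: int = 0,
    pair_id: Optional[str] = None,
) -> tuple[SegmentProfile, SegmentProfile]:
    """Derive a (CNB, surgical) pair independently from one base profile."""
    pair_id = pair_id or f"{base.sample_id}_pair"
    rng_cnb, rng_sur = np.random.default_rng([int(seed), 0xC9B]).spawn(2)
    out = []
    for role, rng in (("CNB", rng_cnb), ("surgical", rng_sur)):
        segs = apply_noise(base, noise, rng)
        out.append(
            SegmentProfile(
                sample_id=f"{base.sample_id}_{role}",
                genome=base.genome,
                segments=segs,
                specimen_type=role,
                pair_id=pair_id,
                context=base.context,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortEntry:
    spec: ArchetypeSpec
    count: int
    noise: Optional[PairNoiseSpec] = None  # when set, emit matched pairs

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class Cohort:
    profiles: list[SegmentProfile]
    truth: pd.DataFrame  # sample, archetype, pair_id, context

    @property
    def metadata(self) -> pd.DataFrame:
        rows = [
            (p.sample_id, p.specimen_type or "", p.pair_id or "",
             p.context, "")
            for p in self.profiles
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "specimen_type", "pair_id", "context", "diagnosis_label"],
        )


def generate_cohort(
    design: Sequence[CohortEntry],
    genome: Optional[ChromosomeTable] = None,
    seed: int = 0,
    loci: Optional[LocusTable] = None,
) -> Cohort:
    """Generate a cohort per the design, with a truth table for recovery tests."""
    genome = genome or ChromosomeTable.hg19()
    loci = loci or LocusTable.hg19()
    rng = np.random.default_rng([int(seed), 0xC0407])
    profiles: list[SegmentProfile] = []
    truth_rows = []
    for ei, entry in enumerate(design):
        for j in range(entry.count):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sid = f"{entry.spec.name}_{ei}_{j}"
            base = generate_profile(
                entry.spec, genome, seed=sub_seed, loci=loci, sample_id=sid
            )
            if entry.noise is None:
                profiles.append(base)
                truth_rows.append((sid, entry.spec.name, "", entry.spec.context))
            else:
                pid = f"pair_{ei}_{j}"
                cnb, sur = generate_matched_pair(
                    base, entry.noise, seed=sub_seed, pair_id=pid
                )
                profiles.extend([cnb, sur])
                truth_rows.append((cnb.sample_id, entry.spec.name, pid, entry.spec.context))
                truth_rows.append((sur.sample_id, entry.spec.name, pid, entry.spec.context))
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "archetype", "pair_id", "context"]
    )
    return Cohort(profiles=profiles, truth=truth)
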