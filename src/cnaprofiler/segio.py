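"""Segment-call data model, SEG-table I/O and segment-level filtering.

The unit of analysis is a per-sample table of copy-number segment calls such
as those exported after TAPS/Rawcopy segmentation of CytoScan HD SNP arrays:
one row per contiguous genomic segment with an absolute copy number and an
allelic-imbalance (LOH) flag. Internally coordinates are 0-based half-open;
the on-disk ``seg_tsv`` dialect is 1-based inclusive (ChAS/Rawcopy
convention) and converted on read/write.

Filtering follows standard practice for diagnostic SNP-array review: only
autosomal segments of at least 100 kb supported by at least 50 probes are
kept, which suppresses constitutional CNVs and technical noise, and neutral
non-LOH segments are dropped because only aberrations enter the similarity,
burden and classification statistics downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from . import intervals as iv

logger = logging.getLogger(__name__)

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
ALL_CHROMS: tuple[str, ...] = AUTOSOMES + ("X", "Y")

SPECIMEN_TYPES = ("CNB", "surgical")
CONTEXTS = ("soft_tissue", "bone", "bone_surface", "intraabdominal", "unknown")
DIAGNOSIS_CLASSES = ("benign", "malignant", "ump", "nonneoplastic", "unknown")

SEG_COLUMNS = ("sample", "chrom", "start", "end", "n_probes", "copy_number", "loh")
META_COLUMNS = ("sample", "specimen_type", "pair_id", "context", "diagnosis_label")


class SegmentTableFormatError(ValueError):
    """Raised when an input table violates the seg_tsv dialect."""


class ConfigurationError(ValueError):
    """Raised on incompatible genomes, unknown identifiers etc."""


def normalize_chrom(label: str) -> str:
    """Normalize chromosome labels: 'chr1' -> '1', 'chrX'/'x' -> 'X'."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if c.lower() in ("x", "y") else c
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    if c not in ALL_CHROMS:
        raise SegmentTableFormatError(f"unknown chromosome label {label!r}")
    return c


@dataclass(frozen=True)
class GenomicSegment:
    """One contiguous segment call (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    n_probes: int
    copy_number: int
    loh: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def state(self, baseline: int) -> str:
        """Aberration state relative to a ploidy baseline.

        gain if CN > baseline, loss if CN < baseline, cnloh for copy-neutral
        LOH, neutral otherwise.
        """
        if self.copy_number > baseline:
            return "gain"
        if self.copy_number < baseline:
            return "loss"
        return "cnloh" if self.loh else "neutral"


@dataclass(frozen=True)
class ChromosomeTable:
    """Chromosome label -> length mapping for one reference assembly."""

    lengths: Mapping[str, int]
    assembly: str = "hg19"

    def __post_init__(self) -> None:
        missing = set(ALL_CHROMS) - set(self.lengths)
        if missing:
            raise ValueError(f"chromosome table missing {sorted(missing)}")
        if any(v <= 0 for v in self.lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def autosomal_length(self) -> int:
        return sum(self.lengths[c] for c in AUTOSOMES)

    @classmethod
    def hg19(cls) -> "ChromosomeTable":
        df = _read_bundled("hg19_chromosomes.tsv")
        return cls(lengths=dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


@dataclass(frozen=True)
class LocusTable:
    """Gene symbol -> (chrom, start, end) intervals, 0-based half-open."""

    loci: Mapping[str, tuple[str, int, int]]
    assembly: str = "hg19"

    def __getitem__(self, gene: str) -> tuple[str, int, int]:
        return self.loci[gene]

    def __iter__(self):
        return iter(self.loci)

    def items(self):
        return self.loci.items()

    def validate(self, genome: ChromosomeTable) -> None:
        for gene, (chrom, start, end) in self.loci.items():
            if chrom not in genome.lengths or not 0 <= start < end <= genome[chrom]:
                raise ValueError(f"locus {gene} outside genome bounds")

    @classmethod
    def hg19(cls) -> "LocusTable":
        df = _read_bundled("hg19_loci.tsv")
        loci = {
            str(r.gene): (str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()
        }
        return cls(loci=loci)


def centromeres(assembly: str = "hg19") -> dict[str, tuple[int, int]]:
    """Centromere (acen) spans per chromosome, used for arm assignment."""
    if assembly != "hg19":
        raise ConfigurationError(f"no centromere table bundled for {assembly}")
    df = _read_bundled("hg19_centromeres.tsv")
    return {
        str(r.chrom): (int(r.cen_start), int(r.cen_end)) for r in df.itertuples()
    }


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("cnaprofiler.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass(frozen=True)
class SegmentProfile:
    """One sample's segment calls plus specimen metadata and ploidy baseline.

    Segments are stored sorted by (chrom, start) and are non-overlapping
    within a chromosome; overlapping input is resolved on construction by
    keeping the segment with more probe support and truncating the other.
    ``ploidy_baseline`` is attached by :func:`filter_segments` (None before).
    """

    sample_id: str
    genome: ChromosomeTable
    segments: tuple[GenomicSegment, ...] = ()
    specimen_type: Optional[str] = None
    pair_id: Optional[str] = None
    context: str = "unknown"
    diagnosis_label: Optional[str] = None
    ploidy_baseline: Optional[int] = None

    def __post_init__(self) -> None:
        if self.specimen_type is not None and self.specimen_type not in SPECIMEN_TYPES:
            raise ValueError(f"unknown specimen_type {self.specimen_type!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        segs = _resolve_overlaps(self.sample_id, self.segments)
        for s in segs:
            if s.end > self.genome[s.chrom]:
                raise ValueError(
                    f"{self.sample_id}: segment {s.chrom}:{s.start}-{s.end} exceeds "
                    f"chromosome length {self.genome[s.chrom]}"
                )
        object.__setattr__(self, "segments", segs)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def is_empty(self) -> bool:
        return len(self.segments) == 0

    def with_metadata(
        self,
        specimen_type: Optional[str] = None,
        pair_id: Optional[str] = None,
        context: Optional[str] = None,
        diagnosis_label: Optional[str] = None,
    ) -> "SegmentProfile":
        return replace(
            self,
            specimen_type=specimen_type if specimen_type is not None else self.specimen_type,
            pair_id=pair_id if pair_id is not None else self.pair_id,
            context=context if context is not None else self.context,
            diagnosis_label=diagnosis_label if diagnosis_label is not None else self.diagnosis_label,
        )


def _sort_key(s: GenomicSegment) -> tuple[int, int]:
    return (ALL_CHROMS.index(s.chrom), s.start)


def _resolve_overlaps(
    sample_id: str, segments: Iterable[GenomicSegment]
) -> tuple[GenomicSegment, ...]:
    """Sort segments; on overlap keep the better-supported one, truncate the other."""
    segs = sorted(segments, key=_sort_key)
    out: list[GenomicSegment] = []
    for s in segs:
        if out and out[-1].chrom == s.chrom and s.start < out[-1].end:
            prev = out[-1]
            logger.warning(
                "%s: overlapping segments %s:%d-%d and %s:%d-%d; truncating the "
                "one with fewer probes",
                sample_id, prev.chrom, prev.start, prev.end, s.chrom, s.start, s.end,
            )
            if s.n_probes > prev.n_probes:
                # truncate prev to end at s.start, or drop it if swallowed
                if prev.start < s.start:
                    out[-1] = replace(prev, end=s.start)
                else:
                    out.pop()
                out.append(s)
            else:
                if s.end > prev.end:
                    out.append(replace(s, start=prev.end))
                # else s entirely inside prev: drop s
        else:
            out.append(s)
    return tuple(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_segment_table(
    path: str | Path,
    genome: Optional[ChromosomeTable] = None,
    dialect: str = "seg_tsv",
) -> list[SegmentProfile]:
    """Read a seg_tsv segment table into one SegmentProfile per sample.

    The dialect is tab-separated with header columns
    ``sample chrom start end n_probes copy_number loh`` and 1-based inclusive
    coordinates; rows are converted to internal 0-based half-open. Profiles
    are returned in order of first appearance of each sample id.
    """
    if dialect != "seg_tsv":
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    genome = genome or ChromosomeTable.hg19()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentTableFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    by_sample: dict[str, list[GenomicSegment]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            start1 = int(row.start)
            end1 = int(row.end)
            n_probes = int(row.n_probes)
            cn = int(row.copy_number)
            loh = _parse_loh(row.loh)
        except (TypeError, ValueError) as exc:
            raise SegmentTableFormatError(f"{path}, line {idx}: {exc}") from exc
        try:
            chrom = normalize_chrom(row.chrom)
        except SegmentTableFormatError as exc:
            raise SegmentTableFormatError(f"{path}, line {idx}: {exc}") from exc
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if end <= start:
            raise SegmentTableFormatError(
                f"{path}, line {idx}: segment end {end1} <= start {start1}"
            )
        by_sample.setdefault(str(row.sample), []).append(
            GenomicSegment(chrom, start, end, n_probes, cn, loh)
        )
    return [
        SegmentProfile(sample_id=sid, genome=genome, segments=tuple(segs))
        for sid, segs in by_sample.items()
    ]


def _parse_loh(value) -> bool:
    v = str(value).strip()
    if v in ("0", "1"):
        return v == "1"
    raise ValueError(f"loh flag must be 0 or 1, got {value!r}")


def write_segment_table(profiles: Iterable[SegmentProfile], path: str | Path) -> None:
    """Write profiles in the seg_tsv dialect (1-based inclusive on disk)."""
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append(
                (p.sample_id, s.chrom, s.start + 1, s.end, s.n_probes,
                 s.copy_number, int(s.loh))
            )
    df = pd.DataFrame(rows, columns=SEG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table (sample, specimen_type, pair_id, context,
    diagnosis_label); empty strings become None."""
    df = pd.read_csv(path, sep="\t", dtype=str).where(lambda d: d.notna(), None)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentTableFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def attach_metadata(
    profiles: Iterable[SegmentProfile], metadata: pd.DataFrame
) -> list[SegmentProfile]:
    meta = {str(r.sample): r for r in metadata.itertuples(index=False)}
    out = []
    for p in profiles:
        r = meta.get(p.sample_id)
        if r is None:
            out.append(p)
            continue
        out.append(
            p.with_metadata(
                specimen_type=r.specimen_type or None,
                pair_id=r.pair_id or None,
                context=r.context or None,
                diagnosis_label=r.diagnosis_label or None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Filtering and derived interval sets
# ---------------------------------------------------------------------------

def estimate_ploidy_baseline(profile: SegmentProfile) -> int:
    """Genome-length-weighted modal copy number over the autosomes.

    Unsegmented autosomal territory counts as copy number 2. Ties are broken
    toward the copy number closest to 2 (diploid prior), then toward the
    lower copy number, so an all-neutral genome is always baseline 2.
    """
    coverage: dict[int, int] = {}
    covered = 0
    for s in profile.segments:
        if s.chrom not in AUTOSOMES:
            continue
        coverage[s.copy_number] = coverage.get(s.copy_number, 0) + s.length
        covered += s.length
    coverage[2] = coverage.get(2, 0) + (profile.genome.autosomal_length - covered)
    return min(coverage, key=lambda cn: (-coverage[cn], abs(cn - 2), cn))


def filter_segments(
    profile: SegmentProfile,
    min_length: int = 100_000,
    min_probes: int = 50,
    autosomes_only: bool = True,
    drop_neutral: bool = True,
) -> SegmentProfile:
    """Apply the standard segment-level filter and attach a ploidy baseline.

    Keeps segments with length >= ``min_length`` AND probe count >=
    ``min_probes`` (closed comparisons), restricted to autosomes by default.
    The ploidy baseline is estimated on the length/probe-filtered set, after
    which neutral non-LOH segments (CN equal to baseline, no allelic
    imbalance) are dropped: only aberrations participate downstream. An
    empty result is valid and means "no CNAs". Idempotent.
    """
    kept = [
        s for s in profile.segments
        if s.length >= min_length
        and s.n_probes >= min_probes
        and (not autosomes_only or s.chrom in AUTOSOMES)
    ]
    sized = replace(profile, segments=tuple(kept))
    baseline = (
        profile.ploidy_baseline
        if profile.ploidy_baseline is not None
        else estimate_ploidy_baseline(sized)
    )
    if drop_neutral:
        kept = [s for s in kept if s.state(baseline) != "neutral"]
    return replace(profile, segments=tuple(kept), ploidy_baseline=baseline)


STATES = ("gain", "loss", "cnloh")


def aberrant_intervals(
    profile: SegmentProfile, state_mode: str = "directional"
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Merged per-chromosome interval sets of aberrant territory.

    ``directional`` returns three disjoint sets keyed 'gain', 'loss',
    'cnloh' relative to the profile's ploidy baseline; ``any_aberration``
    returns their union under the single key 'aberrant'.
    """
    if state_mode not in ("directional", "any_aberration"):
        raise ConfigurationError(f"unknown state_mode {state_mode!r}")
    baseline = (
        profile.ploidy_baseline
        if profile.ploidy_baseline is not None
        else estimate_ploidy_baseline(profile)
    )
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {s: {} for s in STATES}
    for seg in profile.segments:
        state = seg.state(baseline)
        if state == "neutral":
            continue
        raw[state].setdefault(seg.chrom, []).append(seg.interval)
    merged = {
        state: {c: iv.merge(ivs) for c, ivs in per_chrom.items()}
        for state, per_chrom in raw.items()
    }
    if state_mode == "directional":
        return merged
    combined: dict[str, list[tuple[int, int]]] = {}
    for per_chrom in merged.values():
        for c, ivs in per_chrom.items():
            combined.setdefault(c, []).extend(ivs)
    return {"aberrant": {c: iv.merge(ivs) for c, ivs in combined.items()}}
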