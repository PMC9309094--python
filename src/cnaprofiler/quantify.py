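"""CNA burden per sample and the benign-vs-malignant group comparison.

Burden is summarised as the number of copy-number shifts per sample and the
number of autosomes carrying at least one aberration. Adjacent segments with
the same aberration state are coalesced before counting, so a chromosome arm
broken into two segmentation pieces counts as one shift (a ``coalesce=False``
escape hatch counts raw filtered segments instead).

Group comparison uses the two-sided Wilcoxon rank-sum (Mann-Whitney U) test.
To keep results independent of any statistics backend's defaults, the
contract is fixed here: the exact null distribution is used when both groups
have at most 12 observations and the pooled data contain no ties; otherwise
the normal approximation with tie correction and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .segio import (
    AUTOSOMES,
    DIAGNOSIS_CLASSES,
    SegmentProfile,
    estimate_ploidy_baseline,
)


@dataclass(frozen=True)
class QuantificationRecord:
    sample_id: str
    n_cna: int
    n_chrom: int
    diagnosis_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.diagnosis_class not in DIAGNOSIS_CLASSES:
            raise ValueError(f"unknown diagnosis_class {self.diagnosis_class!r}")
        if not (0 <= self.n_chrom <= 22 and self.n_chrom <= self.n_cna):
            raise ValueError("inconsistent CNA counts")
        if self.n_cna == 0 and self.n_chrom != 0:
            raise ValueError("n_chrom must be 0 when n_cna is 0")


def coalesced_segments(profile: SegmentProfile) -> list[tuple[str, int, int, str]]:
    """Aberrant segments after merging touching same-state neighbours.

    Returns (chrom, start, end, state) tuples relative to the profile's
    ploidy baseline; neutral segments are ignored.
    """
    baseline = (
        profile.ploidy_baseline
        if profile.ploidy_baseline is not None
        else estimate_ploidy_baseline(profile)
    )
    out: list[tuple[str, int, int, str]] = []
    for seg in profile.segments:  # already sorted by (chrom, start)
        state = seg.state(baseline)
        if state == "neutral":
            continue
        if out and out[-1][0] == seg.chrom and out[-1][3] == state and out[-1][2] >= seg.start:
            prev = out[-1]
            out[-1] = (prev[0], prev[1], max(prev[2], seg.end), state)
        else:
            out.append((seg.chrom, seg.start, seg.end, state))
    return out


def quantify_profile(
    profile: SegmentProfile,
    diagnosis_class: str = "unknown",
    coalesce: bool = True,
) -> QuantificationRecord:
    """Count copy-number shifts and aberrant autosomes for a filtered profile."""
    if coalesce:
        segs = coalesced_segments(profile)
        chroms = {c for c, *_ in segs if c in AUTOSOMES}
        n_cna = len(segs)
    else:
        baseline = (
            profile.ploidy_baseline
            if profile.ploidy_baseline is not None
            else estimate_ploidy_baseline(profile)
        )
        aberrant = [s for s in profile.segments if s.state(baseline) != "neutral"]
        chroms = {s.chrom for s in aberrant if s.chrom in AUTOSOMES}
        n_cna = len(aberrant)
    return QuantificationRecord(
        sample_id=profile.sample_id,
        n_cna=n_cna,
        n_chrom=len(chroms),
        diagnosis_class=diagnosis_class,
    )


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    medians: dict
    quartiles: dict
    n: dict


def _summary(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    v = np.asarray(values, dtype=float)
    return float(np.median(v)), (
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def compare_groups(
    records: Iterable[QuantificationRecord],
    metric: str = "n_cna",
    group_a: str = "benign",
    group_b: str = "malignant",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test of CNA burden between two classes.

    The test statistic reported is the Mann-Whitney U of the first group.
    """
    if metric not in ("n_cna", "n_chrom"):
        raise ValueError(f"unknown metric {metric!r}")
    xs = [getattr(r, metric) for r in records if r.diagnosis_class == group_a]
    ys = [getattr(r, metric) for r in records if r.diagnosis_class == group_b]
    if not xs or not ys:
        raise ValueError(
            f"both groups must be non-empty (got {len(xs)} {group_a}, {len(ys)} {group_b})"
        )
    pooled = xs + ys
    no_ties = len(set(pooled)) == len(pooled)
    if max(len(xs), len(ys)) <= 12 and no_ties:
        method = "exact"
        res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="exact")
    else:
        method = "normal_approx"
        res = stats.mannwhitneyu(
            xs, ys, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    med_a, q_a = _summary(xs)
    med_b, q_b = _summary(ys)
    return GroupComparison(
        metric=metric,
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=method,
        medians={group_a: med_a, group_b: med_b},
        quartiles={group_a: q_a, group_b: q_b},
        n={group_a: len(xs), group_b: len(ys)},
    )
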