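"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval algebra and statistics
paths: the Jaccard oracle counts per-base memberships in numpy arrays on a
toy genome, and the Wilcoxon oracle enumerates the full permutation null.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from cnaprofiler.segio import AUTOSOMES, SegmentProfile


def brute_baseline(profile: SegmentProfile) -> int:
    """Length-weighted modal CN, unsegmented autosomal bases counted as CN 2,
    ties broken toward 2 then toward the lower CN (mirrors the documented
    rule, computed per-base instead of per-segment)."""
    counts: dict[int, int] = {}
    for chrom in AUTOSOMES:
        arr = np.full(profile.genome[chrom], 2, dtype=np.int64)
        for s in profile.segments:
            if s.chrom == chrom:
                arr[s.start:s.end] = s.copy_number
        vals, cnts = np.unique(arr, return_counts=True)
        for v, c in zip(vals, cnts):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    return min(counts, key=lambda cn: (-counts[cn], abs(cn - 2), cn))


def _state_arrays(profile: SegmentProfile, baseline: int) -> dict[str, np.ndarray]:
    """Per-base state codes per autosome: 0 neutral, 1 gain, 2 loss, 3 cnloh."""
    out = {}
    for chrom in AUTOSOMES:
        arr = np.zeros(profile.genome[chrom], dtype=np.int8)
        for s in profile.segments:
            if s.chrom != chrom:
                continue
            if s.copy_number > baseline:
                code = 1
            elif s.copy_number < baseline:
                code = 2
            elif s.loh:
                code = 3
            else:
                code = 0
            arr[s.start:s.end] = code
        out[chrom] = arr
    return out


def brute_jaccard(
    a: SegmentProfile, b: SegmentProfile, state_mode: str = "directional"
) -> float:
    """Per-base membership-count Jaccard on a small genome."""
    sa = _state_arrays(a, brute_baseline(a))
    sb = _state_arrays(b, brute_baseline(b))
    inter = union = 0
    for chrom in AUTOSOMES:
        xa, xb = sa[chrom], sb[chrom]
        aber_a, aber_b = xa > 0, xb > 0
        union += int(np.sum(aber_a | aber_b))
        if state_mode == "directional":
            inter += int(np.sum(aber_a & aber_b & (xa == xb)))
        else:
            inter += int(np.sum(aber_a & aber_b))
    if union == 0:
        return 1.0
    return inter / union


def wilcoxon_exact_two_sided(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    Requires no ties. p = min(1, 2 * min(P(U <= u), P(U >= u))) where U is
    the Mann-Whitney statistic of the first group under all label
    assignments.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    m, n = len(x), len(y)
    order = sorted(range(m + n), key=lambda i: pooled[i])
    ranks = [0.0] * (m + n)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    u_obs = sum(ranks[:m]) - m * (m + 1) / 2
    all_ranks = list(range(1, m + n + 1))
    cnt_le = cnt_ge = 0
    for combo in combinations(all_ranks, m):
        u = sum(combo) - m * (m + 1) / 2
        if u <= u_obs:
            cnt_le += 1
        if u >= u_obs:
            cnt_ge += 1
    total = comb(m + n, m)
    return min(1.0, 2 * min(cnt_le, cnt_ge) / total)
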