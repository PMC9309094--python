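"""Genomic Jaccard similarity between two copy-number profiles.

Builds two profiles with partially overlapping gains on chromosome 1 and
prints their similarity: overlapping aberrant base pairs divided by the
base-pair length of the union of aberrant territory.
"""

from cnaprofiler import ChromosomeTable, GenomicSegment, SegmentProfile
from cnaprofiler import filter_segments, jaccard_detailed

genome = ChromosomeTable.hg19()

# 10 Mb gain at chr1:10-20 Mb vs 10 Mb gain at chr1:15-25 Mb
a = SegmentProfile(
    sample_id="tumor_a", genome=genome,
    segments=(GenomicSegment("1", 10_000_000, 20_000_000, 9000, 3),),
)
b = SegmentProfile(
    sample_id="tumor_b", genome=genome,
    segments=(GenomicSegment("1", 15_000_000, 25_000_000, 9000, 3),),
)

score = jaccard_detailed(filter_segments(a), filter_segments(b))
print(f"shared aberrant bases : {score.intersection_bp:,}")
print(f"union of aberrations  : {score.union_bp:,}")
print(f"Jaccard similarity    : {score.value:.4f}")
# 5 Mb of the 15 Mb union is shared, so J = 1/3: these profiles overlap
# substantially but are far from identical (J = 1 means complete overlap).
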