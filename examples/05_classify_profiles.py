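"""Rule-based diagnostic indication of copy-number profiles.

Generates one profile per archetype and prints the indication the rule
engine assigns together with the evidence that fired.
"""

from cnaprofiler import (
    classify_profile, default_spec, filter_segments, generate_profile,
)
from cnaprofiler.synthetic import ARCHETYPES

for name in ARCHETYPES:
    profile = filter_segments(generate_profile(default_spec(name), seed=11))
    res = classify_profile(profile)
    top = res.top
    print(f"{name:24s} -> [{top.tier}] {top.label}")
    for fact in top.evidence:
        print(f"{'':24s}    - {fact}")
# The indication is context-dependent by design: the same 12q amplicon reads
# as ALT/WDLS in soft tissue but as parosteal osteosarcoma on a bone surface.
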