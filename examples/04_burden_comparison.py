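"""CNA burden quantification and the benign-vs-malignant comparison.

Quantifies copy-number shifts per sample on a mixed synthetic cohort and
runs the two-sided Wilcoxon rank-sum test between diagnosis classes.
"""

from cnaprofiler import (
    CohortEntry, compare_groups, default_spec, filter_segments,
    generate_cohort, quantify_profile,
)

design = [
    CohortEntry(default_spec("benign_low_complexity"), 15),
    CohortEntry(default_spec("complex_gain"), 8),
    CohortEntry(default_spec("complex_loss"), 7),
]
cohort = generate_cohort(design, seed=3)

records = []
for p in cohort.profiles:
    cls = "benign" if p.sample_id.startswith("benign") else "malignant"
    records.append(quantify_profile(filter_segments(p), diagnosis_class=cls))

res = compare_groups(records, metric="n_cna")
print(f"median CNAs benign    : {res.medians['benign']:.1f}")
print(f"median CNAs malignant : {res.medians['malignant']:.1f}")
print(f"Wilcoxon ({res.method}) p = {res.p_value:.2e}")
# Malignant profiles carry far more copy-number shifts than benign ones;
# the rank-sum test rejects equal burden at any conventional level.
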