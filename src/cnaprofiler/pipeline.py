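"""End-to-end orchestration: read, filter, cluster, quantify, classify.

The full analysis is deterministic: reading the same inputs with the same
configuration reproduces identical non-log outputs, and the run manifest
records the configuration, package version and input checksums so a run can
be audited. Randomness exists only in cohort simulation.

Profiles that are empty after filtering carry real information (no CNAs =
no support for a neoplastic lesion) and are quantified and classified, but
they are excluded from the similarity matrix and dendrogram: clustering is
only meaningful over aberrant profiles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .classifier import ClassifierConfig, classify_profile
from .quantify import compare_groups, quantify_profile
from .segio import (
    ChromosomeTable,
    DIAGNOSIS_CLASSES,
    LocusTable,
    SegmentProfile,
    attach_metadata,
    filter_segments,
    read_metadata,
    read_segment_table,
    write_segment_table,
)
from .similarity import cluster, cut_clusters, sibling_pairs, similarity_matrix
from .synthetic import (
    ArchetypeSpec,
    Cohort,
    CohortEntry,
    PairNoiseSpec,
    generate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one analysis run."""

    segments: str
    out_dir: str
    metadata: Optional[str] = None
    min_length: int = 100_000
    min_probes: int = 50
    autosomes_only: bool = True
    state_mode: str = "directional"
    linkage: str = "complete"
    cut_k: Optional[int] = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cls_kwargs = {k: v for k, v in raw.items() if k != "classifier"}
        cfg = cls(**cls_kwargs)
        if "classifier" in raw:
            cfg.classifier = ClassifierConfig(**raw["classifier"])
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _diagnosis_class(label: Optional[str]) -> str:
    if label and label.strip().lower() in DIAGNOSIS_CLASSES:
        return label.strip().lower()
    return "unknown"


def load_cohort(config: RunConfig, genome: ChromosomeTable) -> list[SegmentProfile]:
    profiles = read_segment_table(config.segments, genome=genome)
    if config.metadata:
        meta = read_metadata(config.metadata)
        # samples listed in the metadata but absent from the segment table are
        # real samples without segment calls (a normal profile writes no rows)
        seen = {p.sample_id for p in profiles}
        for sid in meta["sample"]:
            if str(sid) not in seen:
                profiles.append(SegmentProfile(sample_id=str(sid), genome=genome))
        profiles = attach_metadata(profiles, meta)
    if not profiles:
        raise ValueError("no samples: the segment table contains no rows")
    return profiles


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under out_dir.

    Returns a summary dict (also written as manifest.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = ChromosomeTable.hg19()
    loci = LocusTable.hg19()

    profiles = load_cohort(config, genome)
    filtered = [
        filter_segments(
            p,
            min_length=config.min_length,
            min_probes=config.min_probes,
            autosomes_only=config.autosomes_only,
        )
        for p in profiles
    ]

    # quantification -----------------------------------------------------
    records = [
        quantify_profile(p, diagnosis_class=_diagnosis_class(p.diagnosis_label))
        for p in filtered
    ]
    qdf = pd.DataFrame(
        [(r.sample_id, r.n_cna, r.n_chrom, r.diagnosis_class) for r in records],
        columns=["sample", "n_cna", "n_chrom", "diagnosis_class"],
    )
    qdf.to_csv(out / "quantification.tsv", sep="\t", index=False)
    summary: dict = {"n_samples": len(filtered)}
    classes = set(qdf["diagnosis_class"])
    if {"benign", "malignant"} <= classes:
        summary["burden_comparison"] = {}
        for metric in ("n_cna", "n_chrom"):
            cmp_res = compare_groups(records, metric=metric)
            summary["burden_comparison"][metric] = {
                "statistic": cmp_res.statistic,
                "p_value": cmp_res.p_value,
                "method": cmp_res.method,
                "medians": cmp_res.medians,
                "quartiles": cmp_res.quartiles,
                "n": cmp_res.n,
            }
    with open(out / "quantification_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    # classification ------------------------------------------------------
    cls_rows = []
    cls_json = []
    for p in filtered:
        res = classify_profile(p, loci=loci, config=config.classifier)
        for ind in res.indications:
            cls_rows.append((p.sample_id, ind.tier, ind.label, "; ".join(ind.evidence)))
        cls_json.append(
            {
                "sample": p.sample_id,
                "profile_normal": res.profile_normal,
                "indications": [
                    {"label": i.label, "tier": i.tier, "evidence": list(i.evidence)}
                    for i in res.indications
                ],
            }
        )
    pd.DataFrame(cls_rows, columns=["sample", "tier", "label", "evidence"]).to_csv(
        out / "classification.tsv", sep="\t", index=False
    )
    with open(out / "classification.json", "w") as fh:
        json.dump(cls_json, fh, indent=2, sort_keys=True)

    # clustering ----------------------------------------------------------
    aberrant = [p for p in filtered if not p.is_empty]
    summary["n_aberrant"] = len(aberrant)
    if len(aberrant) >= 2:
        mat = similarity_matrix(aberrant, state_mode=config.state_mode)
        mat.write_tsv(out / "similarity_matrix.tsv")
        tree = cluster(mat, linkage=config.linkage)
        (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        if config.cut_k:
            labels = cut_clusters(tree, config.cut_k)
            pd.DataFrame(
                sorted(labels.items()), columns=["sample", "cluster"]
            ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        pair_ids: dict[str, list[str]] = {}
        for p in aberrant:
            if p.pair_id:
                pair_ids.setdefault(p.pair_id, []).append(p.sample_id)
        pairs = {pid: ids for pid, ids in pair_ids.items() if len(ids) == 2}
        if pairs:
            adj = sibling_pairs(tree, [tuple(v) for v in pairs.values()], matrix=mat)
            pd.DataFrame(
                [
                    (pid, int(a.adjacent), f"{a.jaccard:.6f}")
                    for pid, a in zip(pairs.keys(), adj)
                ],
                columns=["pair_id", "adjacent", "jaccard"],
            ).to_csv(out / "pair_adjacency.tsv", sep="\t", index=False)
            summary["pair_adjacency_rate"] = sum(a.adjacent for a in adj) / len(adj)
    else:
        logger.info(
            "clustering skipped: %d aberrant profile(s) after filtering", len(aberrant)
        )
        summary["clustering_skipped"] = True

    # manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": _config_dict(config),
        "inputs": {
            "segments": _sha256(Path(config.segments)),
            **(
                {"metadata": _sha256(Path(config.metadata))}
                if config.metadata
                else {}
            ),
        },
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def parse_design(raw: dict) -> list[CohortEntry]:
    """Build a cohort design from a flat mapping (YAML-friendly).

    Expected shape::

        entries:
          - archetype: complex_gain
            count: 10
            template_seed: 3        # optional
            noise:                  # optional -> matched pairs
              dropout_rate: 0.05
              boundary_jitter_sd: 10000
              private_rate: 0.2
    """
    if not raw or "entries" not in raw:
        raise ValueError(
            "design must define 'entries', a list of "
            "{archetype, count[, template_seed, context, noise]}"
        )
    entries = []
    for e in raw["entries"]:
        missing = [k for k in ("archetype", "count") if k not in e]
        if missing:
            raise ValueError(f"design entry missing fields: {', '.join(missing)}")
        spec = ArchetypeSpec(
            name=e["archetype"],
            context=e.get(
                "context",
                "intraabdominal" if e["archetype"] == "gist_like"
                else ("unknown" if e["archetype"] == "normal" else "soft_tissue"),
            ),
            template_seed=int(e.get("template_seed", 0)),
        )
        noise = None
        if "noise" in e and e["noise"] is not None:
            noise = PairNoiseSpec(**{k: v for k, v in e["noise"].items()})
        entries.append(CohortEntry(spec=spec, count=int(e["count"]), noise=noise))
    return entries


def simulate(
    design: Sequence[CohortEntry], out_dir: str | Path, seed: int = 0
) -> Cohort:
    """Generate a synthetic cohort and write its segment/metadata/truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(design, seed=seed)
    write_segment_table(cohort.profiles, out / "segments.tsv")
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return cohort
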