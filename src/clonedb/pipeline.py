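"""End-to-end pipeline steps over the relational store.

Each step is resumable: it reads its inputs from the store (or from files),
writes its outputs back, and can run in a separate process from the other
steps with identical results to a single-process run.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .annotate import (
    IDENTIFIED,
    AnnotatedSequence,
    AnnotationConfig,
    SampleMetadata,
    annotate_sample,
)
from .clones import CloneConfig, ClonePartition
from .collapse import collapse_sample, collapse_subject
from .germline import GermlineSet
from .store import Project

__all__ = [
    "identify_samples",
    "collapse_project",
    "clone_project",
    "compute_sample_stats",
]

log = logging.getLogger(__name__)


def identify_samples(
    project: Project,
    germlines: GermlineSet,
    reads_by_sample: Mapping[str, Sequence[tuple[str, str]]],
    metadata: Iterable[SampleMetadata],
    cfg: AnnotationConfig | None = None,
) -> dict[str, dict]:
    """Annotate each sample's reads and persist the results."""
    meta = {m.sample_name: m for m in metadata}
    summaries = {}
    for sample in sorted(reads_by_sample):
        if sample not in meta:
            raise ValueError(f"sample {sample!r} missing from metadata")
        anns, summary = annotate_sample(
            reads_by_sample[sample], meta[sample], germlines, cfg=cfg
        )
        project.save_annotations(meta[sample], anns)
        project.save_sample_stats(sample, summary)
        summaries[sample] = summary
    return summaries


def collapse_project(project: Project) -> dict[str, int]:
    """Collapse stored annotations into subject-level unique sequences."""
    counts = {}
    for subject in project.subjects():
        sample_uniques = []
        for sample in project.samples_of(subject):
            anns = project.load_annotations(sample=sample)
            sample_uniques.extend(collapse_sample(anns))
        uniques = collapse_subject(sample_uniques, subject)
        project.save_uniques(subject, uniques)
        counts[subject] = len(uniques)
        log.info("subject %s: %d unique sequences", subject, len(uniques))
    return counts


def clone_project(
    project: Project, cfg: CloneConfig
) -> dict[str, ClonePartition]:
    """Run clonal inference for every subject in the store."""
    return {
        subject: project.rerun_clones(subject, cfg)
        for subject in project.subjects()
    }


def compute_sample_stats(
    anns: Iterable[AnnotatedSequence],
) -> dict[str, dict]:
    """Per-sample identification counts from a stream of annotations."""
    out: dict[str, dict] = defaultdict(
        lambda: {"n_reads": 0, "n_identified": 0, "mutation_sum": 0.0}
    )
    for a in anns:
        d = out[a.sample]
        d["n_reads"] += 1
        if a.status == IDENTIFIED:
            d["n_identified"] += 1
            d["mutation_sum"] += a.mutation_fraction
    for d in out.values():
        n = d.pop("mutation_sum"), d["n_identified"]
        d["mean_mutation_fraction"] = n[0] / n[1] if n[1] else 0.0
    return dict(out)
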