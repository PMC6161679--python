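"""Shared fixtures: toy hand-built germlines and simulated repertoires."""
from __future__ import annotations

from collections import Counter

import pytest

from clonedb.annotate import AnnotatedSequence, annotate_sample
from clonedb.clones import CloneConfig, eligibility_filter
from clonedb.collapse import collapse_sample, collapse_subject
from clonedb.germline import GermlineGene, GermlineSet
from clonedb.synth import SimConfig, simulate_repertoire, synthetic_germline_set


@pytest.fixture(scope="session")
def germlines() -> GermlineSet:
    """Deterministic synthetic germline set: 3 V families x 3 alleles, 4 Js."""
    return synthetic_germline_set(seed=7)


@pytest.fixture(scope="session")
def germlines_with_pseudogene() -> GermlineSet:
    return synthetic_germline_set(seed=7, include_pseudogene=True)


@pytest.fixture
def toy_j_pair() -> GermlineSet:
    """Two J alleles with equal post-anchor tails, distance 2 apart."""
    j1 = GermlineGene(
        name="IGHJ1*01",
        segment="J",
        gapped_seq="ACGTACGTAC" + "TGGGG" + "ACGTACGTACGTACGTACGT",
        anchor_pos=10,
    )
    j4 = GermlineGene(
        name="IGHJ4*01",
        segment="J",
        gapped_seq="ACGTACGTAC" + "TGGGG" + "ACGTACGTACGTACGTACCC",
        anchor_pos=10,
    )
    v = GermlineGene(
        name="IGHV1-1*01",
        segment="V",
        gapped_seq="A" * 21 + "TATTACTGT",
        anchor_pos=27,
    )
    return GermlineSet(
        v_genes={v.name: v}, j_genes={j1.name: j1, j4.name: j4}
    )


def make_ann(
    seq: str,
    *,
    read_id: str = "r1",
    sample: str = "s1",
    v_ties=("IGHV1-1*01",),
    j_ties=("IGHJ1*01",),
    cdr3_start: int = 0,
    cdr3_end: int = 0,
    copy_number: int = 1,
    status: str = "identified",
    v_mutations=(),
    cdr3_nt: str | None = None,
    cdr3_aa: str | None = None,
) -> AnnotatedSequence:
    """Hand-built annotation for collapse/clone unit tests."""
    from clonedb.annotate import translate_nt

    nt = cdr3_nt if cdr3_nt is not None else seq[cdr3_start:cdr3_end]
    return AnnotatedSequence(
        read_id=read_id,
        sample=sample,
        sequence=seq,
        status=status,
        v_ties=tuple(v_ties),
        j_ties=tuple(j_ties),
        cdr3_start=cdr3_start,
        cdr3_end=cdr3_end,
        cdr3_nt=nt,
        cdr3_aa=cdr3_aa if cdr3_aa is not None else translate_nt(nt),
        v_identity=1.0,
        copy_number=copy_number,
        v_mutations=tuple(v_mutations),
    )


@pytest.fixture(scope="session")
def pipeline_run(germlines):
    """One simulated repertoire pushed through annotate -> collapse ->
    eligibility, with planted clone labels for the eligible uniques."""
    cfg = SimConfig(seed=20, n_clones=20)
    result = simulate_repertoire(cfg, germlines)
    truth = result.truth.set_index("read_id")
    sample_uniques = []
    summaries = {}
    for m in result.metadata:
        anns, summary = annotate_sample(
            result.reads_by_sample[m.sample_name], m, germlines
        )
        summaries[m.sample_name] = summary
        sample_uniques.extend(collapse_sample(anns))
    uniques = collapse_subject(sample_uniques, cfg.subject)
    eligible = eligibility_filter(uniques, CloneConfig())
    planted = [
        Counter(
            truth.loc[rid]["clone_id"] for _, rid in u.member_reads
        ).most_common(1)[0][0]
        for u in eligible
    ]
    return {
        "config": cfg,
        "result": result,
        "truth": truth,
        "uniques": uniques,
        "eligible": eligible,
        "planted": planted,
        "summaries": summaries,
    }
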