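"""Anchor-based V/J assignment, QC flags and the comparison filter."""
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonedb.annotate import (
    IDENTIFIED,
    POTENTIAL_INDEL,
    UNIDENTIFIABLE,
    SampleMetadata,
    annotate_read,
    annotate_sample,
    assign_j,
    assign_v,
    comparison_filter,
    hamming,
    qc_status,
)

NT = st.text(alphabet="ACGTN", min_size=0, max_size=60)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGT", "ACGT", 0),
        ("ACGT", "ACGA", 1),
        ("ANGT", "AGGT", 0),  # N is masked, not a mismatch
        ("AC.T", "ACGT", 0),  # gap positions skipped
    ],
)
def test_hamming_examples(a, b, expected):
    assert hamming(a, b) == expected


def test_hamming_unequal_lengths_raise():
    with pytest.raises(ValueError):
        hamming("ACG", "ACGT")


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 40), st.data())
def test_hamming_matches_bruteforce(n, data):
    """Positionwise brute-force count agrees with hamming on random pairs."""
    a = data.draw(st.text(alphabet="ACGTN", min_size=n, max_size=n))
    b = data.draw(st.text(alphabet="ACGTN", min_size=n, max_size=n))
    oracle = sum(
        1
        for i in range(n)
        if a[i] != b[i] and a[i] != "N" and b[i] != "N"
    )
    assert hamming(a, b) == oracle


class TestAssignJ:
    def test_exact_tail_is_assigned(self, toy_j_pair):
        j1 = toy_j_pair.j_genes["IGHJ1*01"]
        read = "CACACACACA" + j1.seq[j1.anchor_pos :]
        res = assign_j(read, toy_j_pair)
        assert res is not None
        assert res.anchor_pos == 10
        assert "IGHJ1*01" in res.ties and res.distance == 0

    def test_no_anchor_motif_is_unidentifiable(self, toy_j_pair):
        assert assign_j("ACGT" * 20, toy_j_pair) is None

    def test_equidistant_germlines_both_tie(self, toy_j_pair):
        """A tail at Hamming distance 1 from both J alleles yields both ties.

        The two toy tails differ only at their last 2 nt (GT vs CC); the
        chimeric ending "GC" is distance 1 from each (brute-force checked).
        """
        j1 = toy_j_pair.j_genes["IGHJ1*01"]
        j4 = toy_j_pair.j_genes["IGHJ4*01"]
        tail = j1.j_tail[:-2] + "GC"
        assert hamming(tail, j1.j_tail) == 1
        assert hamming(tail, j4.j_tail) == 1
        res = assign_j("CACACACACA" + tail, toy_j_pair)
        assert set(res.ties) == {"IGHJ1*01", "IGHJ4*01"}


def _clean_read(germlines, v_name="IGHV1-1*01", j_name="IGHJ1*01", junction="GCTAAATTTGGGCCCTAG"):
    v = germlines.v_genes[v_name]
    j = germlines.j_genes[j_name]
    return v.seq[: v.anchor_end] + junction + j.seq[j.anchor_pos :]


class TestAssignV:
    def test_exact_copy_full_identity(self, germlines):
        read = _clean_read(germlines)
        j = assign_j(read, germlines)
        v = assign_v(read, j, germlines)
        assert "IGHV1-1*01" in v.ties
        assert v.v_identity == 1.0
        assert v.align_start == 0

    def test_heavily_mutated_read_fails_floor(self, germlines):
        """45% of compared V positions mutated -> identity ~0.55, below the
        60% floor -> unidentifiable."""
        read = _clean_read(germlines)
        rng = random.Random(5)
        v = germlines.v_genes["IGHV1-1*01"]
        mutable = list(range(v.anchor_end - 9))  # keep the anchor context
        sites = rng.sample(mutable, int(0.45 * v.anchor_end))
        seq = list(read)
        for s in sites:
            seq[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[s]]
        ann = annotate_read("r", "s", "".join(seq), germlines)
        assert ann.status == UNIDENTIFIABLE

    def test_near_allele_joins_ties(self, germlines):
        """A read 2 mutations from its true allele stays within the tie
        tolerance of the 4-substitution sibling allele check."""
        read = _clean_read(germlines, v_name="IGHV1-1*02")
        j = assign_j(read, germlines)
        v = assign_v(read, j, germlines)
        assert v.ties[0].startswith("IGHV1-1")
        # mutate 2 of the 4 allele-difference positions toward *01: now
        # distance 2 from both alleles -> both tie
        d01 = [
            i
            for i, (a, b) in enumerate(
                zip(
                    germlines.v_genes["IGHV1-1*01"].seq,
                    germlines.v_genes["IGHV1-1*02"].seq,
                )
            )
            if a != b
        ]
        seq = list(read)
        for i in d01[:2]:
            seq[i] = germlines.v_genes["IGHV1-1*01"].seq[i]
        v2 = assign_v("".join(seq), j, germlines)
        assert {"IGHV1-1*01", "IGHV1-1*02"} <= set(v2.ties)


class TestQc:
    def test_clean_read_identified(self):
        assert qc_status(0.95, (False,) * 100) == IDENTIFIED

    def test_low_overall_identity_unidentifiable(self):
        assert qc_status(0.55, (False,) * 100) == UNIDENTIFIABLE

    def test_scrambled_window_flags_potential_indel(self, germlines):
        """A 30-nt stretch scrambled to ~50% identity with perfect flanks is
        flagged; the sliding-window minimum is verified by brute force."""
        read = _clean_read(germlines)
        rng = random.Random(3)
        seq = list(read)
        start = 60
        for i in range(start, start + 30):
            if rng.random() < 0.5:
                seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        ann = annotate_read("r", "s", "".join(seq), germlines)
        profile = ann.mismatch_profile
        worst = max(
            sum(profile[i : i + 30]) for i in range(len(profile) - 29)
        )
        assert (30 - worst) / 30 < 0.60  # brute-force window check
        assert ann.status == POTENTIAL_INDEL


class TestAnnotateSample:
    def test_unmutated_reads_all_identified(self, germlines):
        meta = SampleMetadata(sample_name="s1", subject="S")
        reads = []
        for i, vn in enumerate(sorted(germlines.v_genes)):
            for j, jn in enumerate(sorted(germlines.j_genes)):
                reads.append(
                    (f"r{i}_{j}", _clean_read(germlines, vn, jn, "GCA" * 6))
                )
        anns, summary = annotate_sample(reads, meta, germlines)
        assert summary["n_identified"] == len(reads)
        assert summary["mean_mutation_fraction"] == 0.0
        for (rid, _), a in zip(reads, anns):
            i, j = map(int, rid[1:].split("_"))
            assert sorted(germlines.v_genes)[i] in a.v_ties
            assert sorted(germlines.j_genes)[j] in a.j_ties

    def test_random_reads_mostly_unidentifiable(self, germlines):
        rng = random.Random(9)
        meta = SampleMetadata(sample_name="s1", subject="S")
        reads = [
            (f"r{i}", "".join(rng.choice("ACGT") for _ in range(350)))
            for i in range(100)
        ]
        anns, summary = annotate_sample(reads, meta, germlines)
        # anchors rarely occur by chance; expect near-zero identification
        assert summary["n_identified"] <= 2

    def test_statuses_partition_input(self, germlines):
        rng = random.Random(1)
        meta = SampleMetadata(sample_name="s1", subject="S")
        reads = [("g", _clean_read(germlines))]
        reads += [
            (f"x{i}", "".join(rng.choice("ACGT") for _ in range(300)))
            for i in range(20)
        ]
        anns, summary = annotate_sample(reads, meta, germlines)
        assert (
            summary["n_identified"]
            + summary["n_unidentifiable"]
            + summary["n_potential_indel"]
            == summary["n_reads"]
            == len(reads)
        )

    def test_empty_input_warns(self, germlines):
        meta = SampleMetadata(sample_name="s1", subject="S")
        with pytest.warns(UserWarning):
            anns, summary = annotate_sample([], meta, germlines)
        assert anns == [] and summary["n_reads"] == 0


class TestComparisonFilter:
    def _ann(self, germlines, **kw):
        return annotate_read("r", "s", _clean_read(germlines, **kw), germlines)

    def test_min_v_bases_boundary(self, germlines):
        ann = self._ann(germlines)
        full = comparison_filter([ann], germlines)
        assert len(full) == 1
        short = comparison_filter([ann], germlines, min_v_length=ann.v_length + 1)
        assert short == []

    @pytest.mark.parametrize("codons,kept", [(1, True), (32, True), (33, False)])
    def test_cdr3_length_bounds_inclusive(self, germlines, codons, kept):
        """CDR3 of 3..96 nt is retained ('between 3 and 96' inclusive)."""
        ann = self._ann(germlines, junction="GCA" * codons)
        assert ann.cdr3_end - ann.cdr3_start == 3 * codons
        assert bool(comparison_filter([ann], germlines)) is kept

    def test_pseudogene_assignment_removed(self, germlines_with_pseudogene):
        g = germlines_with_pseudogene
        pseudo = next(n for n, v in g.v_genes.items() if not v.functional)
        ann = self._ann(g, v_name=pseudo)
        assert pseudo in ann.v_ties
        assert comparison_filter([ann], g) == []

    def test_multi_family_ties_removed(self, germlines):
        from dataclasses import replace

        ann = self._ann(germlines)
        mixed = replace(ann, v_ties=("IGHV1-1*01", "IGHV2-1*01"))
        assert comparison_filter([mixed], germlines) == []


def test_zero_mutation_ties_rank_true_allele_first(germlines):
    """With no mutations, the minimum-distance member of the tie set is the
    generating allele."""
    for vn in sorted(germlines.v_genes):
        read = _clean_read(germlines, v_name=vn)
        ann = annotate_read("r", "s", read, germlines)
        j = assign_j(read, germlines)
        v = assign_v(read, j, germlines)
        assert v.distances[vn][0] == min(d for d, _ in v.distances.values())
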