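"""Clonal inference: similarity, T-cell and lineage methods."""
import random
from collections import defaultdict

import pytest

from clonedb.clones import (
    CloneConfig,
    cdr3_aa_similarity,
    eligibility_filter,
    infer_lineage,
    infer_similarity,
    infer_tcell,
)
from clonedb.collapse import UniqueSequence
from tests.conftest import make_ann


def unique(
    seq,
    cdr3_nt,
    *,
    copies=2,
    sample="s1",
    subject="SUBJ",
    v_ties=("IGHV1-1*01",),
    j_ties=("IGHJ1*01",),
    v_mutations=(),
    cdr3_aa=None,
    rid=None,
):
    rid = rid or f"r_{seq}_{cdr3_nt}"
    ann = make_ann(
        seq,
        read_id=rid,
        sample=sample,
        v_ties=v_ties,
        j_ties=j_ties,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        v_mutations=v_mutations,
    )
    return UniqueSequence(
        subject=subject,
        representative=seq,
        member_reads=frozenset({(sample, rid)}),
        per_sample_copies={sample: copies},
        annotation=ann,
    )


class TestSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("CARDYW", "CARDYW", 1.0),
            ("CARDYWGQGTLVTV"[:10], "CARDYWGQGTXVTV"[:10], 1.0),  # X wildcard
            ("ABCDEFGHIJ", "ABCDEFGHIX", 1.0),
            ("ABCDEFGHIJ", "ABCDEFGHIK", 0.9),
        ],
    )
    def test_similarity_values(self, a, b, expected):
        assert cdr3_aa_similarity(a, b) == pytest.approx(expected)

    def test_five_sixths_below_default_threshold_splits(self):
        """5/6 = 0.8333 < 0.85, so two length-6 CDR3s differing at one
        amino acid are not clonal at the default threshold."""
        a = unique("A" * 30, "TGTGCAAGAGATTACTGG"[:18], cdr3_aa="CARDYW")
        b = unique("C" * 30, "TGTGCAAGAGATTACTGG"[:18], cdr3_aa="CARDYF")
        assert cdr3_aa_similarity("CARDYW", "CARDYF") == pytest.approx(5 / 6)
        p = infer_similarity([a, b])
        assert len(p) == 2

    def test_identical_cdr3s_one_clone(self):
        us = [
            unique(f"{b}AAA", "GCAGCAGCA", copies=c)
            for b, c in zip("ACG", (3, 2, 1))
        ]
        p = infer_similarity(us)
        assert len(p) == 1 and p.clones[0].uniques == 3

    def test_different_j_key_splits(self):
        a = unique("AAAA", "GCAGCAGCA", j_ties=("IGHJ1*01",))
        b = unique("CCCC", "GCAGCAGCA", j_ties=("IGHJ2*01",))
        assert len(infer_similarity([a, b])) == 2

    def test_greedy_chain_hand_trace(self):
        """A~B=0.9, B~C=0.9, A~C=0.8 with copies A=3,B=2,C=1: A founds, B
        joins, C fails the pairwise check against A -> partition {A,B},{C}."""
        aa = {"A": "KKKKKKKKKK", "B": "KKKKKKKKKR", "C": "KKKKKKKKRR"}
        copies = {"A": 3, "B": 2, "C": 1}
        us = {
            k: unique(f"{k*4}", "GCA" * 10, copies=copies[k], cdr3_aa=v, rid=k)
            for k, v in aa.items()
        }
        assert cdr3_aa_similarity(aa["A"], aa["B"]) == 0.9
        assert cdr3_aa_similarity(aa["B"], aa["C"]) == 0.9
        assert cdr3_aa_similarity(aa["A"], aa["C"]) == 0.8
        p = infer_similarity(list(us.values()), CloneConfig(min_copies=1))
        groups = sorted(
            sorted(next(iter(m.member_reads))[1] for m in c.members)
            for c in p.clones
        )
        assert groups == [["A", "B"], ["C"]]

    def test_pairwise_invariant_on_pipeline(self, pipeline_run):
        p = infer_similarity(pipeline_run["eligible"])
        for c in p.clones:
            aas = [m.cdr3_aa for m in c.members]
            keys = {(m.annotation.v_ties, m.annotation.j_ties, len(m.cdr3_nt)) for m in c.members}
            assert len(keys) == 1
            for x in aas:
                for y in aas:
                    assert cdr3_aa_similarity(x, y) >= 0.85


class TestTcell:
    def test_one_nt_difference_splits(self):
        a = unique("AAAA", "GCAGCAGCA")
        b = unique("CCCC", "GCAGCAGCG")
        assert len(infer_tcell([a, b])) == 2

    def test_n_masked_cdr3_joins(self):
        a = unique("AAAA", "GCAGCAGCA", copies=3)
        b = unique("CCCC", "GCAGCNGCA")
        assert len(infer_tcell([a, b])) == 1

    def test_equals_bruteforce_groupby(self, pipeline_run):
        """On N-free CDR3s the T-cell method is exactly a group-by on
        (V key, J key, CDR3 nt)."""
        elig = [u for u in pipeline_run["eligible"] if "N" not in u.cdr3_nt]
        p = infer_tcell(elig)
        oracle = defaultdict(set)
        for u in elig:
            key = (
                ",".join(sorted(u.annotation.v_ties)),
                ",".join(sorted(u.annotation.j_ties)),
                u.cdr3_nt,
            )
            oracle[key].add(u.member_reads)
        assert {c.member_keys for c in p.clones} == {
            frozenset(v) for v in oracle.values()
        }


class TestEligibility:
    def test_copy_threshold(self):
        us = [unique(f"{b*4}", "GCAGCAGCA", copies=c) for b, c in zip("ACG", (1, 2, 3))]
        kept = eligibility_filter(us, CloneConfig())
        assert sorted(u.copies for u in kept) == [2, 3]

    def test_min_copies_one_is_identity(self):
        us = [unique(f"{b*4}", "GCAGCAGCA", copies=1) for b in "ACG"]
        assert len(eligibility_filter(us, CloneConfig(min_copies=1))) == 3

    def test_all_singletons_empty(self):
        us = [unique(f"{b*4}", "GCAGCAGCA", copies=1) for b in "ACG"]
        assert eligibility_filter(us, CloneConfig()) == []


def lineage_unique(name, v_mutations, cdr3="GCAGCAGCA"):
    return unique(
        name, cdr3, v_mutations=tuple((p, "T") for p in v_mutations), rid=name
    )


class TestLineage:
    def test_tight_bucket_single_clone(self):
        """All sequences within 3 mutations of the germline and of each
        other: the budget is never reached -> one clone."""
        us = [
            lineage_unique("AAA1", [5, 9]),
            lineage_unique("AAA2", [5, 9, 12]),
            lineage_unique("AAA3", [5]),
            lineage_unique("AAA4", [5, 9]),
        ]
        p = infer_lineage(us)
        assert len(p) == 1

    def test_two_separated_groups_two_clones(self):
        """Two tight groups ten mutations apart are cut into two clones; by
        brute force, any path between the groups accumulates >= the budget."""
        ga = [lineage_unique(f"A{i}", [3, 7, 11, 15, 19]) for i in range(3)]
        gb = [lineage_unique(f"B{i}", [30, 34, 38, 42, 46]) for i in range(3)]
        sets = [frozenset((p, "T") for p in [3, 7, 11, 15, 19])] * 3 + [
            frozenset((p, "T") for p in [30, 34, 38, 42, 46])
        ] * 3
        for a in sets[:3]:
            for b in sets[3:]:
                assert len(a ^ b) >= 4  # linkage between groups >= budget
        p = infer_lineage(ga + gb)
        assert len(p) == 2
        groups = sorted(
            sorted(m.representative[0] for m in c.members) for c in p.clones
        )
        assert groups == [["A", "A", "A"], ["B", "B", "B"]]

    def test_singleton_bucket(self):
        p = infer_lineage([lineage_unique("AAA", [1, 2, 3, 4, 5, 6])])
        assert len(p) == 1

    def test_order_invariance(self, pipeline_run):
        """The lineage method is order-agnostic: seeded shuffles of the
        input leave the partition unchanged."""
        elig = list(pipeline_run["eligible"])
        baseline = {
            frozenset(c.member_keys) for c in infer_lineage(elig).clones
        }
        rng = random.Random(0)
        for _ in range(5):
            shuffled = list(elig)
            rng.shuffle(shuffled)
            again = {
                frozenset(c.member_keys) for c in infer_lineage(shuffled).clones
            }
            assert again == baseline


@pytest.mark.parametrize("method", ["similarity", "tcell", "lineage"])
def test_partition_property(pipeline_run, method):
    """Every eligible sequence belongs to exactly one clone."""
    fn = {"similarity": infer_similarity, "tcell": infer_tcell, "lineage": infer_lineage}[method]
    p = fn(pipeline_run["eligible"])
    seen = [m.member_reads for c in p.clones for m in c.members]
    assert len(seen) == len(pipeline_run["eligible"])
    assert len(set(seen)) == len(seen)


def test_clone_key_and_subject_invariant(pipeline_run):
    for p in (
        infer_similarity(pipeline_run["eligible"]),
        infer_lineage(pipeline_run["eligible"]),
    ):
        for c in p.clones:
            assert {m.subject for m in c.members} == {"S1"}
            assert {len(m.cdr3_nt) for m in c.members} == {c.cdr3_len}


def test_planted_clone_recovery(pipeline_run):
    """Similarity and lineage methods recover planted clones (ARI >= 0.95)."""
    from sklearn.metrics import adjusted_rand_score

    for fn in (infer_similarity, infer_lineage):
        p = fn(pipeline_run["eligible"])
        asg = p.assignment()
        inferred = [asg[u.member_reads] for u in pipeline_run["eligible"]]
        assert adjusted_rand_score(pipeline_run["planted"], inferred) >= 0.95
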