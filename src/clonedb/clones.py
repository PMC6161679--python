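"""Clonal inference: grouping subject-level unique sequences into clones.

Three methods are provided, all operating on clone-eligible unique sequences
(copy number >= 2 by default, suppressing sequencing-error singletons) and all
constrained so that members of a clone share the same V key, J key, CDR3
length and subject:

* ``similarity`` (B cells): greedy assignment in order of decreasing copy
  number; a sequence joins the first clone in which it has at least 85%
  CDR3 amino-acid similarity to *every* member, else founds a new clone.
* ``tcell``: T-cell receptors do not hypermutate, so clones require 100%
  CDR3 nucleotide identity (N positions wildcard, consistent with collapse).
* ``lineage``: per (V, J, CDR3-length) bucket, a neighbor-joining lineage is
  built over the members' mutation sets with the germline as the root;
  traversing from the root, the subtree at the first node where the
  accumulated mutation count reaches a budget (default four) becomes a clone.
  Mutations observed in fewer than two bucket members are masked before tree
  construction to suppress sequencing-error noise; unlike the greedy methods
  the result is independent of input order.
"""
from __future__ import annotations

import io
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

from .collapse import UniqueSequence, n_equal

__all__ = [
    "Clone",
    "CloneConfig",
    "ClonePartition",
    "cdr3_aa_similarity",
    "eligibility_filter",
    "infer_clones",
    "infer_similarity",
    "infer_tcell",
    "infer_lineage",
]

log = logging.getLogger(__name__)


@dataclass
class CloneConfig:
    """Parameters of clonal inference."""

    method: str = "similarity"  # similarity | tcell | lineage
    #: minimum subject-level copies for a sequence to be clone-eligible
    min_copies: int = 2
    #: pairwise CDR3 amino-acid similarity required by the similarity method
    similarity_threshold: float = 0.85
    #: mutations accumulated from the germline root before a lineage subtree
    #: is cut into a clone
    mutation_budget: int = 4
    #: a mutation must occur in at least this many bucket members to count in
    #: the lineage tree (masks sequencing-error singletons)
    lineage_min_seqs: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.mutation_budget < 1:
            raise ValueError("mutation_budget must be >= 1")
        if self.method not in ("similarity", "tcell", "lineage"):
            raise ValueError(f"unknown clonal method {self.method!r}")


@dataclass
class Clone:
    """A set of unique sequences inferred to share an ancestral rearrangement."""

    clone_id: int
    subject: str
    v_key: str
    j_key: str
    cdr3_len: int
    members: list[UniqueSequence]

    @property
    def uniques(self) -> int:
        return len(self.members)

    @property
    def copies(self) -> int:
        return sum(m.copies for m in self.members)

    @property
    def instances(self) -> int:
        return sum(m.instances for m in self.members)

    @property
    def consensus_cdr3_aa(self) -> str:
        seqs = [m.cdr3_aa for m in self.members if m.cdr3_aa]
        if not seqs:
            return ""
        length = len(seqs[0])
        out = []
        for i in range(length):
            counts = Counter(s[i] for s in seqs if i < len(s) and s[i] != "X")
            out.append(min(counts, key=lambda c: (-counts[c], c)) if counts else "X")
        return "".join(out)

    @property
    def member_keys(self) -> frozenset:
        """Content-based identity keys of the members (read-provenance sets)."""
        return frozenset(m.member_reads for m in self.members)

    def per_sample_copies(self) -> dict[str, int]:
        out: Counter[str] = Counter()
        for m in self.members:
            out.update(m.per_sample_copies)
        return dict(out)


@dataclass
class ClonePartition:
    """The labeled clone set produced by one inference method."""

    subject: str
    method: str
    clones: list[Clone]

    def assignment(self) -> dict[frozenset, int]:
        """Map member identity key (read-provenance set) -> clone id."""
        out = {}
        for c in self.clones:
            for m in c.members:
                out[m.member_reads] = c.clone_id
        return out

    def clone_sets(self) -> dict[int, frozenset]:
        return {c.clone_id: c.member_keys for c in self.clones}

    def __len__(self) -> int:
        return len(self.clones)


def cdr3_aa_similarity(a: str, b: str) -> float:
    """Fraction of matching positions between equal-length CDR3 amino-acid
    strings.  X (from N-containing codons) is a wildcard and counts as a
    match, consistent with N handling at the nucleotide level."""
    if len(a) != len(b):
        raise ValueError(f"unequal CDR3 lengths: {len(a)} vs {len(b)}")
    if not a:
        return 1.0
    matches = sum(1 for x, y in zip(a, b) if x == y or x == "X" or y == "X")
    return matches / len(a)


def eligibility_filter(
    uniques: Iterable[UniqueSequence], cfg: CloneConfig | None = None
) -> list[UniqueSequence]:
    """Keep sequences with enough copies to be clone-eligible."""
    cfg = cfg or CloneConfig()
    uniques = list(uniques)
    kept = [u for u in uniques if u.copies >= cfg.min_copies]
    removed = len(uniques) - len(kept)
    if removed:
        log.info("eligibility filter removed %d of %d sequences", removed, len(uniques))
    if not kept and uniques:
        log.warning("no sequences are clone-eligible (all copies < %d)", cfg.min_copies)
    return kept


def _v_key(u: UniqueSequence) -> str:
    return ",".join(sorted(u.annotation.v_ties))


def _j_key(u: UniqueSequence) -> str:
    return ",".join(sorted(u.annotation.j_ties))


def _subject_of(uniques: Sequence[UniqueSequence]) -> str:
    subjects = {u.subject for u in uniques}
    if len(subjects) > 1:
        raise ValueError(f"uniques span multiple subjects: {sorted(subjects)}")
    return subjects.pop() if subjects else ""


def _sorted_by_copies(uniques: Iterable[UniqueSequence]) -> list[UniqueSequence]:
    return sorted(uniques, key=lambda u: (-u.copies, u.representative))


# ----------------------------------------------------------------------------
# similarity method (B cells)
# ----------------------------------------------------------------------------

def infer_similarity(
    uniques: Sequence[UniqueSequence], cfg: CloneConfig | None = None
) -> ClonePartition:
    """Greedy CDR3 amino-acid similarity clustering in decreasing copy order.

    A sequence joins the earliest-founded clone with matching V key, J key and
    CDR3 length in which it is at least ``similarity_threshold`` similar to
    every current member; otherwise it founds a new clone.  CDR3s that do not
    translate (length not divisible by 3) fall back to exact N-tolerant
    nucleotide identity.
    """
    cfg = cfg or CloneConfig(method="similarity")
    subject = _subject_of(uniques)
    clones: list[tuple[tuple, list[UniqueSequence]]] = []
    for u in _sorted_by_copies(uniques):
        key = (_v_key(u), _j_key(u), len(u.cdr3_nt))
        placed = False
        for ckey, members in clones:
            if ckey != key:
                continue
            if u.cdr3_aa:
                ok = all(
                    m.cdr3_aa
                    and cdr3_aa_similarity(u.cdr3_aa, m.cdr3_aa)
                    >= cfg.similarity_threshold
                    for m in members
                )
            else:
                ok = all(n_equal(u.cdr3_nt, m.cdr3_nt) for m in members)
            if ok:
                members.append(u)
                placed = True
                break
        if not placed:
            clones.append((key, [u]))
    return _build_partition(subject, "similarity", clones)


# ----------------------------------------------------------------------------
# T-cell method
# ----------------------------------------------------------------------------

def infer_tcell(
    uniques: Sequence[UniqueSequence], cfg: CloneConfig | None = None
) -> ClonePartition:
    """Group by V key, J key and 100% CDR3 nucleotide identity.

    N positions match any base (greedy in decreasing copy order against clone
    founders, as in collapsing); with N-free CDR3s this is exactly a group-by
    on (V key, J key, CDR3 sequence).
    """
    subject = _subject_of(uniques)
    clones: list[tuple[tuple, list[UniqueSequence]]] = []
    for u in _sorted_by_copies(uniques):
        key = (_v_key(u), _j_key(u), len(u.cdr3_nt))
        placed = False
        for (ckey, members) in clones:
            if ckey == key and n_equal(u.cdr3_nt, members[0].cdr3_nt):
                members.append(u)
                placed = True
                break
        if not placed:
            clones.append((key, [u]))
    return _build_partition(subject, "tcell", clones)


# ----------------------------------------------------------------------------
# lineage-separation method
# ----------------------------------------------------------------------------

def _bucket_mutation_sets(
    members: Sequence[UniqueSequence], min_seqs: int
) -> list[frozenset]:
    """Per-member mutation sets vs the bucket germline scaffold.

    V mutations come from annotation (positions in the shared germline frame);
    CDR3 mutations are differences from the bucket's majority-consensus CDR3.
    Mutations seen in fewer than ``min_seqs`` members are masked as likely
    sequencing error.  Substitutions carried by *every* member are treated as
    reference (undetected allele) differences rather than somatic mutations:
    they carry no lineage signal and would otherwise exhaust the mutation
    budget before any branching occurs.
    """
    cdr3s = [m.cdr3_nt for m in members]
    length = len(cdr3s[0]) if cdr3s else 0
    consensus = []
    for i in range(length):
        counts = Counter(s[i] for s in cdr3s if s[i] != "N")
        consensus.append(min(counts, key=lambda c: (-counts[c], c)) if counts else "N")
    sets = []
    for m in members:
        muts = {("v", pos, base) for pos, base in m.annotation.v_mutations}
        for i, base in enumerate(m.cdr3_nt):
            if base != "N" and consensus[i] != "N" and base != consensus[i]:
                muts.add(("c", i, base))
        sets.append(muts)
    counts: Counter = Counter()
    for s in sets:
        counts.update(s)
    threshold = min(min_seqs, len(members))
    n = len(members)
    return [
        frozenset(x for x in s if threshold <= counts[x] and (n == 1 or counts[x] < n))
        for s in sets
    ]


def _nj_root_and_cut(
    sets: Sequence[frozenset], budget: int
) -> list[list[int]]:
    """Cut a germline-rooted NJ lineage into clones by mutation budget.

    Returns groups of member indices.  The tree is built on symmetric
    difference distances with an all-germline (empty set) outgroup; internal
    nodes take parsimony-reconstructed mutation states (per-mutation Fitch,
    ambiguities resolved toward the parent so deep nodes stay germline-like);
    traversal from the root cuts the subtree at the first node whose
    accumulated mutation count reaches the budget.  Members above every cut
    point form one residual clone.
    """
    n = len(sets)
    if n == 1:
        return [[0]]
    labels = ["g"] + [f"m{i}" for i in range(n)]
    all_sets = [frozenset()] + list(sets)
    buf = io.StringIO()
    buf.write("x," + ",".join(labels) + "\n")
    for i, a in enumerate(all_sets):
        row = [str(len(a ^ b)) for b in all_sets]
        buf.write(labels[i] + "," + ",".join(row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    tree = pdm.nj_tree()
    gnode = tree.find_node_with_taxon_label("g")
    tree.reroot_at_edge(gnode.edge, update_bipartitions=False)

    def leaf_indices(node) -> list[int]:
        return [
            int(lf.taxon.label[1:])
            for lf in node.leaf_iter()
            if lf.taxon.label != "g"
        ]

    def leaf_set(node) -> frozenset:
        if node.taxon.label == "g":
            return frozenset()
        return all_sets[int(node.taxon.label[1:]) + 1]

    # Fitch bottom-up: per node, mutations definitely present / ambiguous
    fitch: dict = {}

    def fitch_up(node) -> tuple[frozenset, frozenset]:
        if node.is_leaf():
            state = (leaf_set(node), frozenset())
        else:
            children = [fitch_up(ch) for ch in node.child_nodes()]
            present, maybe = children[0]
            for p2, m2 in children[1:]:
                universe = present | maybe | p2 | m2
                new_p, new_m = set(), set()
                for mut in universe:
                    s1 = 1 if mut in present else (2 if mut in maybe else 0)
                    s2 = 1 if mut in p2 else (2 if mut in m2 else 0)
                    pair = {s1, s2}
                    if pair == {1} or pair == {1, 2}:
                        new_p.add(mut)
                    elif pair == {0, 1} or pair == {2}:
                        new_m.add(mut)
                    # 0/0 and 0/2 resolve to absent
                present, maybe = frozenset(new_p), frozenset(new_m)
            state = (present, maybe)
        fitch[id(node)] = state
        return state

    groups: list[list[int]] = []
    residual: list[int] = []

    def walk(node, parent_set: frozenset, cum: int) -> None:
        present, maybe = fitch[id(node)]
        # ambiguous states resolve toward the parent (germline at the root)
        s = present | (maybe & parent_set)
        cum = cum + len(s ^ parent_set)
        if cum >= budget:
            idx = leaf_indices(node)
            if idx:
                groups.append(sorted(idx))
            return
        if node.is_leaf():
            residual.extend(leaf_indices(node))
            return
        for ch in node.child_nodes():
            walk(ch, s, cum)

    root = tree.seed_node
    for ch in root.child_nodes():
        if ch.is_leaf() and ch.taxon is not None and ch.taxon.label == "g":
            continue
        fitch_up(ch)
        walk(ch, frozenset(), 0)
    if residual:
        groups.append(sorted(residual))
    return groups


def infer_lineage(
    uniques: Sequence[UniqueSequence], cfg: CloneConfig | None = None
) -> ClonePartition:
    """Lineage-separation clonal inference (order-agnostic).

    Sequences are bucketed by V key, J key and CDR3 length; a germline-rooted
    neighbor-joining lineage is built per bucket and cut where the mutation
    count accumulated from the root reaches ``mutation_budget``.
    """
    cfg = cfg or CloneConfig(method="lineage")
    subject = _subject_of(uniques)
    buckets: dict[tuple, list[UniqueSequence]] = defaultdict(list)
    for u in uniques:
        buckets[(_v_key(u), _j_key(u), len(u.cdr3_nt))].append(u)
    clones: list[tuple[tuple, list[UniqueSequence]]] = []
    for key in sorted(buckets, key=repr):
        members = sorted(buckets[key], key=lambda u: u.representative)
        sets = _bucket_mutation_sets(members, cfg.lineage_min_seqs)
        for group in _nj_root_and_cut(sets, cfg.mutation_budget):
            clones.append((key, [members[i] for i in group]))
    return _build_partition(subject, "lineage", clones)


# ----------------------------------------------------------------------------
# shared
# ----------------------------------------------------------------------------

def _build_partition(
    subject: str, method: str, raw: Sequence[tuple[tuple, list[UniqueSequence]]]
) -> ClonePartition:
    clones = []
    for i, (key, members) in enumerate(raw, start=1):
        v_key, j_key, cdr3_len = key
        clones.append(
            Clone(
                clone_id=i,
                subject=subject,
                v_key=v_key,
                j_key=j_key,
                cdr3_len=cdr3_len,
                members=list(members),
            )
        )
    return ClonePartition(subject=subject, method=method, clones=clones)


def infer_clones(
    uniques: Sequence[UniqueSequence], cfg: CloneConfig
) -> ClonePartition:
    """Dispatch to the configured clonal-inference method, applying the
    eligibility filter first."""
    eligible = eligibility_filter(uniques, cfg)
    if cfg.method == "similarity":
        return infer_similarity(eligible, cfg)
    if cfg.method == "tcell":
        return infer_tcell(eligible, cfg)
    return infer_lineage(eligible, cfg)
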