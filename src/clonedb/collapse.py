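"""N-tolerant multi-level sequence collapsing.

Reads are deduplicated at two levels.  Within a sample, sequences differing
only at N positions (bases masked for low quality) collapse into sample-level
unique sequences carrying a copy number.  Across all samples of one subject,
sample-level uniques collapse again into subject-level unique sequences, each
carrying *copies* (total duplicates across samples) and *instances* (number of
samples it occurred in — a lower bound on the number of contributing cells
when samples are biologically independent).

N-equality is not transitive, so chains are resolved by a deterministic greedy
pass: candidates are visited in order of decreasing copy number (ties broken
lexicographically) and merged into the first earlier-founded group whose
founding sequence they N-match.  Only sequences with identical V-tie sets,
J-tie sets and aligned length are ever compared; differing tie sets keep
sequences apart.  The representative of a group is the member with the fewest
N symbols (tie: highest copy, then lexicographic order).
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotate import IDENTIFIED, AnnotatedSequence

__all__ = [
    "n_equal",
    "SampleUnique",
    "UniqueSequence",
    "collapse_sample",
    "collapse_subject",
]


def n_equal(a: str, b: str) -> bool:
    """True iff the sequences match at every position, treating N as a
    wildcard.  Unequal lengths never collapse (different rearrangement
    frames), so they compare unequal rather than raising."""
    if len(a) != len(b):
        return False
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


@dataclass
class SampleUnique:
    """A sample-level unique sequence with its within-sample copy number."""

    sample: str
    sequence: str
    copy_number: int
    read_ids: tuple[str, ...]
    annotation: AnnotatedSequence

    @property
    def collapse_key(self) -> tuple:
        return self.annotation.collapse_key


@dataclass
class UniqueSequence:
    """A subject-level unique sequence (Table-of-terms semantics).

    ``copies``  — total duplicates across all samples of the subject;
    ``instances`` — number of samples the sequence occurred in.
    """

    subject: str
    representative: str
    member_reads: frozenset[tuple[str, str]]  # (sample, read_id)
    per_sample_copies: Mapping[str, int]
    annotation: AnnotatedSequence

    @property
    def copies(self) -> int:
        return sum(self.per_sample_copies.values())

    @property
    def instances(self) -> int:
        return sum(1 for v in self.per_sample_copies.values() if v > 0)

    @property
    def collapse_key(self) -> tuple:
        return self.annotation.collapse_key

    @property
    def cdr3_nt(self) -> str:
        return self.annotation.cdr3_nt

    @property
    def cdr3_aa(self) -> str:
        return self.annotation.cdr3_aa


def _pick_representative(members: Sequence[tuple[str, int]]) -> str:
    """Fewest Ns, tie -> highest copy, tie -> lexicographic."""
    return min(members, key=lambda m: (m[0].count("N"), -m[1], m[0]))[0]


def collapse_sample(anns: Iterable[AnnotatedSequence]) -> list[SampleUnique]:
    """Collapse the identified reads of one sample into unique sequences.

    Exact duplicates are merged first; the resulting distinct sequences are
    then N-tolerantly merged by the greedy decreasing-copy pass.  Copy numbers
    are conserved: the output copies sum to the input read count.
    """
    anns = [a for a in anns if a.status == IDENTIFIED]
    samples = {a.sample for a in anns}
    if len(samples) > 1:
        raise ValueError(f"reads from multiple samples: {sorted(samples)}")
    buckets: dict[tuple, dict[str, list]] = defaultdict(dict)
    for a in anns:
        entry = buckets[a.collapse_key].setdefault(a.sequence, [0, [], a])
        entry[0] += a.copy_number
        entry[1].append(a.read_id)
    out: list[SampleUnique] = []
    for key in sorted(buckets, key=repr):
        seqs = buckets[key]
        groups: list[list[str]] = []  # member sequences; [0] is the founder
        order = sorted(seqs, key=lambda s: (-seqs[s][0], s))
        for s in order:
            for g in groups:
                if n_equal(s, g[0]):
                    g.append(s)
                    break
            else:
                groups.append([s])
        for g in groups:
            members = [(s, seqs[s][0]) for s in g]
            rep = _pick_representative(members)
            read_ids = tuple(rid for s in g for rid in seqs[s][1])
            out.append(
                SampleUnique(
                    sample=next(iter(samples)) if samples else "",
                    sequence=rep,
                    copy_number=sum(c for _, c in members),
                    read_ids=read_ids,
                    annotation=seqs[rep][2],
                )
            )
    return out


def collapse_subject(
    sample_uniques: Iterable[SampleUnique], subject: str
) -> list[UniqueSequence]:
    """Collapse sample-level uniques of one subject across its samples.

    The same greedy N-tolerant merge is applied across samples; each output
    carries per-sample copy counts, total copies and instances.  Copies are
    conserved relative to the input.
    """
    items = list(sample_uniques)
    buckets: dict[tuple, list[SampleUnique]] = defaultdict(list)
    for u in items:
        buckets[u.collapse_key].append(u)
    out: list[UniqueSequence] = []
    for key in sorted(buckets, key=repr):
        members = sorted(
            buckets[key], key=lambda u: (-u.copy_number, u.sequence, u.sample)
        )
        groups: list[list[SampleUnique]] = []
        for u in members:
            for g in groups:
                if n_equal(u.sequence, g[0].sequence):
                    g.append(u)
                    break
            else:
                groups.append([u])
        for g in groups:
            per_sample: Counter[str] = Counter()
            reads = set()
            for u in g:
                per_sample[u.sample] += u.copy_number
                reads.update((u.sample, rid) for rid in u.read_ids)
            rep = _pick_representative([(u.sequence, u.copy_number) for u in g])
            rep_u = next(u for u in g if u.sequence == rep)
            out.append(
                UniqueSequence(
                    subject=subject,
                    representative=rep,
                    member_reads=frozenset(reads),
                    per_sample_copies=dict(per_sample),
                    annotation=rep_u.annotation,
                )
            )
    return out
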