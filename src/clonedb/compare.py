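"""Clone-partition comparison by sequence-set relations.

Given two clone partitions drawn from a shared sequence universe (sequences
matched by content, not by internal ids), every clone is labeled against the
other partition:

* *identical* — some clone of the other partition holds exactly the same
  sequences (symmetric: identical counts match on both sides);
* *superset* / *subset* — a strict superset/subset of some other-side clone;
* *intersecting* — a nonempty proper overlap with some other-side clone;
* *disjoint* — shares no sequence with any other-side clone.

A clone can carry several labels at once (e.g. superset of one clone while
intersecting another); the report exposes both the per-label tallies and the
multi-label profile counts.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping

from .clones import ClonePartition

__all__ = ["CloneLabelReport", "label_partitions"]

LABELS = ("identical", "subset", "superset", "intersecting", "disjoint")


@dataclass
class CloneLabelReport:
    """Per-clone label sets for both partitions plus summary tallies."""

    labels_a: dict[Hashable, frozenset[str]]
    labels_b: dict[Hashable, frozenset[str]]

    def counts(self, side: str = "a") -> Counter:
        """Number of clones carrying each label (a clone may count toward
        several labels)."""
        labels = self.labels_a if side == "a" else self.labels_b
        out: Counter = Counter()
        for ls in labels.values():
            out.update(ls)
        return out

    def profile_counts(self, side: str = "a") -> Counter:
        """Number of clones per exact label combination (exclusive rows)."""
        labels = self.labels_a if side == "a" else self.labels_b
        return Counter(" & ".join(sorted(ls)) for ls in labels.values())

    def summary(self) -> dict[str, dict[str, int]]:
        return {
            "a": {k: self.counts("a").get(k, 0) for k in LABELS},
            "b": {k: self.counts("b").get(k, 0) for k in LABELS},
        }


def _as_sets(p) -> dict[Hashable, frozenset]:
    if isinstance(p, ClonePartition):
        return {cid: s for cid, s in p.clone_sets().items()}
    return {cid: frozenset(s) for cid, s in dict(p).items()}


def _label_side(
    ours: Mapping[Hashable, frozenset], theirs: Mapping[Hashable, frozenset]
) -> dict[Hashable, frozenset[str]]:
    out = {}
    for cid, a in ours.items():
        labels = set()
        for b in theirs.values():
            inter = a & b
            if not inter:
                continue
            if a == b:
                labels.add("identical")
            elif inter == b:
                labels.add("superset")
            elif inter == a:
                labels.add("subset")
            else:
                labels.add("intersecting")
        if not labels:
            labels.add("disjoint")
        out[cid] = frozenset(labels)
    return out


def label_partitions(p, q) -> CloneLabelReport:
    """Label every clone of partition ``p`` against partition ``q`` and vice
    versa.

    Partitions may be :class:`~clonedb.clones.ClonePartition` objects (members
    matched by read-provenance sets) or plain mappings of clone id to a set of
    hashable sequence keys.
    """
    a, b = _as_sets(p), _as_sets(q)
    if not a or not b:
        warnings.warn("comparing against an empty partition; all clones disjoint")
    return CloneLabelReport(
        labels_a=_label_side(a, b),
        labels_b=_label_side(b, a),
    )
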