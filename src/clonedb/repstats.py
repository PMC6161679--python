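"""Aggregate repertoire statistics.

Implements the standard descriptive layer over a clone partition: Hill-number
diversity profiles, incidence-based rarefaction with extrapolation past the
observed number of replicates, pairwise clonal overlap between samples as
cosine similarity, and clone-size distributions measured either as copies or
as instances.

The diversity of order ``q`` is ``(sum_i p_i^q)^(1/(1-q))`` where ``p_i`` is
the fraction of the repertoire (copies or instances) in clone ``i``; order 0
is richness, order 1 is evaluated as the Shannon limit ``exp(-sum p ln p)``,
and increasing order weights large clones more heavily.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clones import Clone, ClonePartition

__all__ = [
    "AbundanceVector",
    "DiversityProfile",
    "diversity",
    "diversity_profile",
    "cosine_overlap",
    "rarefaction",
    "rarefaction_curve",
    "clone_size_distribution",
    "clone_instance_filter",
    "partition_abundance",
    "sample_abundance_vectors",
    "overlap_matrix",
]


@dataclass
class AbundanceVector:
    """Per-clone abundances (copies or instances), possibly for one sample."""

    clone_ids: tuple[int, ...]
    values: tuple[int, ...]
    measure: str = "copies"  # copies | instances

    def __post_init__(self) -> None:
        if len(self.clone_ids) != len(self.values):
            raise ValueError("clone_ids and values must have equal length")
        if any(v < 0 for v in self.values):
            raise ValueError("abundances must be non-negative")


@dataclass
class DiversityProfile:
    orders: tuple[float, ...]
    values: tuple[float, ...]


def _values(v) -> np.ndarray:
    arr = np.asarray(getattr(v, "values", v), dtype=float)
    if arr.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    return arr


def diversity(v, q: float) -> float:
    """Hill diversity of order ``q`` (effective number of clones).

    Order 0 returns richness; order 1 is evaluated exactly as the Shannon
    limit rather than near-1 interpolation.
    """
    if q < 0:
        raise ValueError("order q must be >= 0")
    arr = _values(v)
    total = arr.sum()
    if total <= 0:
        raise ValueError("abundance vector has no positive entries")
    p = arr[arr > 0] / total
    if q == 0:
        return float(len(p))
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def diversity_profile(v, orders: Sequence[float]) -> DiversityProfile:
    return DiversityProfile(
        orders=tuple(orders), values=tuple(diversity(v, q) for q in orders)
    )


def cosine_overlap(a, b) -> float:
    """Cosine similarity between two per-clone abundance vectors indexed over
    the same clone universe; 1 iff proportional, 0 iff disjoint support."""
    x, y = _values(a), _values(b)
    if len(x) != len(y):
        raise ValueError("vectors must be indexed over the same clone universe")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine overlap undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def rarefaction(incidence: Sequence[int], k: int, n_samples: int | None = None) -> float:
    """Expected clone richness when only ``k`` of ``S`` replicates are drawn.

    ``incidence`` holds, per clone, the number of replicates it occurred in
    (its instances).  For ``k <= S`` the closed-form hypergeometric
    interpolation is exact: each clone is detected unless all ``k`` drawn
    replicates miss it.  For ``k > S`` richness is extrapolated with a Chao2
    estimate of the undetected clone count from the singleton/doubleton
    incidence frequencies.
    """
    s = [int(x) for x in incidence]
    if k < 1:
        raise ValueError("subsample size k must be >= 1")
    S = int(n_samples) if n_samples is not None else (max(s) if s else 0)
    if S < 1:
        raise ValueError("at least one replicate is required")
    if any(x < 0 or x > S for x in s):
        raise ValueError("incidence counts must lie in [0, S]")
    s = [x for x in s if x > 0]
    R = len(s)
    if k <= S:
        denom = math.comb(S, k)
        return float(
            sum(1.0 - math.comb(S - si, k) / denom for si in s)
        )
    q1 = sum(1 for x in s if x == 1)
    q2 = sum(1 for x in s if x == 2)
    if q1 == 0:
        return float(R)
    if q2 > 0:
        q0 = (S - 1) / S * q1 * q1 / (2.0 * q2)
    else:
        q0 = (S - 1) / S * q1 * (q1 - 1) / 2.0
    if q0 <= 0:
        return float(R)
    m = k - S
    return float(R + q0 * (1.0 - (1.0 - q1 / (S * q0 + q1)) ** m))


def rarefaction_curve(
    incidence: Sequence[int], ks: Sequence[int], n_samples: int | None = None
) -> list[tuple[int, float]]:
    return [(k, rarefaction(incidence, k, n_samples)) for k in ks]


def _clone_size(c: Clone, measure: str) -> int:
    if measure == "copies":
        return c.copies
    if measure == "instances":
        return c.instances
    raise ValueError(f"unknown size measure {measure!r}")


def clone_size_distribution(partition, measure: str = "copies") -> dict[int, int]:
    """Histogram mapping clone size to the number of clones of that size."""
    if isinstance(partition, ClonePartition):
        sizes = [_clone_size(c, measure) for c in partition.clones]
    else:
        sizes = [int(x) for x in partition]
    return dict(Counter(sizes))


def clone_instance_filter(
    partition: ClonePartition, min_instances: int
) -> ClonePartition:
    """Retain clones with at least ``min_instances`` instances."""
    return ClonePartition(
        subject=partition.subject,
        method=partition.method,
        clones=[c for c in partition.clones if c.instances >= min_instances],
    )


def clone_copy_filter(partition: ClonePartition, min_copies: int) -> ClonePartition:
    """Retain clones with at least ``min_copies`` total copies."""
    return ClonePartition(
        subject=partition.subject,
        method=partition.method,
        clones=[c for c in partition.clones if c.copies >= min_copies],
    )


def partition_abundance(
    partition: ClonePartition, measure: str = "copies"
) -> AbundanceVector:
    """Whole-repertoire abundance vector of a partition."""
    return AbundanceVector(
        clone_ids=tuple(c.clone_id for c in partition.clones),
        values=tuple(_clone_size(c, measure) for c in partition.clones),
        measure=measure,
    )


def sample_abundance_vectors(
    partition: ClonePartition, samples: Sequence[str] | None = None
) -> dict[str, AbundanceVector]:
    """Per-sample clone copy vectors over the full clone universe of the
    partition (suitable inputs to :func:`cosine_overlap`)."""
    per_clone = [(c.clone_id, c.per_sample_copies()) for c in partition.clones]
    if samples is None:
        samples = sorted({s for _, psc in per_clone for s in psc})
    ids = tuple(cid for cid, _ in per_clone)
    return {
        s: AbundanceVector(
            clone_ids=ids,
            values=tuple(psc.get(s, 0) for _, psc in per_clone),
            measure="copies",
        )
        for s in samples
    }


def overlap_matrix(
    partition: ClonePartition, samples: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Pairwise cosine clonal-overlap matrix between samples."""
    vecs = sample_abundance_vectors(partition, samples)
    names = sorted(vecs)
    n = len(names)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = cosine_overlap(vecs[names[i]], vecs[names[j]])
    return names, out
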