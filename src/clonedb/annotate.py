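"""Anchor-based V/J germline assignment.

The assignment strategy avoids full local alignment: each read is positioned
against the IMGT frame using two conserved landmarks.  The J segment is found
first by scanning the read for a W/F-G-X-G anchor motif; every germline J is
then compared over the shared post-anchor window by Hamming distance and the
closest gene(s) become the J call.  The V segment is positioned by locating
the conserved Cys-104 anchor context upstream of the J anchor, after which
each germline V is compared over the full overlapping window.  Germlines whose
distance is statistically indistinguishable from the best one are retained as
"gene-ties", so a read may carry several V or J calls.

Reads without a J anchor, without a V anchor, or with overall V-germline
identity below a configurable floor (default 60%) are marked unidentifiable.
Reads containing a 30-nt window of less than 60% germline identity are flagged
as potential insertion/deletion carriers and excluded from clonal analysis.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .germline import GermlineGene, GermlineSet, family_of, motif_matches

__all__ = [
    "SampleMetadata",
    "AnnotatedSequence",
    "AnnotationConfig",
    "hamming",
    "assign_j",
    "assign_v",
    "qc_flags",
    "annotate_read",
    "annotate_sample",
    "comparison_filter",
    "translate_nt",
]

log = logging.getLogger(__name__)

IDENTIFIED = "identified"
UNIDENTIFIABLE = "unidentifiable"
POTENTIAL_INDEL = "potential_indel"


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample metadata: a unique sample name, the subject (source organism)
    it came from, and free-form keys (tissue, cell subset, ...)."""

    sample_name: str
    subject: str
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_name:
            raise ValueError("sample_name must be non-empty")
        if not self.subject:
            raise ValueError(f"sample {self.sample_name!r}: subject must be non-empty")


@dataclass
class AnnotationConfig:
    """Tunable parameters of the anchoring method."""

    #: overall V-germline identity floor below which a read is unidentifiable
    min_similarity: float = 0.60
    #: sliding window length for insertion/deletion detection (nt)
    indel_window: int = 30
    #: identity floor within the sliding window
    indel_floor: float = 0.60
    #: gene-tie tolerance scale: genes within max(1, ceil(p_hat*L*tau)) extra
    #: mismatches of the best gene are reported as ties
    tie_tau: float = 0.5
    #: maximum CDR3 span searched between the V and J anchors (nt)
    max_cdr3_length: int = 99
    #: mismatches tolerated when locating the 9-nt V anchor context in a read
    max_v_anchor_mismatches: int = 2
    #: minimum compared V positions for an assignment to count
    min_v_overlap: int = 30


@dataclass(frozen=True)
class AnnotatedSequence:
    """One read after V/J assignment.

    Coordinates are 0-based, half-open, on the read.  ``v_align_start`` is the
    germline (ungapped V frame) position corresponding to read position 0.
    ``v_mutations`` holds (germline-frame position, read base) pairs relative
    to the lexicographically first allele of the V tie set, enabling
    position-comparable mutation sets across reads of one subject.
    """

    read_id: str
    sample: str
    sequence: str
    status: str = UNIDENTIFIABLE
    v_ties: tuple[str, ...] = ()
    j_ties: tuple[str, ...] = ()
    v_align_start: int = 0
    cdr3_start: int = 0
    cdr3_end: int = 0
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    v_identity: float = 0.0
    mutation_fraction: float = 0.0
    v_length: int = 0
    copy_number: int = 1
    v_mutations: tuple[tuple[int, str], ...] = ()
    mismatch_profile: tuple[bool, ...] = ()

    @property
    def junction_nt(self) -> str:
        """CDR3 plus the conserved anchor codons (AIRR junction convention)."""
        if self.status != IDENTIFIED:
            return ""
        start = self.cdr3_start - 3
        end = self.cdr3_end + 3
        if start < 0 or end > len(self.sequence):
            return ""
        return self.sequence[start:end]

    @property
    def collapse_key(self) -> tuple:
        return (self.v_ties, self.j_ties, len(self.sequence))

    def to_dict(self) -> dict:
        return {
            "read_id": self.read_id,
            "sample": self.sample,
            "sequence": self.sequence,
            "status": self.status,
            "v_ties": list(self.v_ties),
            "j_ties": list(self.j_ties),
            "v_align_start": self.v_align_start,
            "cdr3_start": self.cdr3_start,
            "cdr3_end": self.cdr3_end,
            "cdr3_nt": self.cdr3_nt,
            "cdr3_aa": self.cdr3_aa,
            "v_identity": self.v_identity,
            "mutation_fraction": self.mutation_fraction,
            "v_length": self.v_length,
            "copy_number": self.copy_number,
            "v_mutations": [list(m) for m in self.v_mutations],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnnotatedSequence":
        return cls(
            read_id=d["read_id"],
            sample=d["sample"],
            sequence=d["sequence"],
            status=d["status"],
            v_ties=tuple(d["v_ties"]),
            j_ties=tuple(d["j_ties"]),
            v_align_start=d["v_align_start"],
            cdr3_start=d["cdr3_start"],
            cdr3_end=d["cdr3_end"],
            cdr3_nt=d["cdr3_nt"],
            cdr3_aa=d["cdr3_aa"],
            v_identity=d["v_identity"],
            mutation_fraction=d["mutation_fraction"],
            v_length=d["v_length"],
            copy_number=d["copy_number"],
            v_mutations=tuple((int(p), b) for p, b in d.get("v_mutations", [])),
        )


# ----------------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    """Hamming distance skipping positions where either symbol is N or a gap.

    N marks a base masked for low quality; it carries no evidence for or
    against a mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x not in "N." and y not in "N."
    )


def _compare(a: str, b: str) -> tuple[int, int, tuple[bool, ...]]:
    """(mismatches, compared positions, per-compared-position mismatch flags).

    Positions where either symbol is N or a gap are excluded from comparison.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    profile = []
    mm = 0
    for x, y in zip(a, b):
        if x in "N." or y in "N.":
            continue
        bad = x != y
        mm += bad
        profile.append(bad)
    return mm, len(profile), tuple(profile)


def translate_nt(nt: str) -> str:
    """Standard-code translation; codons containing N translate to X where
    ambiguous.  Returns '' unless the length is divisible by 3."""
    if not nt or len(nt) % 3:
        return ""
    return str(Seq(nt).translate())


def _tie_delta(p_hat: float, length: int, tau: float) -> int:
    """Extra mismatches tolerated for gene-ties, scaled with mutational load."""
    return max(1, math.ceil(p_hat * length * tau))


# ----------------------------------------------------------------------------
# J assignment
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class JAssignment:
    ties: tuple[str, ...]
    anchor_pos: int  # read position of the J anchor motif (CDR3 end)
    distance: int
    compared: int


def assign_j(
    seq: str,
    germlines: GermlineSet,
    *,
    p_hat: float = 0.0,
    tie_tau: float = 0.5,
) -> JAssignment | None:
    """Assign J gene-ties by anchoring on the conserved W/F-G-X-G motif.

    Every motif occurrence in the read is considered; for each germline J the
    post-anchor tail is compared by Hamming distance and the best-scoring
    placement wins.  Returns None when no anchor motif occurs in the read.
    """
    motifs = germlines.j_anchor_motifs
    min_len = min(len(m) for m in motifs)
    hits = [
        t
        for t in range(len(seq) - min_len + 1)
        if any(motif_matches(seq, t, m) for m in motifs)
    ]
    if not hits or not germlines.j_genes:
        return None
    best: dict[str, tuple[int, int, int]] = {}  # name -> (dist, -compared, t)
    for name in sorted(germlines.j_genes):
        gene = germlines.j_genes[name]
        tail = gene.j_tail
        for t in hits:
            window = seq[t : t + len(tail)]
            if len(window) < min_len:
                continue
            mm, comp, _ = _compare(window, tail[: len(window)])
            cand = (mm, -comp, t)
            if name not in best or cand < best[name]:
                best[name] = cand
    if not best:
        return None
    winner = min(best.items(), key=lambda kv: (kv[1], kv[0]))
    w_name, (w_dist, w_neg_comp, w_t) = winner
    delta = _tie_delta(p_hat, -w_neg_comp, tie_tau)
    ties = tuple(sorted(n for n, (d, _, _) in best.items() if d <= w_dist + delta))
    return JAssignment(ties=ties, anchor_pos=w_t, distance=w_dist, compared=-w_neg_comp)


# ----------------------------------------------------------------------------
# V assignment
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class VAssignment:
    ties: tuple[str, ...]
    align_start: int  # germline-frame position of read position 0 (may be <0)
    anchor_end: int  # read position just past the Cys codon (CDR3 start)
    v_identity: float
    distance: int
    compared: int
    mismatch_profile: tuple[bool, ...]
    distances: Mapping[str, tuple[int, int]]  # name -> (dist, compared)


def _v_candidate_sites(
    seq: str,
    j_anchor: int,
    windows: Sequence[str],
    cfg: AnnotationConfig,
) -> dict[str, list[int]]:
    """Candidate read positions of each distinct V anchor context.

    The anchor context must end between the J anchor (zero-length CDR3) and
    ``max_cdr3_length`` nt upstream of it.
    """
    wlen = len(windows[0]) if windows else 0
    lo = max(0, j_anchor - cfg.max_cdr3_length - wlen)
    hi = j_anchor - wlen
    sites: dict[str, list[int]] = {w: [] for w in windows}
    for p in range(lo, hi + 1):
        frag = seq[p : p + wlen]
        for w in windows:
            mm = sum(
                1 for x, y in zip(frag, w) if x != y and x != "N" and y != "N"
            )
            if mm <= cfg.max_v_anchor_mismatches:
                sites[w].append(p)
    return sites


def assign_v(
    seq: str,
    j_result: JAssignment,
    germlines: GermlineSet,
    *,
    p_hat: float = 0.0,
    cfg: AnnotationConfig | None = None,
) -> VAssignment | None:
    """Assign V gene-ties by positioning the read on the Cys-104 anchor.

    Requires a successful J assignment (reads without a J anchor are excluded
    from V assignment).  Returns None when no V anchor context is found.
    """
    cfg = cfg or AnnotationConfig()
    windows = germlines.v_anchor_windows
    if not windows:
        return None
    sites = _v_candidate_sites(seq, j_result.anchor_pos, windows, cfg)
    per_gene: dict[str, tuple[int, int, int, int, tuple[bool, ...]]] = {}
    for name in sorted(germlines.v_genes):
        gene = germlines.v_genes[name]
        gseq = gene.seq
        g_end = gene.anchor_end  # germline position aligned to the anchor end
        best = None
        for p in sites.get(gene.v_anchor_window, ()):  # read anchor start
            read_end = p + len(gene.v_anchor_window)
            g0 = g_end - read_end  # germline position of read[0]
            r_lo = max(0, -g0)
            g_lo = max(0, g0)
            if read_end - r_lo < cfg.min_v_overlap:
                continue
            mm, comp, profile = _compare(
                seq[r_lo:read_end], gseq[g_lo : g_lo + (read_end - r_lo)]
            )
            if comp < cfg.min_v_overlap:
                continue
            cand = (mm, -comp, p, g0, profile)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is not None:
            per_gene[name] = best
    if not per_gene:
        return None
    w_name = min(per_gene, key=lambda n: (per_gene[n][:3], n))
    w_mm, w_neg_comp, w_p, w_g0, w_profile = per_gene[w_name]
    comp = -w_neg_comp
    delta = _tie_delta(p_hat, comp, cfg.tie_tau)
    ties = tuple(
        sorted(n for n, (d, *_rest) in per_gene.items() if d <= w_mm + delta)
    )
    anchor_end = w_p + len(germlines.v_genes[w_name].v_anchor_window)
    return VAssignment(
        ties=ties,
        align_start=w_g0,
        anchor_end=anchor_end,
        v_identity=1.0 - w_mm / comp if comp else 0.0,
        distance=w_mm,
        compared=comp,
        mismatch_profile=w_profile,
        distances={n: (d, -nc) for n, (d, nc, *_r) in per_gene.items()},
    )


# ----------------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------------

def qc_status(
    v_identity: float,
    mismatch_profile: Sequence[bool],
    window: int = 30,
    floor: float = 0.60,
) -> str:
    """Status from overall V identity and the per-position mismatch profile.

    A read is unidentifiable below the overall identity floor; a read with any
    length-``window`` run of compared positions below the floor carries a
    potential insertion or deletion.
    """
    if v_identity < floor:
        return UNIDENTIFIABLE
    n = len(mismatch_profile)
    if n >= window:
        mm = sum(mismatch_profile[:window])
        worst = mm
        for i in range(window, n):
            mm += mismatch_profile[i] - mismatch_profile[i - window]
            worst = max(worst, mm)
        if (window - worst) / window < floor:
            return POTENTIAL_INDEL
    return IDENTIFIED


def qc_flags(
    ann: AnnotatedSequence, window: int = 30, floor: float = 0.60
) -> str:
    """QC status of an annotated read with a putative V alignment."""
    return qc_status(ann.v_identity, ann.mismatch_profile, window, floor)


# ----------------------------------------------------------------------------
# per-read / per-sample annotation
# ----------------------------------------------------------------------------

def _v_mutation_set(
    seq: str, v: VAssignment, ref: GermlineGene
) -> tuple[tuple[int, str], ...]:
    """Mismatch positions (germline frame) vs the tie-set reference allele."""
    g0 = v.align_start
    muts = []
    for r in range(max(0, -g0), v.anchor_end):
        g = g0 + r
        if g >= len(ref.seq):
            break
        a, b = seq[r], ref.seq[g]
        if a != b and a != "N" and b != "N":
            muts.append((g, a))
    return tuple(muts)


def annotate_read(
    read_id: str,
    sample: str,
    seq: str,
    germlines: GermlineSet,
    *,
    cfg: AnnotationConfig | None = None,
    p_hat: float = 0.0,
) -> AnnotatedSequence:
    """Annotate one read; always returns a record with exactly one status."""
    cfg = cfg or AnnotationConfig()
    seq = seq.upper()
    base = AnnotatedSequence(read_id=read_id, sample=sample, sequence=seq)
    j = assign_j(seq, germlines, p_hat=p_hat, tie_tau=cfg.tie_tau)
    if j is None:
        return base
    v = assign_v(seq, j, germlines, p_hat=p_hat, cfg=cfg)
    if v is None:
        return base
    status = qc_status(v.v_identity, v.mismatch_profile, cfg.indel_window, cfg.indel_floor)
    cdr3_start, cdr3_end = v.anchor_end, j.anchor_pos
    cdr3_nt = seq[cdr3_start:cdr3_end]
    ref = germlines.v_genes[v.ties[0]]
    return AnnotatedSequence(
        read_id=read_id,
        sample=sample,
        sequence=seq,
        status=status,
        v_ties=v.ties if status != UNIDENTIFIABLE else (),
        j_ties=j.ties if status != UNIDENTIFIABLE else (),
        v_align_start=v.align_start,
        cdr3_start=cdr3_start,
        cdr3_end=cdr3_end,
        cdr3_nt=cdr3_nt,
        cdr3_aa=translate_nt(cdr3_nt),
        v_identity=v.v_identity,
        mutation_fraction=v.distance / v.compared if v.compared else 0.0,
        v_length=v.compared,
        v_mutations=_v_mutation_set(seq, v, ref) if status == IDENTIFIED else (),
        mismatch_profile=v.mismatch_profile,
    )


def annotate_sample(
    reads: Iterable[tuple[str, str]],
    meta: SampleMetadata,
    germlines: GermlineSet,
    *,
    cfg: AnnotationConfig | None = None,
) -> tuple[list[AnnotatedSequence], dict]:
    """Annotate every read of one sample and summarize.

    ``reads`` is an iterable of (read id, sequence).  Gene-ties depend on the
    sample's mean mutation fraction, so annotation runs in two passes: the
    first estimates the mutational load, the second finalizes tie sets with
    the tolerance scaled to it.  Results are memoized per distinct sequence
    (duplicate reads are annotated once).
    """
    cfg = cfg or AnnotationConfig()
    reads = list(reads)
    if not reads:
        warnings.warn(f"sample {meta.sample_name!r}: no input reads", stacklevel=2)
        return [], _summary(meta, [])

    def run(p_hat: float) -> list[AnnotatedSequence]:
        cache: dict[str, AnnotatedSequence] = {}
        out = []
        for rid, seq in reads:
            seq = seq.upper()
            hit = cache.get(seq)
            if hit is None:
                hit = annotate_read(
                    rid, meta.sample_name, seq, germlines, cfg=cfg, p_hat=p_hat
                )
                cache[seq] = hit
            out.append(replace(hit, read_id=rid))
        return out

    first = run(0.0)
    rates = [a.mutation_fraction for a in first if a.status == IDENTIFIED]
    p_hat = sum(rates) / len(rates) if rates else 0.0
    anns = run(p_hat) if p_hat > 0 else first
    summary = _summary(meta, anns)
    log.info(
        "sample %s: %d reads, %d identified, %d unidentifiable, %d potential indel, "
        "mean mutation %.4f, mean length %.1f",
        meta.sample_name,
        summary["n_reads"],
        summary["n_identified"],
        summary["n_unidentifiable"],
        summary["n_potential_indel"],
        summary["mean_mutation_fraction"],
        summary["mean_length"],
    )
    return anns, summary


def _summary(meta: SampleMetadata, anns: Sequence[AnnotatedSequence]) -> dict:
    ident = [a for a in anns if a.status == IDENTIFIED]
    return {
        "sample": meta.sample_name,
        "subject": meta.subject,
        "n_reads": len(anns),
        "n_identified": len(ident),
        "n_unidentifiable": sum(1 for a in anns if a.status == UNIDENTIFIABLE),
        "n_potential_indel": sum(1 for a in anns if a.status == POTENTIAL_INDEL),
        "mean_mutation_fraction": (
            sum(a.mutation_fraction for a in ident) / len(ident) if ident else 0.0
        ),
        "mean_length": (
            sum(len(a.sequence) for a in anns) / len(anns) if anns else 0.0
        ),
    }


def comparison_filter(
    anns: Iterable[AnnotatedSequence],
    germlines: GermlineSet,
    *,
    min_v_length: int = 160,
    min_cdr3: int = 3,
    max_cdr3: int = 96,
) -> list[AnnotatedSequence]:
    """Filter to reads suitable for cross-method comparison.

    Keeps identified reads with at least ``min_v_length`` aligned V bases, a
    CDR3 of 3-96 nt (inclusive), a functional V assignment (no pseudogenes)
    and all V-ties from a single V-gene family.
    """
    out = []
    for a in anns:
        if a.status != IDENTIFIED:
            continue
        if a.v_length < min_v_length:
            continue
        cdr3_len = a.cdr3_end - a.cdr3_start
        if not min_cdr3 <= cdr3_len <= max_cdr3:
            continue
        if not all(germlines.is_functional(t) for t in a.v_ties):
            continue
        if len({family_of(t) for t in a.v_ties}) != 1:
            continue
        out.append(a)
    return out
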