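"""Synthetic repertoire generation with known ground truth.

The generator emulates the data the pipeline is designed for: a subject
sampled through several biologically independent replicates, whose repertoire
consists of expanded clones.  Each clone picks a germline V and J allele,
builds a junction by random nucleotide insertion between the trimmed V anchor
and the J anchor, and acquires somatic hypermutation in two layers — a shared
*trunk* carried by every member (mutations fixed during clonal expansion) and
*private* mutations distinguishing members.  Each member is sequenced as
several raw reads (PCR copies) distributed across the replicate samples, with
per-base sequencing error and N-masking of low-quality calls applied per
read.  Conserved anchor motifs are never mutated: their conservation is the
biological premise of the anchoring method.

Every read is recorded in a truth table (true alleles, clone, member,
mutation load), so parameter-recovery tests need no external data.

The germline sets produced by :func:`synthetic_germline_set` are synthetic:
IMGT-gapped alleles with realistic structure (families, allele variants,
conserved Tyr-Tyr-Cys V anchor and W-G-X-G J anchor, fixed J tails) but
randomly generated sequence content.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import SampleMetadata
from .germline import GAP, GermlineGene, GermlineSet, motif_matches, save_germlines

__all__ = [
    "SimConfig",
    "SimResult",
    "synthetic_germline_set",
    "simulate_repertoire",
    "write_repertoire",
]

_BASES = np.array(list("ACGT"))

#: V architecture: 104 IMGT codons with a 2-codon gap region, ending in the
#: conserved Tyr-Tyr-Cys anchor; a germline CDR3 stub follows the Cys codon.
_V_CODONS = 104
_GAP_CODONS = (60, 61)  # IMGT codons rendered as gaps (missing in all alleles)
_V_ANCHOR_NT = "TATTACTGT"  # Tyr-Tyr-Cys
_J_MOTIFS = ("TGGGG", "TTCGG", "TTTGG")


@dataclass
class SimConfig:
    """Study conditions for one simulated subject.

    ``shm_rate`` is the expected per-base germline divergence of each clone
    member over the germline-templated (non-junction) region; a fraction
    ``trunk_fraction`` of that load is shared by all members of a clone and
    the remainder is private to each member.
    """

    seed: int = 1
    n_clones: int = 20
    members_per_clone: tuple[int, int] = (4, 8)  # uniform inclusive range
    copies_per_member: tuple[int, int] = (2, 6)
    shm_rate: float = 0.03
    trunk_fraction: float = 0.8
    seq_error_rate: float = 0.001
    n_mask_rate: float = 0.002
    n_samples: int = 4
    junction_codons: tuple[int, int] = (6, 15)  # CDR3 of 18..45 nt
    subject: str = "S1"

    def __post_init__(self) -> None:
        for rate in (self.shm_rate, self.seq_error_rate, self.n_mask_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.trunk_fraction <= 1:
            raise ValueError("trunk_fraction must lie in [0, 1]")


@dataclass
class SimResult:
    reads_by_sample: dict[str, list[tuple[str, str]]]
    truth: pd.DataFrame  # one row per read
    metadata: list[SampleMetadata]

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.reads_by_sample.values())


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=3 * n))


def synthetic_germline_set(
    n_families: int = 3,
    alleles_per_family: int = 3,
    n_j: int = 4,
    seed: int = 7,
    *,
    family_divergence: float = 0.25,
    allele_divergence: int = 4,
    include_pseudogene: bool = False,
) -> GermlineSet:
    """Generate a synthetic IMGT-gapped germline V/J set.

    V alleles are grouped into families (~``family_divergence`` mutual
    divergence) with ``allele_divergence`` substitutions between alleles of
    one gene.  All V alleles end in the conserved Tyr-Tyr-Cys anchor at IMGT
    codon 104; all J alleles share a fixed-length tail past the W-G-X-G
    anchor.
    """
    rng = np.random.default_rng(seed)
    n_coding = _V_CODONS - len(_GAP_CODONS)
    v_genes: dict[str, GermlineGene] = {}
    base = None
    for fam in range(1, n_families + 1):
        if base is None:
            body = list(_random_codons(rng, n_coding - 3))
        else:
            body = list(base)
            for i in range(len(body)):
                if rng.random() < family_divergence:
                    body[i] = rng.choice([b for b in "ACGT" if b != body[i]])
        if base is None:
            base = list(body)
        fam_seq = "".join(body) + _V_ANCHOR_NT
        for al in range(1, alleles_per_family + 1):
            seq = list(fam_seq)
            if al > 1:
                # mutate outside the anchor context
                sites = rng.choice(
                    len(seq) - len(_V_ANCHOR_NT), size=allele_divergence, replace=False
                )
                for s in sites:
                    seq[s] = rng.choice([b for b in "ACGT" if b != seq[s]])
            ungapped = "".join(seq)
            gap_at = (_GAP_CODONS[0] - 1) * 3
            gapped = ungapped[:gap_at] + GAP * (3 * len(_GAP_CODONS)) + ungapped[gap_at:]
            name = f"IGHV{fam}-1*{al:02d}"
            v_genes[name] = GermlineGene(
                name=name,
                segment="V",
                gapped_seq=gapped,
                functional=True,
                anchor_pos=len(ungapped) - 3,
            )
    if include_pseudogene:
        name = f"IGHV{n_families + 1}-1*01"
        ungapped = _random_codons(rng, n_coding - 3) + _V_ANCHOR_NT
        gap_at = (_GAP_CODONS[0] - 1) * 3
        gapped = ungapped[:gap_at] + GAP * (3 * len(_GAP_CODONS)) + ungapped[gap_at:]
        v_genes[name] = GermlineGene(
            name=name,
            segment="V",
            gapped_seq=gapped,
            functional=False,
            anchor_pos=len(ungapped) - 3,
        )
    j_genes: dict[str, GermlineGene] = {}
    head_len, tail_len = 15, 30
    for j in range(1, n_j + 1):
        motif = _J_MOTIFS[0]
        while True:
            head = "".join(rng.choice(_BASES, size=head_len))
            tail = "".join(rng.choice(_BASES, size=tail_len))
            seq = head + motif + tail
            # the anchor must be the 5'-most motif occurrence
            spurious = any(
                motif_matches(seq, p, m)
                for p in range(head_len)
                for m in _J_MOTIFS
            )
            if not spurious:
                break
        name = f"IGHJ{j}*01"
        j_genes[name] = GermlineGene(
            name=name,
            segment="J",
            gapped_seq=seq,
            functional=True,
            anchor_pos=head_len,
        )
    return GermlineSet(v_genes=v_genes, j_genes=j_genes, species="synthetic")


def _mutate(
    rng: np.random.Generator,
    seq: list[str],
    rate: float,
    eligible: np.ndarray,
) -> list[int]:
    """Substitute eligible positions independently at ``rate``; returns the
    mutated positions."""
    if rate <= 0 or eligible.size == 0:
        return []
    hits = eligible[rng.random(eligible.size) < rate]
    for pos in hits:
        seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return [int(h) for h in hits]


def simulate_repertoire(cfg: SimConfig, germlines: GermlineSet) -> SimResult:
    """Simulate a repertoire of planted clones with full ground truth.

    Reads are emitted deterministically for a fixed seed.  The number of reads
    equals the sum of planned member copies.
    """
    if not germlines.v_genes or not germlines.j_genes:
        raise ValueError("empty germline set")
    rng = np.random.default_rng(cfg.seed)
    v_names = sorted(germlines.v_genes)
    j_names = sorted(germlines.j_genes)
    samples = [f"{cfg.subject}_rep{i + 1}" for i in range(cfg.n_samples)]
    reads_by_sample: dict[str, list[tuple[str, str]]] = {s: [] for s in samples}
    truth_rows = []
    trunk_rate = cfg.shm_rate * cfg.trunk_fraction
    private_rate = cfg.shm_rate * (1.0 - cfg.trunk_fraction)
    for ci in range(1, cfg.n_clones + 1):
        v = germlines.v_genes[v_names[rng.integers(len(v_names))]]
        j = germlines.j_genes[j_names[rng.integers(len(j_names))]]
        n_junction = 3 * rng.integers(
            cfg.junction_codons[0], cfg.junction_codons[1] + 1
        )
        junction = "".join(rng.choice(_BASES, size=n_junction))
        v_part = v.seq[: v.anchor_end]
        j_part = j.seq[j.anchor_pos :]
        ancestor = v_part + junction + j_part
        # germline-templated positions eligible for SHM: V and J regions minus
        # the conserved anchor contexts
        protected = set(range(len(v_part) - len(_V_ANCHOR_NT), len(v_part)))
        j_start = len(v_part) + n_junction
        protected |= set(range(j_start, j_start + 5))
        eligible = np.array(
            [
                p
                for p in range(len(ancestor))
                if p not in protected and not len(v_part) <= p < j_start
            ]
        )
        trunk_seq = list(ancestor)
        trunk_muts = _mutate(rng, trunk_seq, trunk_rate, eligible)
        n_members = int(
            rng.integers(cfg.members_per_clone[0], cfg.members_per_clone[1] + 1)
        )
        for mi in range(1, n_members + 1):
            member_seq = list(trunk_seq)
            private_muts = _mutate(rng, member_seq, private_rate, eligible)
            member = "".join(member_seq)
            n_copies = int(
                rng.integers(cfg.copies_per_member[0], cfg.copies_per_member[1] + 1)
            )
            member_id = f"c{ci}_m{mi}"
            for ri in range(1, n_copies + 1):
                read = list(member)
                _mutate(rng, read, cfg.seq_error_rate, np.arange(len(read)))
                if cfg.n_mask_rate > 0:
                    mask = rng.random(len(read)) < cfg.n_mask_rate
                    for p in np.flatnonzero(mask):
                        read[p] = "N"
                sample = samples[rng.integers(len(samples))]
                read_id = f"{member_id}_r{ri}"
                reads_by_sample[sample].append((read_id, "".join(read)))
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sample": sample,
                        "clone_id": ci,
                        "member_id": member_id,
                        "v_allele": v.name,
                        "j_allele": j.name,
                        "cdr3_length": int(n_junction),
                        "n_trunk_mutations": len(trunk_muts),
                        "n_private_mutations": len(private_muts),
                        "member_sequence": member,
                    }
                )
    metadata = [
        SampleMetadata(sample_name=s, subject=cfg.subject, extra={"replicate": str(i + 1)})
        for i, s in enumerate(samples)
    ]
    truth = pd.DataFrame(truth_rows)
    return SimResult(reads_by_sample=reads_by_sample, truth=truth, metadata=metadata)


def write_repertoire(
    result: SimResult,
    directory: str | Path,
    germlines: GermlineSet | None = None,
) -> Path:
    """Write a simulated repertoire as per-sample FASTA files plus
    ``metadata.tsv`` and ``truth.tsv`` (and germline FASTAs when given)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample, reads in result.reads_by_sample.items():
        with open(directory / f"{sample}.fasta", "w") as fh:
            for rid, seq in reads:
                fh.write(f">{rid}\n{seq}\n")
    rows = [
        {
            "file_name": f"{m.sample_name}.fasta",
            "sample_name": m.sample_name,
            "subject": m.subject,
            **dict(m.extra),
        }
        for m in result.metadata
    ]
    pd.DataFrame(rows).to_csv(directory / "metadata.tsv", sep="\t", index=False)
    result.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    if germlines is not None:
        save_germlines(germlines.v_genes.values(), directory / "v_germlines.fasta")
        save_germlines(germlines.j_genes.values(), directory / "j_germlines.fasta")
    return directory
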