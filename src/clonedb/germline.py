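"""IMGT-gap-aligned germline V/J reference handling.

Germline genes are loaded from a pair of FASTA files (V genes, J genes) whose
sequences are IMGT gap-aligned: ``.`` characters pad every allele onto the
standardized IMGT codon numbering so that biologically equivalent positions are
directly comparable across alleles.  All downstream anchoring arithmetic relies
on two conserved landmarks:

* the V anchor: the codon of the conserved 2nd-CYS (Cys-104 in IMGT numbering)
  at the 3' end of the V segment, located through its IMGT-gapped position;
* the J anchor: the conserved W/F-G-X-G block of the J segment, located by
  scanning each J for a configurable motif set (default ``TGGGG``, ``TTCGG``,
  ``TTTGG``) and taking the 5'-most hit.

The CDR3 lies between the two anchors (exclusive of both conserved codons).
For the anchoring method to work across alleles, the length of every J gene
past the anchor must be identical; loading fails otherwise.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GermlineGene",
    "GermlineSet",
    "load_germlines",
    "family_of",
    "gene_of",
    "save_germlines",
    "DEFAULT_J_ANCHOR_MOTIFS",
    "DEFAULT_V_ANCHOR_CODON",
]

#: Conserved J motifs encoding the W/F-G-X-G block (Trp-Gly / Phe-Gly codons).
DEFAULT_J_ANCHOR_MOTIFS: tuple[str, ...] = ("TGGGG", "TTCGG", "TTTGG")

#: IMGT codon number of the conserved 2nd-CYS that ends the V segment.
DEFAULT_V_ANCHOR_CODON: int = 104

#: Width of the V anchor context used to position reads (ends at the Cys codon;
#: covers the conserved Tyr-Tyr-Cys block in heavy chains).
V_ANCHOR_LENGTH: int = 9

GAP = "."
_VALID_NT = set("ACGTN")
_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9()/.:-]*(\*[A-Za-z0-9_.]+)?$")


def gene_of(name: str) -> str:
    """Return the gene token of an allele identifier (name without ``*allele``).

    >>> gene_of("IGHV1-2*02")
    'IGHV1-2'
    """
    if not name or not _NAME_RE.match(name):
        raise ValueError(f"unparseable allele name: {name!r}")
    return name.split("*", 1)[0]


def family_of(name: str) -> str:
    """Return the gene family token: the text before the first hyphen.

    >>> family_of("IGHV1-2*02")
    'IGHV1'
    >>> family_of("TRBV20-1*01")
    'TRBV20'
    """
    return gene_of(name).split("-", 1)[0]


def motif_matches(seq: str, pos: int, motif: str) -> bool:
    """True if ``seq[pos:pos+len(motif)]`` equals the motif, treating N as a
    wildcard (a masked base never vetoes a motif hit)."""
    if pos < 0 or pos + len(motif) > len(seq):
        return False
    for a, b in zip(seq[pos : pos + len(motif)], motif):
        if a != b and a != "N":
            return False
    return True


@dataclass(frozen=True)
class GermlineGene:
    """One IMGT-gap-aligned germline V or J allele.

    ``anchor_pos`` is the 0-based position, in the *ungapped* sequence, of the
    start of the conserved anchor: the Cys codon for V genes, the W/F-G-X-G
    motif for J genes.
    """

    name: str
    segment: str  # "V" or "J"
    gapped_seq: str
    functional: bool = True
    anchor_pos: int = -1

    def __post_init__(self) -> None:
        gene_of(self.name)  # validates the grammar
        if self.segment not in ("V", "J"):
            raise ValueError(f"segment must be 'V' or 'J', got {self.segment!r}")
        if not self.gapped_seq:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.seq) - _VALID_NT
        if bad:
            raise ValueError(
                f"{self.name}: invalid nucleotide(s) {sorted(bad)} in sequence"
            )

    @property
    def seq(self) -> str:
        """Ungapped nucleotide sequence."""
        return self.gapped_seq.replace(GAP, "")

    @property
    def family(self) -> str:
        return family_of(self.name)

    @property
    def gene(self) -> str:
        return gene_of(self.name)

    def position_map(self) -> dict[int, int]:
        """Map of gapped position -> ungapped position for every non-gap site.

        The map is a bijection onto ``range(len(self.seq))``.
        """
        out: dict[int, int] = {}
        u = 0
        for g, c in enumerate(self.gapped_seq):
            if c != GAP:
                out[g] = u
                u += 1
        return out

    def gapped_to_ungapped(self, gapped_pos: int) -> int:
        """Ungapped index of a gapped position (which must not be a gap)."""
        if not 0 <= gapped_pos < len(self.gapped_seq):
            raise IndexError(f"{self.name}: gapped position {gapped_pos} out of range")
        if self.gapped_seq[gapped_pos] == GAP:
            raise ValueError(f"{self.name}: position {gapped_pos} is a gap")
        return sum(1 for c in self.gapped_seq[:gapped_pos] if c != GAP)

    # --- anchor geometry -------------------------------------------------
    @property
    def anchor_end(self) -> int:
        """Ungapped end (exclusive) of the anchor: Cys codon end for V genes,
        motif end for J genes."""
        if self.segment == "V":
            return self.anchor_pos + 3
        return self.anchor_pos + 5

    @property
    def v_anchor_window(self) -> str:
        """The anchor context used to position reads against this V gene."""
        if self.segment != "V":
            raise ValueError("v_anchor_window is defined for V genes only")
        return self.seq[self.anchor_end - V_ANCHOR_LENGTH : self.anchor_end]

    @property
    def j_tail(self) -> str:
        """J sequence from the anchor to the 3' end."""
        if self.segment != "J":
            raise ValueError("j_tail is defined for J genes only")
        return self.seq[self.anchor_pos :]


@dataclass
class GermlineSet:
    """A validated collection of germline V and J alleles for one locus."""

    v_genes: dict[str, GermlineGene]
    j_genes: dict[str, GermlineGene]
    species: str = "custom"
    j_anchor_motifs: tuple[str, ...] = DEFAULT_J_ANCHOR_MOTIFS
    v_anchor_codon: int = DEFAULT_V_ANCHOR_CODON

    def __post_init__(self) -> None:
        for name, g in {**self.v_genes, **self.j_genes}.items():
            if name != g.name:
                raise ValueError(f"key {name!r} does not match gene name {g.name!r}")
        dup = set(self.v_genes) & set(self.j_genes)
        if dup:
            raise ValueError(f"allele names shared between V and J sets: {sorted(dup)}")
        self._validate_j_tails()

    def _validate_j_tails(self) -> None:
        tails = {name: len(g.seq) - g.anchor_pos for name, g in self.j_genes.items()}
        if len(set(tails.values())) > 1:
            detail = ", ".join(f"{n}={l}" for n, l in sorted(tails.items()))
            raise ValueError(
                "J genes must have a fixed length past the anchor (3' end of the "
                f"CDR3); got {detail}"
            )

    @property
    def j_tail_length(self) -> int:
        if not self.j_genes:
            raise ValueError("no J genes loaded")
        g = next(iter(self.j_genes.values()))
        return len(g.seq) - g.anchor_pos

    @property
    def v_anchor_windows(self) -> tuple[str, ...]:
        """Distinct V anchor contexts across the loaded alleles."""
        return tuple(sorted({g.v_anchor_window for g in self.v_genes.values()}))

    def functional_only(self) -> "GermlineSet":
        return GermlineSet(
            v_genes={n: g for n, g in self.v_genes.items() if g.functional},
            j_genes={n: g for n, g in self.j_genes.items() if g.functional},
            species=self.species,
            j_anchor_motifs=self.j_anchor_motifs,
            v_anchor_codon=self.v_anchor_codon,
        )

    def is_functional(self, allele: str) -> bool:
        g = self.v_genes.get(allele) or self.j_genes.get(allele)
        return g is not None and g.functional


# ----------------------------------------------------------------------------
# FASTA loading
# ----------------------------------------------------------------------------

def _parse_header(description: str) -> tuple[str, bool | None]:
    """Parse a FASTA header into (allele name, functional or None).

    Accepts IMGT's 16-field ``|``-delimited headers (name in field 2,
    functionality in field 4: F / ORF / P, possibly parenthesized) and bare
    ``>IGHV1-2*02`` headers (functionality unknown -> None).
    """
    if "|" in description:
        fields = description.split("|")
        if len(fields) < 2 or not fields[1].strip():
            raise ValueError(f"malformed IMGT header: {description!r}")
        name = fields[1].strip()
        functional: bool | None = None
        if len(fields) >= 4 and fields[3].strip():
            functional = fields[3].strip().strip("()[]").upper() == "F"
        return name, functional
    name = description.split()[0]
    return name, None


def _check_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: not a FASTA file (line {lineno} does not start "
                        "with '>')"
                    )
                return
    raise ValueError(f"{path}: empty FASTA file")


def _load_fasta(path: str | Path) -> list[tuple[str, bool | None, str]]:
    path = Path(path)
    _check_fasta(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, functional = _parse_header(rec.description)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {name!r} has an empty sequence")
        out.append((name, functional, seq))
    return out


def _v_anchor_from_gaps(name: str, gapped: str, codon: int) -> int:
    """Ungapped position of the conserved Cys codon located via IMGT numbering."""
    g = (codon - 1) * 3
    if g + 3 > len(gapped):
        raise ValueError(
            f"{name}: gapped V sequence too short to contain IMGT codon {codon}"
        )
    codon_seq = gapped[g : g + 3]
    if GAP in codon_seq:
        raise ValueError(f"{name}: IMGT codon {codon} falls on gap positions")
    ungapped = sum(1 for c in gapped[:g] if c != GAP)
    if ungapped < V_ANCHOR_LENGTH - 3:
        raise ValueError(f"{name}: V sequence too short upstream of the anchor")
    return ungapped


def _j_anchor_from_motifs(name: str, seq: str, motifs: Sequence[str]) -> int:
    """5'-most occurrence of any J anchor motif in the ungapped J sequence."""
    for pos in range(len(seq) - min(len(m) for m in motifs) + 1):
        for m in motifs:
            if motif_matches(seq, pos, m):
                return pos
    raise ValueError(f"{name}: no J anchor motif {tuple(motifs)} found")


def load_germlines(
    v_path: str | Path,
    j_path: str | Path,
    functional_only: bool = False,
    *,
    species: str = "custom",
    v_anchor_codon: int = DEFAULT_V_ANCHOR_CODON,
    j_anchor_motifs: Sequence[str] = DEFAULT_J_ANCHOR_MOTIFS,
) -> GermlineSet:
    """Load and validate an IMGT-gap-aligned germline V/J reference pair.

    Parameters
    ----------
    v_path, j_path:
        FASTA files of IMGT-gap-aligned V and J alleles.  Headers may be
        IMGT-style (``|``-delimited) or bare allele names.
    functional_only:
        Drop pseudogenes/ORFs (as flagged in IMGT headers).  When headers carry
        no functionality field, every allele is treated as functional and a
        warning is issued.
    """
    motifs = tuple(j_anchor_motifs)
    genes: dict[str, dict[str, GermlineGene]] = {"V": {}, "J": {}}
    saw_unknown_functionality = False
    for segment, path in (("V", v_path), ("J", j_path)):
        for name, functional, gapped in _load_fasta(path):
            if functional is None:
                saw_unknown_functionality = True
                functional = True
            ungapped = gapped.replace(GAP, "")
            if segment == "V":
                anchor = _v_anchor_from_gaps(name, gapped, v_anchor_codon)
            else:
                anchor = _j_anchor_from_motifs(name, ungapped, motifs)
            gene = GermlineGene(
                name=name,
                segment=segment,
                gapped_seq=gapped,
                functional=functional,
                anchor_pos=anchor,
            )
            if name in genes[segment]:
                raise ValueError(f"duplicate allele name {name!r} in {segment} file")
            genes[segment][name] = gene
    if saw_unknown_functionality:
        warnings.warn(
            "germline headers carry no functionality field; treating all alleles "
            "as functional",
            stacklevel=2,
        )
    gset = GermlineSet(
        v_genes=genes["V"],
        j_genes=genes["J"],
        species=species,
        j_anchor_motifs=motifs,
        v_anchor_codon=v_anchor_codon,
    )
    if functional_only:
        gset = gset.functional_only()
    return gset


def save_germlines(genes: Iterable[GermlineGene], path: str | Path) -> Path:
    """Write germline alleles back to FASTA (lossless on name and sequence)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.name}\n{g.gapped_seq}\n")
    return path
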