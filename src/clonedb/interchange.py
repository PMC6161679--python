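"""Ecosystem interchange: AIRR Rearrangement TSV, Change-O TSV, VDJtools
clonotype tables, FASTA/FASTQ reading and the sample-metadata template.

Gene ties are serialized as comma-joined sorted allele lists in ``v_call`` /
``j_call``.  The exported ``junction`` follows the AIRR convention (CDR3 plus
the conserved Cys and Trp/Phe anchor codons); internally the package works
with the anchor-free CDR3, and conversion happens only at this boundary.
Tables are plain TSV, UTF-8, newline-terminated, with a deterministic column
order per dialect.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .annotate import (
    IDENTIFIED,
    AnnotatedSequence,
    SampleMetadata,
    translate_nt,
)
from .clones import ClonePartition
from .germline import GermlineSet

__all__ = [
    "AIRR_COLUMNS",
    "CHANGEO_COLUMNS",
    "write_metadata_template",
    "read_metadata",
    "read_sequence_file",
    "annotations_to_frame",
    "export_rearrangements",
    "import_rearrangements",
    "export_vdjtools",
    "ImportResult",
]

#: AIRR Rearrangement vocabulary subset used by the package.
AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "duplicate_count",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "v_identity",
    "clone_id",
    "sample",
    "subject",
]

#: Change-O column names for the same content (core set).
_AIRR_TO_CHANGEO = {
    "sequence_id": "SEQUENCE_ID",
    "sequence": "SEQUENCE_INPUT",
    "duplicate_count": "DUPCOUNT",
    "v_call": "V_CALL",
    "j_call": "J_CALL",
    "junction": "JUNCTION",
    "junction_aa": "JUNCTION_AA",
    "v_identity": "V_IDENTITY",
    "clone_id": "CLONE",
    "sample": "SAMPLE",
    "subject": "SUBJECT",
}
CHANGEO_COLUMNS = [_AIRR_TO_CHANGEO[c] for c in AIRR_COLUMNS]
_CHANGEO_TO_AIRR = {v: k for k, v in _AIRR_TO_CHANGEO.items()}

_SEQ_EXTENSIONS = {
    ".fasta": "fasta",
    ".fa": "fasta",
    ".fna": "fasta",
    ".fastq": "fastq",
    ".fq": "fastq",
}


# ----------------------------------------------------------------------------
# sequence files and metadata
# ----------------------------------------------------------------------------

def read_sequence_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA/FASTQ file into (read id, sequence) pairs.  Quality scores
    are ignored beyond any N-masking already applied upstream."""
    path = Path(path)
    fmt = _SEQ_EXTENSIONS.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"unrecognized sequence file extension: {path.name}")
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_metadata_template(
    directory: str | Path, use_filenames: bool = False
) -> Path:
    """Write a ``metadata.tsv`` template for the sequence files in a directory.

    One row per FASTA/FASTQ file with required columns ``sample_name`` and
    ``subject``; with ``use_filenames`` the sample name is pre-filled from the
    filename stripped of its extension.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _SEQ_EXTENSIONS
    )
    if not files:
        raise ValueError(f"no FASTA/FASTQ files found in {directory}")
    stems: dict[str, Path] = {}
    for p in files:
        if p.stem in stems:
            raise ValueError(
                f"duplicate sample basename {p.stem!r}: {stems[p.stem].name} "
                f"and {p.name}"
            )
        stems[p.stem] = p
    rows = [
        {
            "file_name": p.name,
            "sample_name": p.stem if use_filenames else "",
            "subject": "",
        }
        for p in files
    ]
    out = directory / "metadata.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a completed metadata TSV into per-sample metadata records."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample_name", "subject"):
        if col not in df.columns:
            raise ValueError(f"metadata file is missing the {col!r} column")
    extra_cols = [c for c in df.columns if c not in ("sample_name", "subject")]
    out = []
    seen = set()
    for _, row in df.iterrows():
        name = row["sample_name"]
        if name in seen:
            raise ValueError(f"duplicate sample_name {name!r} in metadata")
        seen.add(name)
        out.append(
            SampleMetadata(
                sample_name=name,
                subject=row["subject"],
                extra={c: row[c] for c in extra_cols if row[c]},
            )
        )
    return out


# ----------------------------------------------------------------------------
# rearrangement tables
# ----------------------------------------------------------------------------

def annotations_to_frame(
    anns: Iterable[AnnotatedSequence],
    *,
    subjects: Mapping[str, str] | None = None,
    clone_ids: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """AIRR-vocabulary DataFrame of identified annotations.

    ``subjects`` maps sample name to subject; ``clone_ids`` maps read id to
    clone id (empty when pre-clonal).
    """
    rows = []
    for a in anns:
        if a.status != IDENTIFIED:
            continue
        junction = a.junction_nt
        rows.append(
            {
                "sequence_id": a.read_id,
                "sequence": a.sequence,
                "duplicate_count": a.copy_number,
                "v_call": ",".join(sorted(a.v_ties)),
                "j_call": ",".join(sorted(a.j_ties)),
                "junction": junction,
                "junction_aa": translate_nt(junction),
                "v_identity": round(a.v_identity, 6),
                "clone_id": (
                    clone_ids.get(a.read_id, "") if clone_ids else ""
                ),
                "sample": a.sample,
                "subject": subjects.get(a.sample, "") if subjects else "",
            }
        )
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def export_rearrangements(
    anns: Iterable[AnnotatedSequence],
    path: str | Path,
    dialect: str = "airr",
    *,
    subjects: Mapping[str, str] | None = None,
    clone_ids: Mapping[str, int] | None = None,
    min_copies: int = 1,
) -> Path:
    """Write annotations as an AIRR or Change-O rearrangement TSV."""
    if dialect not in ("airr", "changeo"):
        raise ValueError(f"unknown rearrangement dialect {dialect!r}")
    df = annotations_to_frame(anns, subjects=subjects, clone_ids=clone_ids)
    if min_copies > 1:
        df = df[df["duplicate_count"] >= min_copies]
    if dialect == "changeo":
        df = df.rename(columns=_AIRR_TO_CHANGEO)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class ImportResult:
    annotations: list[AnnotatedSequence]
    rejected: list[tuple[str, str]]  # (sequence_id, reason)


def _detect_dialect(columns: Sequence[str]) -> str:
    if "sequence_id" in columns:
        return "airr"
    if "SEQUENCE_ID" in columns:
        return "changeo"
    raise ValueError(
        "cannot detect rearrangement dialect: neither 'sequence_id' (AIRR) nor "
        "'SEQUENCE_ID' (Change-O) in header"
    )


def import_rearrangements(
    path: str | Path,
    germlines: GermlineSet,
    metadata: Iterable[SampleMetadata],
    *,
    default_sample: str | None = None,
) -> ImportResult:
    """Import a pre-annotated AIRR or Change-O TSV.

    The dialect is autodetected from the header.  Gene calls are split on
    commas into tie sets and validated against the loaded germlines; rows with
    unknown genes or unknown samples are rejected and listed in the report.
    """
    meta = {m.sample_name: m for m in metadata}
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    dialect = _detect_dialect(list(df.columns))
    if dialect == "changeo":
        df = df.rename(columns=_CHANGEO_TO_AIRR)
    mandatory = ["sequence_id", "sequence", "v_call", "j_call", "junction"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    anns: list[AnnotatedSequence] = []
    rejected: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        rid = row["sequence_id"]
        sample = row.get("sample", "") or default_sample or ""
        if sample not in meta:
            raise ValueError(f"row {rid!r}: unknown sample {sample!r}")
        v_ties = tuple(sorted(t for t in row["v_call"].split(",") if t))
        j_ties = tuple(sorted(t for t in row["j_call"].split(",") if t))
        unknown_v = [t for t in v_ties if t not in germlines.v_genes]
        unknown_j = [t for t in j_ties if t not in germlines.j_genes]
        if unknown_v or unknown_j:
            rejected.append(
                (rid, f"unknown gene(s): {','.join(unknown_v + unknown_j)}")
            )
            continue
        seq = row["sequence"].upper()
        junction = row["junction"].upper()
        jpos = seq.find(junction) if junction else -1
        if junction and jpos < 0:
            rejected.append((rid, "junction not found in sequence"))
            continue
        cdr3_start = jpos + 3 if junction else 0
        cdr3_end = jpos + len(junction) - 3 if junction else 0
        cdr3_nt = junction[3:-3] if junction else ""
        v_identity = float(row.get("v_identity") or 1.0)
        anns.append(
            AnnotatedSequence(
                read_id=rid,
                sample=sample,
                sequence=seq,
                status=IDENTIFIED,
                v_ties=v_ties,
                j_ties=j_ties,
                cdr3_start=cdr3_start,
                cdr3_end=cdr3_end,
                cdr3_nt=cdr3_nt,
                cdr3_aa=translate_nt(cdr3_nt),
                v_identity=v_identity,
                mutation_fraction=1.0 - v_identity,
                v_length=cdr3_start,
                copy_number=int(row.get("duplicate_count") or 1),
            )
        )
    return ImportResult(annotations=anns, rejected=rejected)


# ----------------------------------------------------------------------------
# VDJtools clonotype tables
# ----------------------------------------------------------------------------

VDJTOOLS_COLUMNS = ["count", "freq", "cdr3nt", "cdr3aa", "v", "j"]


def export_vdjtools(
    partition: ClonePartition,
    directory: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Aggregate a clone partition into per-sample VDJtools clonotype tables.

    Each sample gets one table of per-clone copy counts and frequencies
    (frequencies sum to 1 per sample).  Tables are returned and, when a
    directory is given, written as ``vdjtools.<sample>.tsv``.
    """
    samples = sorted(
        {s for c in partition.clones for s in c.per_sample_copies()}
    )
    out: dict[str, pd.DataFrame] = {}
    for sample in samples:
        rows = []
        for c in partition.clones:
            count = c.per_sample_copies().get(sample, 0)
            if count <= 0:
                continue
            founder = c.members[0]
            rows.append(
                {
                    "count": count,
                    "freq": 0.0,
                    "cdr3nt": founder.cdr3_nt,
                    "cdr3aa": founder.cdr3_aa,
                    "v": c.v_key,
                    "j": c.j_key,
                }
            )
        df = pd.DataFrame(rows, columns=VDJTOOLS_COLUMNS)
        if len(df):
            df["freq"] = df["count"] / df["count"].sum()
            df = df.sort_values("count", ascending=False, kind="stable")
            df = df.reset_index(drop=True)
        out[sample] = df
        if directory is not None:
            Path(directory).mkdir(parents=True, exist_ok=True)
            df.to_csv(Path(directory) / f"vdjtools.{sample}.tsv", sep="\t", index=False)
    return out
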