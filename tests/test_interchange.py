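"""AIRR/Change-O/VDJtools interchange and the metadata template."""
import pandas as pd
import pytest

from clonedb.annotate import SampleMetadata, annotate_sample
from clonedb.clones import infer_similarity
from clonedb.interchange import (
    AIRR_COLUMNS,
    CHANGEO_COLUMNS,
    export_rearrangements,
    export_vdjtools,
    import_rearrangements,
    read_metadata,
    write_metadata_template,
)


class TestMetadataTemplate:
    def test_use_filenames_strips_extensions(self, tmp_path):
        (tmp_path / "a.fasta").write_text(">r1\nACGT\n")
        (tmp_path / "b.fastq").write_text("@r1\nACGT\n+\nIIII\n")
        out = write_metadata_template(tmp_path, use_filenames=True)
        df = pd.read_csv(out, sep="\t")
        assert list(df["sample_name"]) == ["a", "b"]
        assert {"sample_name", "subject"} <= set(df.columns)

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no FASTA/FASTQ"):
            write_metadata_template(tmp_path)

    def test_duplicate_basenames_error(self, tmp_path):
        (tmp_path / "a.fasta").write_text(">r1\nACGT\n")
        (tmp_path / "a.fastq").write_text("@r1\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="a"):
            write_metadata_template(tmp_path, use_filenames=True)

    def test_roundtrip_through_read_metadata(self, tmp_path):
        (tmp_path / "a.fasta").write_text(">r1\nACGT\n")
        out = write_metadata_template(tmp_path, use_filenames=True)
        df = pd.read_csv(out, sep="\t")
        df["subject"] = "S1"
        df.to_csv(out, sep="\t", index=False)
        meta = read_metadata(out)
        assert meta[0].sample_name == "a" and meta[0].subject == "S1"


@pytest.fixture(scope="module")
def annotated(germlines):
    """A handful of real annotations from clean synthetic reads."""
    meta = SampleMetadata(sample_name="s1", subject="SUBJ")
    reads = []
    for i, vn in enumerate(sorted(germlines.v_genes)[:4]):
        v = germlines.v_genes[vn]
        j = germlines.j_genes[sorted(germlines.j_genes)[i % 2]]
        junction = "GCTAAATTTGGGCCC"[: 3 * (3 + i % 2)]
        reads.append(
            (f"r{i}", v.seq[: v.anchor_end] + junction + j.seq[j.anchor_pos :])
        )
    anns, _ = annotate_sample(reads, meta, germlines)
    return anns


FIELDS = ["sequence_id", "v_call", "j_call", "junction", "junction_aa", "v_identity", "sequence", "duplicate_count"]


def frame_of(anns):
    from clonedb.interchange import annotations_to_frame

    return (
        annotations_to_frame(anns, subjects={"s1": "SUBJ"})[FIELDS]
        .sort_values("sequence_id")
        .reset_index(drop=True)
    )


class TestRoundTrips:
    def test_airr_roundtrip_identity(self, tmp_path, germlines, annotated):
        path = export_rearrangements(
            annotated, tmp_path / "out.tsv", "airr", subjects={"s1": "SUBJ"}
        )
        meta = [SampleMetadata(sample_name="s1", subject="SUBJ")]
        result = import_rearrangements(path, germlines, meta)
        assert result.rejected == []
        pd.testing.assert_frame_equal(
            frame_of(result.annotations), frame_of(annotated)
        )
        # internal CDR3 semantics survive the junction conversion
        for a, b in zip(result.annotations, annotated):
            assert a.cdr3_nt == b.cdr3_nt and a.cdr3_aa == b.cdr3_aa

    def test_changeo_dialect_equals_airr(self, tmp_path, germlines, annotated):
        meta = [SampleMetadata(sample_name="s1", subject="SUBJ")]
        a = export_rearrangements(annotated, tmp_path / "a.tsv", "airr", subjects={"s1": "SUBJ"})
        c = export_rearrangements(annotated, tmp_path / "c.tsv", "changeo", subjects={"s1": "SUBJ"})
        header = open(c).readline().rstrip("\n").split("\t")
        assert header == CHANGEO_COLUMNS
        ra = import_rearrangements(a, germlines, meta)
        rc = import_rearrangements(c, germlines, meta)
        pd.testing.assert_frame_equal(
            frame_of(ra.annotations), frame_of(rc.annotations)
        )

    def test_unknown_gene_rejected(self, tmp_path, germlines, annotated):
        path = export_rearrangements(
            annotated, tmp_path / "out.tsv", "airr", subjects={"s1": "SUBJ"}
        )
        df = pd.read_csv(path, sep="\t")
        df.loc[0, "v_call"] = "IGHV9-99*01"
        df.to_csv(path, sep="\t", index=False)
        meta = [SampleMetadata(sample_name="s1", subject="SUBJ")]
        result = import_rearrangements(path, germlines, meta)
        assert len(result.rejected) == 1
        assert "IGHV9-99*01" in result.rejected[0][1]
        assert len(result.annotations) == len(annotated) - 1

    def test_missing_mandatory_column(self, tmp_path, germlines, annotated):
        path = export_rearrangements(
            annotated, tmp_path / "out.tsv", "airr", subjects={"s1": "SUBJ"}
        )
        df = pd.read_csv(path, sep="\t").drop(columns=["junction"])
        df.to_csv(path, sep="\t", index=False)
        meta = [SampleMetadata(sample_name="s1", subject="SUBJ")]
        with pytest.raises(ValueError, match="junction"):
            import_rearrangements(path, germlines, meta)

    def test_unknown_sample_errors(self, tmp_path, germlines, annotated):
        path = export_rearrangements(
            annotated, tmp_path / "out.tsv", "airr", subjects={"s1": "SUBJ"}
        )
        with pytest.raises(ValueError, match="unknown sample"):
            import_rearrangements(
                path, germlines, [SampleMetadata(sample_name="zz", subject="S")]
            )

    def test_min_copies_export_filter(self, tmp_path, annotated):
        from dataclasses import replace

        anns = [
            replace(a, copy_number=(1 if i == 0 else 3))
            for i, a in enumerate(annotated)
        ]
        path = export_rearrangements(
            anns, tmp_path / "out.tsv", "airr", min_copies=2
        )
        df = pd.read_csv(path, sep="\t")
        assert len(df) == len(annotated) - 1
        assert (df["duplicate_count"] >= 2).all()


def test_vdjtools_frequencies_sum_to_one(pipeline_run, tmp_path):
    partition = infer_similarity(pipeline_run["eligible"])
    tables = export_vdjtools(partition, tmp_path)
    assert tables
    for sample, df in tables.items():
        assert list(df.columns) == ["count", "freq", "cdr3nt", "cdr3aa", "v", "j"]
        if len(df):
            assert df["freq"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (tmp_path / f"vdjtools.{sample}.tsv").exists()


def test_airr_column_order_is_deterministic(tmp_path, annotated):
    path = export_rearrangements(annotated, tmp_path / "o.tsv", "airr")
    assert open(path).readline().rstrip("\n").split("\t") == AIRR_COLUMNS
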