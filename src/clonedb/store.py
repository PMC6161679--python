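"""Relational persistence for repertoire projects.

Each project owns its own embedded SQLite database (any engine reachable
through Python's DB-API could back the same schema; the file-based engine
keeps projects isolated and needs no server).  The schema mirrors the pipeline
levels: subjects, samples, per-read annotations, subject-level collapsed
uniques, and clones with their membership links.  Pipeline steps are
incremental and resumable: identify, collapse and clonal inference can run in
separate processes against the same store, and clones are recomputed per
subject without touching any other subject's rows.
"""
from __future__ import annotations

import hashlib
import json
import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .annotate import AnnotatedSequence, SampleMetadata
from .clones import Clone, CloneConfig, ClonePartition, infer_clones
from .collapse import UniqueSequence

__all__ = ["ProjectConfig", "Project", "create_project", "open_project"]

_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")

SCHEMA = """
CREATE TABLE subjects (
    id INTEGER PRIMARY KEY,
    identifier TEXT NOT NULL UNIQUE
);
CREATE TABLE samples (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    subject_id INTEGER NOT NULL REFERENCES subjects(id),
    metadata TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE sequences (
    id INTEGER PRIMARY KEY,
    sample_id INTEGER NOT NULL REFERENCES samples(id),
    read_id TEXT NOT NULL,
    status TEXT NOT NULL,
    payload TEXT NOT NULL
);
CREATE TABLE sequence_collapse (
    id INTEGER PRIMARY KEY,
    subject_id INTEGER NOT NULL REFERENCES subjects(id),
    representative TEXT NOT NULL,
    copies INTEGER NOT NULL,
    instances INTEGER NOT NULL,
    payload TEXT NOT NULL
);
CREATE TABLE clones (
    id INTEGER PRIMARY KEY,
    subject_id INTEGER NOT NULL REFERENCES subjects(id),
    method TEXT NOT NULL,
    clone_num INTEGER NOT NULL,
    v_key TEXT NOT NULL,
    j_key TEXT NOT NULL,
    cdr3_len INTEGER NOT NULL,
    uniques INTEGER NOT NULL,
    copies INTEGER NOT NULL,
    instances INTEGER NOT NULL,
    consensus_cdr3_aa TEXT NOT NULL
);
CREATE TABLE clone_members (
    clone_id INTEGER NOT NULL REFERENCES clones(id),
    collapse_id INTEGER NOT NULL REFERENCES sequence_collapse(id)
);
CREATE TABLE sample_stats (
    sample_id INTEGER NOT NULL REFERENCES samples(id),
    payload TEXT NOT NULL
);
CREATE TABLE clone_stats (
    clone_id INTEGER NOT NULL REFERENCES clones(id),
    payload TEXT NOT NULL
);
"""


@dataclass(frozen=True)
class ProjectConfig:
    """Connection details for one project: its name and database location."""

    name: str
    db_path: str

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"name": self.name, "db_path": self.db_path}))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProjectConfig":
        d = json.loads(Path(path).read_text())
        return cls(name=d["name"], db_path=d["db_path"])


def create_project(
    name: str, config_dir: str | Path, force: bool = False
) -> ProjectConfig:
    """Create a project database and write its configuration file.

    Project names must consist of only alphanumeric characters and
    underscores so each project maps cleanly onto a database identifier.
    """
    if not _NAME_RE.match(name or ""):
        raise ValueError(
            f"invalid project name {name!r}: use only alphanumerics and underscores"
        )
    config_dir = Path(config_dir)
    config_dir.mkdir(parents=True, exist_ok=True)
    cfg_path = config_dir / f"{name}.json"
    db_path = config_dir / f"{name}.sqlite"
    if (cfg_path.exists() or db_path.exists()) and not force:
        raise FileExistsError(f"project {name!r} already exists in {config_dir}")
    if db_path.exists():
        db_path.unlink()
    cfg = ProjectConfig(name=name, db_path=str(db_path))
    cfg.save(cfg_path)
    with sqlite3.connect(db_path) as conn:
        conn.executescript(SCHEMA)
    return cfg


def open_project(config: ProjectConfig | str | Path) -> "Project":
    if not isinstance(config, ProjectConfig):
        config = ProjectConfig.load(config)
    return Project(config)


class Project:
    """A handle on one project's relational store."""

    def __init__(self, config: ProjectConfig):
        self.config = config
        self.conn = sqlite3.connect(config.db_path)
        self.conn.execute("PRAGMA foreign_keys = ON")

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Project":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # --- subjects / samples ---------------------------------------------
    def ensure_subject(self, identifier: str) -> int:
        cur = self.conn.execute(
            "SELECT id FROM subjects WHERE identifier = ?", (identifier,)
        )
        row = cur.fetchone()
        if row:
            return row[0]
        cur = self.conn.execute(
            "INSERT INTO subjects (identifier) VALUES (?)", (identifier,)
        )
        self.conn.commit()
        return cur.lastrowid

    def ensure_sample(self, meta: SampleMetadata) -> int:
        cur = self.conn.execute("SELECT id FROM samples WHERE name = ?", (meta.sample_name,))
        row = cur.fetchone()
        if row:
            return row[0]
        sid = self.ensure_subject(meta.subject)
        cur = self.conn.execute(
            "INSERT INTO samples (name, subject_id, metadata) VALUES (?, ?, ?)",
            (meta.sample_name, sid, json.dumps(dict(meta.extra))),
        )
        self.conn.commit()
        return cur.lastrowid

    def subjects(self) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute(
                "SELECT identifier FROM subjects ORDER BY identifier"
            )
        ]

    def samples_of(self, subject: str) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute(
                "SELECT s.name FROM samples s JOIN subjects t ON s.subject_id = t.id "
                "WHERE t.identifier = ? ORDER BY s.name",
                (subject,),
            )
        ]

    # --- annotations -----------------------------------------------------
    def save_annotations(
        self, meta: SampleMetadata, anns: Iterable[AnnotatedSequence]
    ) -> None:
        sample_id = self.ensure_sample(meta)
        self.conn.execute("DELETE FROM sequences WHERE sample_id = ?", (sample_id,))
        self.conn.executemany(
            "INSERT INTO sequences (sample_id, read_id, status, payload) "
            "VALUES (?, ?, ?, ?)",
            [
                (sample_id, a.read_id, a.status, json.dumps(a.to_dict()))
                for a in anns
            ],
        )
        self.conn.commit()

    def load_annotations(
        self, *, sample: str | None = None, subject: str | None = None
    ) -> list[AnnotatedSequence]:
        if sample is not None:
            q = (
                "SELECT q.payload FROM sequences q JOIN samples s ON q.sample_id = s.id "
                "WHERE s.name = ? ORDER BY q.id"
            )
            rows = self.conn.execute(q, (sample,))
        elif subject is not None:
            q = (
                "SELECT q.payload FROM sequences q JOIN samples s ON q.sample_id = s.id "
                "JOIN subjects t ON s.subject_id = t.id WHERE t.identifier = ? "
                "ORDER BY q.id"
            )
            rows = self.conn.execute(q, (subject,))
        else:
            rows = self.conn.execute("SELECT payload FROM sequences ORDER BY id")
        return [AnnotatedSequence.from_dict(json.loads(r[0])) for r in rows]

    # --- subject-level uniques ------------------------------------------
    def save_uniques(self, subject: str, uniques: Iterable[UniqueSequence]) -> None:
        sid = self.ensure_subject(subject)
        cur = self.conn.execute(
            "SELECT id FROM sequence_collapse WHERE subject_id = ?", (sid,)
        )
        old = [r[0] for r in cur.fetchall()]
        if old:
            self.conn.executemany(
                "DELETE FROM clone_members WHERE collapse_id = ?",
                [(i,) for i in old],
            )
            self.conn.execute(
                "DELETE FROM sequence_collapse WHERE subject_id = ?", (sid,)
            )
        payloads = []
        for u in uniques:
            payloads.append(
                (
                    sid,
                    u.representative,
                    u.copies,
                    u.instances,
                    json.dumps(
                        {
                            "representative": u.representative,
                            "member_reads": sorted(map(list, u.member_reads)),
                            "per_sample_copies": u.per_sample_copies,
                            "annotation": u.annotation.to_dict(),
                        }
                    ),
                )
            )
        self.conn.executemany(
            "INSERT INTO sequence_collapse "
            "(subject_id, representative, copies, instances, payload) "
            "VALUES (?, ?, ?, ?, ?)",
            payloads,
        )
        self.conn.commit()

    def load_uniques(self, subject: str) -> list[UniqueSequence]:
        rows = self.conn.execute(
            "SELECT c.payload FROM sequence_collapse c "
            "JOIN subjects t ON c.subject_id = t.id WHERE t.identifier = ? "
            "ORDER BY c.id",
            (subject,),
        )
        out = []
        for (payload,) in rows:
            d = json.loads(payload)
            out.append(
                UniqueSequence(
                    subject=subject,
                    representative=d["representative"],
                    member_reads=frozenset(
                        (s, r) for s, r in d["member_reads"]
                    ),
                    per_sample_copies=d["per_sample_copies"],
                    annotation=AnnotatedSequence.from_dict(d["annotation"]),
                )
            )
        return out

    def _unique_row_ids(self, subject: str) -> dict[frozenset, int]:
        sid = self.ensure_subject(subject)
        rows = self.conn.execute(
            "SELECT id, payload FROM sequence_collapse WHERE subject_id = ?",
            (sid,),
        )
        out = {}
        for rowid, payload in rows:
            d = json.loads(payload)
            out[frozenset((s, r) for s, r in d["member_reads"])] = rowid
        return out

    # --- clones ----------------------------------------------------------
    def save_partition(self, partition: ClonePartition) -> None:
        sid = self.ensure_subject(partition.subject)
        old = [
            r[0]
            for r in self.conn.execute(
                "SELECT id FROM clones WHERE subject_id = ? AND method = ?",
                (sid, partition.method),
            )
        ]
        if old:
            self.conn.executemany(
                "DELETE FROM clone_members WHERE clone_id = ?", [(i,) for i in old]
            )
            self.conn.executemany(
                "DELETE FROM clone_stats WHERE clone_id = ?", [(i,) for i in old]
            )
            self.conn.execute(
                "DELETE FROM clones WHERE subject_id = ? AND method = ?",
                (sid, partition.method),
            )
        row_ids = self._unique_row_ids(partition.subject)
        for c in partition.clones:
            cur = self.conn.execute(
                "INSERT INTO clones (subject_id, method, clone_num, v_key, j_key, "
                "cdr3_len, uniques, copies, instances, consensus_cdr3_aa) "
                "VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    sid,
                    partition.method,
                    c.clone_id,
                    c.v_key,
                    c.j_key,
                    c.cdr3_len,
                    c.uniques,
                    c.copies,
                    c.instances,
                    c.consensus_cdr3_aa,
                ),
            )
            clone_row = cur.lastrowid
            for m in c.members:
                collapse_id = row_ids.get(m.member_reads)
                if collapse_id is not None:
                    self.conn.execute(
                        "INSERT INTO clone_members (clone_id, collapse_id) "
                        "VALUES (?, ?)",
                        (clone_row, collapse_id),
                    )
        self.conn.commit()

    def load_partition(self, subject: str, method: str) -> ClonePartition:
        uniques = {u.member_reads: u for u in self.load_uniques(subject)}
        sid = self.ensure_subject(subject)
        clones = []
        for row in self.conn.execute(
            "SELECT id, clone_num, v_key, j_key, cdr3_len FROM clones "
            "WHERE subject_id = ? AND method = ? ORDER BY clone_num",
            (sid, method),
        ):
            rowid, num, v_key, j_key, cdr3_len = row
            members = []
            for (collapse_id,) in self.conn.execute(
                "SELECT collapse_id FROM clone_members WHERE clone_id = ?", (rowid,)
            ):
                (payload,) = self.conn.execute(
                    "SELECT payload FROM sequence_collapse WHERE id = ?",
                    (collapse_id,),
                ).fetchone()
                d = json.loads(payload)
                key = frozenset((s, r) for s, r in d["member_reads"])
                members.append(uniques[key])
            clones.append(
                Clone(
                    clone_id=num,
                    subject=subject,
                    v_key=v_key,
                    j_key=j_key,
                    cdr3_len=cdr3_len,
                    members=sorted(members, key=lambda m: m.representative),
                )
            )
        return ClonePartition(subject=subject, method=method, clones=clones)

    def rerun_clones(self, subject: str, cfg: CloneConfig) -> ClonePartition:
        """Recompute clones for one subject from its stored uniques, leaving
        every other subject's rows untouched.  Clone ids are regenerated."""
        if subject not in self.subjects():
            raise ValueError(f"unknown subject {subject!r}")
        uniques = self.load_uniques(subject)
        partition = infer_clones(uniques, cfg)
        self.save_partition(partition)
        return partition

    # --- stats / integrity ----------------------------------------------
    def save_sample_stats(self, sample: str, payload: dict) -> None:
        cur = self.conn.execute("SELECT id FROM samples WHERE name = ?", (sample,))
        row = cur.fetchone()
        if not row:
            raise ValueError(f"unknown sample {sample!r}")
        self.conn.execute("DELETE FROM sample_stats WHERE sample_id = ?", (row[0],))
        self.conn.execute(
            "INSERT INTO sample_stats (sample_id, payload) VALUES (?, ?)",
            (row[0], json.dumps(payload)),
        )
        self.conn.commit()

    def rows_digest(self, *, exclude_subject: str | None = None) -> str:
        """Checksum of all stored rows, optionally excluding one subject's
        (used to verify per-subject isolation of reruns)."""
        h = hashlib.sha256()
        excluded = None
        if exclude_subject is not None:
            cur = self.conn.execute(
                "SELECT id FROM subjects WHERE identifier = ?", (exclude_subject,)
            )
            row = cur.fetchone()
            excluded = row[0] if row else None
        for table, subject_col in (
            ("subjects", "id"),
            ("samples", "subject_id"),
            ("sequences", None),
            ("sequence_collapse", "subject_id"),
            ("clones", "subject_id"),
        ):
            if table == "sequences":
                q = (
                    "SELECT q.* FROM sequences q JOIN samples s ON q.sample_id = s.id"
                )
                if excluded is not None:
                    q += f" WHERE s.subject_id != {excluded}"
                q += " ORDER BY q.id"
            else:
                q = f"SELECT * FROM {table}"
                if excluded is not None:
                    q += f" WHERE {subject_col} != {excluded}"
                q += " ORDER BY id"
            for row in self.conn.execute(q):
                h.update(repr(row).encode())
        # membership links of non-excluded subjects
        q = (
            "SELECT m.* FROM clone_members m JOIN clones c ON m.clone_id = c.id"
        )
        if excluded is not None:
            q += f" WHERE c.subject_id != {excluded}"
        q += " ORDER BY m.clone_id, m.collapse_id"
        for row in self.conn.execute(q):
            h.update(repr(row).encode())
        return h.hexdigest()

    def check_referential_integrity(self) -> list[str]:
        """Return a list of violations (empty when the store is consistent)."""
        problems = []
        for (n,) in self.conn.execute(
            "SELECT COUNT(*) FROM clone_members m "
            "LEFT JOIN sequence_collapse c ON m.collapse_id = c.id WHERE c.id IS NULL"
        ):
            if n:
                problems.append(f"{n} clone members without a unique sequence")
        for (n,) in self.conn.execute(
            "SELECT COUNT(*) FROM sequences q "
            "LEFT JOIN samples s ON q.sample_id = s.id WHERE s.id IS NULL"
        ):
            if n:
                problems.append(f"{n} sequences without a sample")
        return problems
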