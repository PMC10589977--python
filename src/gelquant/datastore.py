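"""Embedded relational store for gels, lanes, images, measurements and the
analysis log.

Everything a result depends on lives in one SQLite file: the project
hierarchy, gel and sample metadata, the source image's path and content
hash, every analysis step with its full parameters (the *analysis log*), and
the stored measurement values. Because the log is parameter-complete,
any stored analysis can be re-executed and checked bit-for-bit against the
stored values (see :mod:`gelquant.engine`).

All tables and views carry the ``gelquant_`` namespace prefix so that the
layout ports unchanged to a schema inside a shared server database. Data
access for statistics goes through three SQL views —
``gelquant_project_paths``, ``gelquant_reference_measurements`` and
``gelquant_normalized`` — which are plain ``CREATE VIEW`` statements visible
below; the normalized view computes the reference value r and the normalized
value w directly in SQL, so R and any other client can fetch finished
numbers without running this package.

Stores open by default in *viewing* mode semantics only when requested:
``open_store(path, readonly=True)`` returns a handle on which every mutation
raises, mirroring a viewing/editing mode split without any UI state.
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ReadOnlyStoreError, StoreError
from .normalization import LaneRecord
from .serialize import canonical_json, from_canonical_json

SCHEMA_VERSION = 1

#: Operation names allowed in the analysis log.
OPERATIONS = frozenset({"read_image", "crop", "subtract_background", "measure_lane"})

_SCHEMA = """
CREATE TABLE gelquant_schema_info (
    version INTEGER NOT NULL
);
CREATE TABLE gelquant_project (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    parent_id INTEGER REFERENCES gelquant_project(id)
);
CREATE UNIQUE INDEX gelquant_project_unique
    ON gelquant_project (IFNULL(parent_id, -1), name);
CREATE TABLE gelquant_gel (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    comment TEXT NOT NULL DEFAULT ''
);
CREATE TABLE gelquant_gel_project (
    gel_id INTEGER NOT NULL REFERENCES gelquant_gel(id),
    project_id INTEGER NOT NULL REFERENCES gelquant_project(id),
    UNIQUE (gel_id, project_id)
);
CREATE TABLE gelquant_measurement_type (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE gelquant_lane (
    id INTEGER PRIMARY KEY,
    gel_id INTEGER NOT NULL REFERENCES gelquant_gel(id),
    lane_index INTEGER NOT NULL,
    sample_id TEXT NOT NULL DEFAULT '',
    protein REAL,
    is_reference INTEGER NOT NULL DEFAULT 0,
    UNIQUE (gel_id, lane_index)
);
CREATE TABLE gelquant_image (
    id INTEGER PRIMARY KEY,
    gel_id INTEGER NOT NULL REFERENCES gelquant_gel(id),
    path TEXT NOT NULL,
    content_hash TEXT NOT NULL
);
CREATE TABLE gelquant_analysis_step (
    id INTEGER PRIMARY KEY,
    image_id INTEGER NOT NULL REFERENCES gelquant_image(id),
    step_index INTEGER NOT NULL,
    operation TEXT NOT NULL,
    params TEXT NOT NULL,
    UNIQUE (image_id, step_index)
);
CREATE TABLE gelquant_measurement (
    id INTEGER PRIMARY KEY,
    image_id INTEGER NOT NULL REFERENCES gelquant_image(id),
    measurement_type_id INTEGER NOT NULL REFERENCES gelquant_measurement_type(id),
    lane_id INTEGER NOT NULL REFERENCES gelquant_lane(id),
    region_y0 INTEGER NOT NULL,
    region_y1 INTEGER NOT NULL,
    value REAL NOT NULL,
    success INTEGER NOT NULL DEFAULT 1,
    UNIQUE (image_id, measurement_type_id, lane_id, region_y0, region_y1)
);
"""

_VIEWS = """
CREATE VIEW gelquant_project_paths AS
WITH RECURSIVE pp(id, path) AS (
    SELECT id, name FROM gelquant_project WHERE parent_id IS NULL
    UNION ALL
    SELECT p.id, pp.path || '/' || p.name
    FROM gelquant_project p JOIN pp ON p.parent_id = pp.id
)
SELECT id, path FROM pp;

CREATE VIEW gelquant_reference_measurements AS
SELECT m.image_id AS image_id,
       m.measurement_type_id AS measurement_type_id,
       AVG(m.value / l.protein) AS r,
       COUNT(*) AS n_reference
FROM gelquant_measurement m
JOIN gelquant_lane l ON m.lane_id = l.id
WHERE l.is_reference = 1 AND m.success = 1 AND l.protein IS NOT NULL
GROUP BY m.image_id, m.measurement_type_id;

CREATE VIEW gelquant_normalized AS
SELECT g.id AS gel_id, g.name AS gel,
       m.image_id AS image_id,
       t.name AS measurement_type,
       l.lane_index AS lane_index,
       l.sample_id AS sample_id,
       l.protein AS protein,
       m.region_y0 AS region_y0, m.region_y1 AS region_y1,
       m.value AS value,
       ref.r AS r,
       (m.value / l.protein) / ref.r AS w
FROM gelquant_measurement m
JOIN gelquant_lane l ON m.lane_id = l.id
JOIN gelquant_gel g ON l.gel_id = g.id
JOIN gelquant_measurement_type t ON m.measurement_type_id = t.id
JOIN gelquant_reference_measurements ref
  ON ref.image_id = m.image_id
 AND ref.measurement_type_id = m.measurement_type_id
WHERE m.success = 1 AND l.protein IS NOT NULL;
"""


@dataclass(frozen=True)
class Project:
    id: int
    name: str
    parent_id: int | None


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def open_store(path, readonly: bool = False) -> "GelStore":
    """Create or open a single-file store at ``path``.

    With ``readonly=True`` the file must exist; the returned handle permits
    queries and views but raises :class:`ReadOnlyStoreError` on mutation.
    """
    return GelStore(path, readonly=readonly)


class GelStore:
    def __init__(self, path, readonly: bool = False):
        self.path = str(path)
        self.readonly = readonly
        if readonly:
            if not Path(self.path).exists():
                raise StoreError(f"store not found: {self.path}")
            self.conn = sqlite3.connect(f"file:{self.path}?mode=ro", uri=True)
        else:
            self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self._init_or_check_schema()

    # -- lifecycle -------------------------------------------------------

    def close(self):
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def _init_or_check_schema(self):
        cur = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='gelquant_schema_info'"
        )
        if cur.fetchone() is None:
            if self.readonly:
                raise StoreError(f"{self.path} is not a gelquant store")
            with self.conn:
                self.conn.executescript(_SCHEMA + _VIEWS)
                self.conn.execute(
                    "INSERT INTO gelquant_schema_info (version) VALUES (?)",
                    (SCHEMA_VERSION,),
                )
            return
        (version,) = self.conn.execute(
            "SELECT version FROM gelquant_schema_info"
        ).fetchone()
        if version > SCHEMA_VERSION:
            raise StoreError(
                f"store schema version {version} is newer than this software "
                f"supports ({SCHEMA_VERSION}); upgrade the software to open it"
            )

    def _mutable(self):
        if self.readonly:
            raise ReadOnlyStoreError(
                "store is open in viewing mode; reopen without readonly to edit"
            )
        return self.conn

    # -- projects --------------------------------------------------------

    def create_project(self, path_string: str) -> Project:
        """Get-or-create the project at ``"A/B/C"``, creating ancestors."""
        parts = path_string.split("/")
        if any(not p for p in parts):
            raise StoreError(f"empty name component in project path {path_string!r}")
        conn = self._mutable()
        parent_id = None
        proj = None
        with conn:
            for name in parts:
                row = conn.execute(
                    "SELECT id FROM gelquant_project WHERE name=? AND parent_id IS ?",
                    (name, parent_id),
                ).fetchone()
                if row is None:
                    cur = conn.execute(
                        "INSERT INTO gelquant_project (name, parent_id) VALUES (?,?)",
                        (name, parent_id),
                    )
                    pid = cur.lastrowid
                else:
                    pid = row[0]
                proj = Project(pid, name, parent_id)
                parent_id = pid
        return proj

    def project_id(self, path_string: str) -> int:
        row = self.conn.execute(
            "SELECT id FROM gelquant_project_paths WHERE path = ?", (path_string,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown project {path_string!r}")
        return row[0]

    def _project_subtree(self, project_id: int) -> list[int]:
        rows = self.conn.execute(
            """
            WITH RECURSIVE sub(id) AS (
                SELECT id FROM gelquant_project WHERE id = ?
                UNION ALL
                SELECT p.id FROM gelquant_project p JOIN sub ON p.parent_id = sub.id
            ) SELECT id FROM sub
            """,
            (project_id,),
        ).fetchall()
        if not rows:
            raise StoreError(f"unknown project id {project_id}")
        return [r[0] for r in rows]

    # -- gels, lanes, types, images -------------------------------------

    def add_gel(self, name: str, comment: str = "", projects=()) -> int:
        conn = self._mutable()
        with conn:
            gid = conn.execute(
                "INSERT INTO gelquant_gel (name, comment) VALUES (?,?)",
                (name, comment),
            ).lastrowid
        for p in projects:
            self.link_gel_project(gid, p)
        return gid

    def link_gel_project(self, gel_id: int, project) -> None:
        pid = project if isinstance(project, int) else self.project_id(project)
        conn = self._mutable()
        with conn:
            conn.execute(
                "INSERT OR IGNORE INTO gelquant_gel_project (gel_id, project_id) VALUES (?,?)",
                (gel_id, pid),
            )

    def add_measurement_type(self, name: str) -> int:
        conn = self._mutable()
        with conn:
            row = conn.execute(
                "SELECT id FROM gelquant_measurement_type WHERE name=?", (name,)
            ).fetchone()
            if row:
                return row[0]
            return conn.execute(
                "INSERT INTO gelquant_measurement_type (name) VALUES (?)", (name,)
            ).lastrowid

    def set_lane(self, gel_id: int, lane: LaneRecord) -> int:
        """Insert or update the sample record of one lane of a gel."""
        conn = self._mutable()
        with conn:
            conn.execute(
                """
                INSERT INTO gelquant_lane (gel_id, lane_index, sample_id, protein, is_reference)
                VALUES (?,?,?,?,?)
                ON CONFLICT (gel_id, lane_index) DO UPDATE
                SET sample_id=excluded.sample_id, protein=excluded.protein,
                    is_reference=excluded.is_reference
                """,
                (gel_id, lane.lane_index, lane.sample_id, lane.protein,
                 int(lane.is_reference)),
            )
            return conn.execute(
                "SELECT id FROM gelquant_lane WHERE gel_id=? AND lane_index=?",
                (gel_id, lane.lane_index),
            ).fetchone()[0]

    def lanes_for_gel(self, gel_id: int) -> list[LaneRecord]:
        rows = self.conn.execute(
            "SELECT lane_index, sample_id, protein, is_reference FROM gelquant_lane "
            "WHERE gel_id=? ORDER BY lane_index",
            (gel_id,),
        ).fetchall()
        return [
            LaneRecord(lane_index=i, sample_id=s, protein=m, is_reference=bool(ref))
            for (i, s, m, ref) in rows
        ]

    def add_image(self, gel_id: int, path) -> int:
        """Register a source image; its content hash is fixed at ingest."""
        p = Path(path)
        if not p.exists():
            raise StoreError(f"image file not found: {p}")
        conn = self._mutable()
        with conn:
            return conn.execute(
                "INSERT INTO gelquant_image (gel_id, path, content_hash) VALUES (?,?,?)",
                (gel_id, str(p), file_hash(p)),
            ).lastrowid

    def image_record(self, image_id: int):
        row = self.conn.execute(
            "SELECT id, gel_id, path, content_hash FROM gelquant_image WHERE id=?",
            (image_id,),
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown image id {image_id}")
        return {"id": row[0], "gel_id": row[1], "path": row[2], "content_hash": row[3]}

    # -- analysis log ----------------------------------------------------

    def record_step(self, image_id: int, operation: str, params: dict) -> int:
        """Append one operation to the image's analysis log.

        Parameters are stored in canonical JSON so the log is a complete,
        replayable record.
        """
        if operation not in OPERATIONS:
            raise StoreError(f"unknown operation {operation!r}")
        self.image_record(image_id)
        conn = self._mutable()
        with conn:
            (nxt,) = conn.execute(
                "SELECT IFNULL(MAX(step_index), -1) + 1 FROM gelquant_analysis_step "
                "WHERE image_id=?",
                (image_id,),
            ).fetchone()
            conn.execute(
                "INSERT INTO gelquant_analysis_step (image_id, step_index, operation, params) "
                "VALUES (?,?,?,?)",
                (image_id, nxt, operation, canonical_json(params)),
            )
        return nxt

    def steps(self, image_id: int) -> list[tuple[int, str, dict]]:
        rows = self.conn.execute(
            "SELECT step_index, operation, params FROM gelquant_analysis_step "
            "WHERE image_id=? ORDER BY step_index",
            (image_id,),
        ).fetchall()
        return [(i, op, from_canonical_json(p)) for (i, op, p) in rows]

    def clear_analysis(self, image_id: int) -> None:
        conn = self._mutable()
        with conn:
            conn.execute(
                "DELETE FROM gelquant_analysis_step WHERE image_id=?", (image_id,)
            )
            conn.execute(
                "DELETE FROM gelquant_measurement WHERE image_id=?", (image_id,)
            )

    # -- measurements ----------------------------------------------------

    def store_measurement(
        self,
        image_id: int,
        measurement_type: str,
        lane_index: int,
        region_y0: int,
        region_y1: int,
        value: float,
        success: bool = True,
    ) -> int:
        img = self.image_record(image_id)
        type_id = self.add_measurement_type(measurement_type)
        conn = self._mutable()
        row = conn.execute(
            "SELECT id FROM gelquant_lane WHERE gel_id=? AND lane_index=?",
            (img["gel_id"], lane_index),
        ).fetchone()
        if row is None:
            raise StoreError(
                f"gel {img['gel_id']} has no lane with index {lane_index}"
            )
        with conn:
            return conn.execute(
                """
                INSERT INTO gelquant_measurement
                    (image_id, measurement_type_id, lane_id, region_y0, region_y1, value, success)
                VALUES (?,?,?,?,?,?,?)
                ON CONFLICT (image_id, measurement_type_id, lane_id, region_y0, region_y1)
                DO UPDATE SET value=excluded.value, success=excluded.success
                """,
                (image_id, type_id, row[0], region_y0, region_y1, value, int(success)),
            ).lastrowid

    def set_measurement_success(
        self, image_id: int, measurement_type: str, lane_index: int, success: bool
    ) -> None:
        conn = self._mutable()
        with conn:
            conn.execute(
                """
                UPDATE gelquant_measurement SET success=?
                WHERE image_id=? AND lane_id IN (
                    SELECT l.id FROM gelquant_lane l
                    JOIN gelquant_image i ON i.gel_id = l.gel_id
                    WHERE i.id=? AND l.lane_index=?)
                AND measurement_type_id = (
                    SELECT id FROM gelquant_measurement_type WHERE name=?)
                """,
                (int(success), image_id, image_id, lane_index, measurement_type),
            )

    def measurements(self, image_id: int) -> pd.DataFrame:
        return pd.read_sql_query(
            """
            SELECT m.image_id, t.name AS measurement_type, l.lane_index,
                   m.region_y0, m.region_y1, m.value, m.success
            FROM gelquant_measurement m
            JOIN gelquant_lane l ON m.lane_id = l.id
            JOIN gelquant_measurement_type t ON m.measurement_type_id = t.id
            WHERE m.image_id = ?
            ORDER BY t.name, l.lane_index, m.region_y0
            """,
            self.conn,
            params=(image_id,),
        )

    # -- views -----------------------------------------------------------

    def view_project_paths(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT id, path FROM gelquant_project_paths ORDER BY path", self.conn
        )

    def view_reference_measurements(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM gelquant_reference_measurements "
            "ORDER BY image_id, measurement_type_id",
            self.conn,
        )

    def view_normalized(self) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM gelquant_normalized "
            "ORDER BY gel, image_id, lane_index, measurement_type, region_y0",
            self.conn,
        )

    # -- export ----------------------------------------------------------

    _RAW_SQL = """
    SELECT g.name AS gel, i.id AS image, t.name AS measurement_type,
           l.lane_index AS lane, l.sample_id AS sample_id, l.protein AS m,
           mm.value AS v, mm.success AS success
    FROM gelquant_measurement mm
    JOIN gelquant_image i ON mm.image_id = i.id
    JOIN gelquant_gel g ON i.gel_id = g.id
    JOIN gelquant_lane l ON mm.lane_id = l.id
    JOIN gelquant_measurement_type t ON mm.measurement_type_id = t.id
    {where}
    ORDER BY g.name, i.id, l.lane_index, t.name, mm.region_y0
    """

    _NORM_SQL = """
    SELECT g.name AS gel, i.id AS image, t.name AS measurement_type,
           l.lane_index AS lane, l.sample_id AS sample_id, l.protein AS m,
           mm.value AS v, ref.r AS r, (mm.value / l.protein) / ref.r AS w
    FROM gelquant_measurement mm
    JOIN gelquant_image i ON mm.image_id = i.id
    JOIN gelquant_gel g ON i.gel_id = g.id
    JOIN gelquant_lane l ON mm.lane_id = l.id
    JOIN gelquant_measurement_type t ON mm.measurement_type_id = t.id
    JOIN gelquant_reference_measurements ref
      ON ref.image_id = mm.image_id AND ref.measurement_type_id = mm.measurement_type_id
    WHERE mm.success = 1 AND l.protein IS NOT NULL {extra}
    ORDER BY g.name, i.id, l.lane_index, t.name, mm.region_y0
    """

    def export_tables(self, project: str | int | None = None):
        """Raw and normalized result tables, optionally limited to a project
        subtree. Returns ``(raw_df, normalized_df)``."""
        if project is None:
            raw = pd.read_sql_query(self._RAW_SQL.format(where=""), self.conn)
            norm = pd.read_sql_query(self._NORM_SQL.format(extra=""), self.conn)
            return raw, norm
        pid = project if isinstance(project, int) else self.project_id(project)
        ids = self._project_subtree(pid)
        marks = ",".join("?" * len(ids))
        gel_filter = (
            f"g.id IN (SELECT gel_id FROM gelquant_gel_project WHERE project_id IN ({marks}))"
        )
        raw = pd.read_sql_query(
            self._RAW_SQL.format(where="WHERE " + gel_filter), self.conn, params=ids
        )
        norm = pd.read_sql_query(
            self._NORM_SQL.format(extra="AND " + gel_filter), self.conn, params=ids
        )
        return raw, norm

    def export_spreadsheet(self, out_path, project: str | int | None = None):
        """Write the raw and normalized tables to a spreadsheet.

        ``.xlsx`` output is one workbook with sheets ``raw`` and
        ``normalized``; any other extension writes an RFC 4180 CSV pair
        ``<stem>_raw.csv`` / ``<stem>_normalized.csv``. Returns the list of
        files written.
        """
        raw, norm = self.export_tables(project)
        out_path = Path(out_path)
        if out_path.suffix.lower() == ".xlsx":
            with pd.ExcelWriter(out_path, engine="openpyxl") as xl:
                raw.to_excel(xl, sheet_name="raw", index=False)
                norm.to_excel(xl, sheet_name="normalized", index=False)
            return [out_path]
        raw_p = out_path.with_name(out_path.stem + "_raw.csv")
        norm_p = out_path.with_name(out_path.stem + "_normalized.csv")
        raw.to_csv(raw_p, index=False)
        norm.to_csv(norm_p, index=False)
        return [raw_p, norm_p]
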