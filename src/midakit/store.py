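"""Embedded single-file archive for records and results.

A self-contained, relocatable SQLite database replaces a networked server:
the portable artifact is the schema, not the transport.  Tables:

* ``metabolite(id, name)`` — one row per metabolite name;
* ``record(id, metabolite_id, fragment, atom_mass, fixed_value, timestamp)``
  — unique on (metabolite, fragment, timestamp), so re-importing identical
  records is a no-op;
* ``channel(record_id, mz, rep1, rep2, rep3, standard)`` — intensities per
  m/z channel, cascade-deleted with their record;
* ``result(record_id, replicate, enrichment, mean, sd, created_at)`` —
  per-replicate enrichments, cascade-deleted with their record.

Timestamps are stored as ISO-8601 text.  Every write happens inside a
transaction, so concurrent readers never observe a partial import.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass

from .formats import IsoRecord, parse_iso, write_iso
from .mida import EnrichmentResult

__all__ = ["Archive", "ArchiveError", "open_archive"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS metabolite (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS record (
    id INTEGER PRIMARY KEY,
    metabolite_id INTEGER NOT NULL REFERENCES metabolite(id),
    fragment INTEGER NOT NULL,
    atom_mass INTEGER NOT NULL,
    fixed_value TEXT NOT NULL DEFAULT '',
    timestamp TEXT NOT NULL DEFAULT '',
    UNIQUE (metabolite_id, fragment, timestamp)
);
CREATE TABLE IF NOT EXISTS channel (
    record_id INTEGER NOT NULL REFERENCES record(id) ON DELETE CASCADE,
    mz INTEGER NOT NULL,
    rep1 REAL NOT NULL,
    rep2 REAL NOT NULL,
    rep3 REAL NOT NULL,
    standard REAL NOT NULL,
    UNIQUE (record_id, mz)
);
CREATE TABLE IF NOT EXISTS result (
    record_id INTEGER NOT NULL REFERENCES record(id) ON DELETE CASCADE,
    replicate INTEGER NOT NULL,
    enrichment REAL NOT NULL,
    mean REAL NOT NULL,
    sd REAL NOT NULL,
    created_at TEXT NOT NULL DEFAULT ''
);
"""


class ArchiveError(ValueError):
    """Referential violation, invalid filter or refused destructive call."""


@dataclass(frozen=True)
class _RecordKey:
    name: str
    fragment: int
    timestamp: str


class Archive:
    """Open (creating if needed) a single-file record/result archive."""

    def __init__(self, path=":memory:"):
        self._conn = sqlite3.connect(str(path))
        self._conn.execute("PRAGMA foreign_keys = ON")
        with self._conn:
            self._conn.executescript(_SCHEMA)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Archive":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- import ------------------------------------------------------------

    def import_records(self, records) -> int:
        """Insert records; identical re-imports are skipped.  Returns the
        number of newly stored records.  Per-record constraint violations
        are collected without aborting the batch."""
        imported = 0
        errors: list[str] = []
        with self._conn:
            for rec in records:
                try:
                    imported += self._import_one(rec)
                except (sqlite3.Error, ArchiveError) as exc:
                    errors.append(f"{rec.name}: {exc}")
        if errors:
            raise ArchiveError(
                f"{imported} imported; failures: " + "; ".join(errors))
        return imported

    def _import_one(self, rec: IsoRecord) -> int:
        cur = self._conn.execute(
            "INSERT OR IGNORE INTO metabolite (name) VALUES (?)", (rec.name,))
        (met_id,) = self._conn.execute(
            "SELECT id FROM metabolite WHERE name = ?", (rec.name,)).fetchone()
        cur = self._conn.execute(
            "INSERT OR IGNORE INTO record "
            "(metabolite_id, fragment, atom_mass, fixed_value, timestamp) "
            "VALUES (?, ?, ?, ?, ?)",
            (met_id, rec.fragment, rec.atom_mass, rec.fixed_value,
             rec.timestamp))
        if cur.rowcount == 0:
            return 0  # identical key already archived
        rec_id = cur.lastrowid
        self._conn.executemany(
            "INSERT INTO channel (record_id, mz, rep1, rep2, rep3, standard) "
            "VALUES (?, ?, ?, ?, ?, ?)",
            [(rec_id, mz, r1, r2, r3, s) for mz, r1, r2, r3, s in
             zip(rec.mz, rec.intensities_1, rec.intensities_2,
                 rec.intensities_3, rec.standard)])
        return 1

    # -- query -------------------------------------------------------------

    @staticmethod
    def _filter_clause(name_pattern, date_from, date_to):
        if date_from is not None and date_to is not None and date_from > date_to:
            raise ArchiveError(
                f"invalid date range: {date_from!r} > {date_to!r}")
        clauses, params = [], []
        if name_pattern is not None:
            clauses.append("m.name LIKE ?")
            params.append(name_pattern.replace("*", "%"))
        if date_from is not None:
            clauses.append("r.timestamp >= ?")
            params.append(date_from)
        if date_to is not None:
            clauses.append("r.timestamp <= ?")
            params.append(date_to)
        where = (" WHERE " + " AND ".join(clauses)) if clauses else ""
        return where, params

    def query_records(self, name_pattern=None, date_from=None,
                      date_to=None) -> list[IsoRecord]:
        """Fetch records matching a name pattern (``*`` or SQL ``%``
        wildcards) and/or an ISO-8601 date window.  Channels are restored
        in m/z order."""
        where, params = self._filter_clause(name_pattern, date_from, date_to)
        rows = self._conn.execute(
            f"SELECT r.id, m.name, r.fragment, r.atom_mass, r.fixed_value, "
            f"r.timestamp FROM record r JOIN metabolite m "
            f"ON m.id = r.metabolite_id{where} ORDER BY r.id", params).fetchall()
        out = []
        for rec_id, name, fragment, atom_mass, fixed, ts in rows:
            chans = self._conn.execute(
                "SELECT mz, rep1, rep2, rep3, standard FROM channel "
                "WHERE record_id = ? ORDER BY mz", (rec_id,)).fetchall()
            out.append(IsoRecord(
                name=name,
                mz=tuple(c[0] for c in chans),
                intensities_1=tuple(c[1] for c in chans),
                intensities_2=tuple(c[2] for c in chans),
                intensities_3=tuple(c[3] for c in chans),
                standard=tuple(c[4] for c in chans),
                atom_mass=atom_mass, fragment=fragment,
                fixed_value=fixed, timestamp=ts))
        return out

    # -- delete ------------------------------------------------------------

    def delete_records(self, name_pattern=None, date_from=None,
                       date_to=None, delete_all=False) -> int:
        """Delete matching records (channels and results cascade).

        An empty filter is refused unless ``delete_all=True``."""
        if name_pattern is None and date_from is None and date_to is None \
                and not delete_all:
            raise ArchiveError(
                "refusing to delete with an empty filter; pass "
                "delete_all=True to clear the archive")
        where, params = self._filter_clause(name_pattern, date_from, date_to)
        with self._conn:
            cur = self._conn.execute(
                f"DELETE FROM record WHERE id IN (SELECT r.id FROM record r "
                f"JOIN metabolite m ON m.id = r.metabolite_id{where})", params)
        return cur.rowcount

    # -- results -----------------------------------------------------------

    def _record_id(self, name: str, fragment: int, timestamp: str):
        row = self._conn.execute(
            "SELECT r.id FROM record r JOIN metabolite m "
            "ON m.id = r.metabolite_id "
            "WHERE m.name = ? AND r.fragment = ? AND r.timestamp = ?",
            (name, fragment, timestamp)).fetchone()
        return row[0] if row else None

    def store_results(self, keyed_results, created_at: str = "") -> int:
        """Store ``(record, result)`` pairs; the record must already be
        archived, otherwise a referential error is raised."""
        count = 0
        with self._conn:
            for rec, res in keyed_results:
                rec_id = self._record_id(rec.name, rec.fragment, rec.timestamp)
                if rec_id is None:
                    raise ArchiveError(
                        f"cannot store results for {rec.name!r}: record is "
                        f"not archived")
                self._conn.execute(
                    "DELETE FROM result WHERE record_id = ?", (rec_id,))
                for i, enr in enumerate(res.per_replicate, start=1):
                    self._conn.execute(
                        "INSERT INTO result (record_id, replicate, enrichment, "
                        "mean, sd, created_at) VALUES (?, ?, ?, ?, ?, ?)",
                        (rec_id, i, enr, res.mean, res.sd, created_at))
                    count += 1
        return count

    def query_results(self, name_pattern=None):
        """Fetch stored results as (name, replicate, enrichment, mean, sd)."""
        where, params = self._filter_clause(name_pattern, None, None)
        return self._conn.execute(
            f"SELECT m.name, s.replicate, s.enrichment, s.mean, s.sd "
            f"FROM result s JOIN record r ON r.id = s.record_id "
            f"JOIN metabolite m ON m.id = r.metabolite_id{where} "
            f"ORDER BY r.id, s.replicate", params).fetchall()

    # -- interchange --------------------------------------------------------

    def dump(self) -> str:
        """Serialize the whole archive to the ``.iso`` dialect."""
        return write_iso(self.query_records())

    def load(self, source) -> int:
        """Import ``.iso`` content (path, stream or string)."""
        return self.import_records(parse_iso(source))


def open_archive(path=":memory:") -> Archive:
    """Open (or create) an archive at ``path``."""
    return Archive(path)
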