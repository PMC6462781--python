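"""Relational storage of the experiment hierarchy.

A zero-configuration single-file SQLite store, so a whole study can be
shared as one file and queried from any SQL-speaking tool. The layout
normalises the identifier's strain/media/environment components into their
own tables and keys everything else on canonical serialized identifiers,
which makes saves idempotent upserts: re-saving the same experiment inserts
nothing.

Computed features are deliberately NOT persisted — they are cheap to
recompute and storing them invites staleness. A replicate trial may belong
to several experiments; membership is a many-to-many link table.

The schema is versioned; opening a store written by an incompatible version
fails before any write.
"""

from __future__ import annotations

import math
import sqlite3
from contextlib import contextmanager
from dataclasses import replace
from pathlib import Path

import numpy as np

from .errors import StoreError
from .identifiers import parse_identifier, serialize_identifier
from .schema import AnalyteCourse, Experiment, ReplicateTrial, SingleTrial

SCHEMA_VERSION = 1

_DDL = """
CREATE TABLE IF NOT EXISTS schema_version (version INTEGER NOT NULL);
CREATE TABLE IF NOT EXISTS strains (
    id INTEGER PRIMARY KEY, name TEXT, knockouts TEXT, plasmids TEXT,
    UNIQUE(name, knockouts, plasmids));
CREATE TABLE IF NOT EXISTS media (
    id INTEGER PRIMARY KEY, name TEXT, components TEXT, UNIQUE(name, components));
CREATE TABLE IF NOT EXISTS environments (
    id INTEGER PRIMARY KEY, labware TEXT, temperature REAL, shaking_speed REAL,
    UNIQUE(labware, temperature, shaking_speed));
CREATE TABLE IF NOT EXISTS experiments (
    id INTEGER PRIMARY KEY, label TEXT NOT NULL UNIQUE);
CREATE TABLE IF NOT EXISTS replicate_trials (
    id INTEGER PRIMARY KEY, identifier TEXT NOT NULL UNIQUE,
    strain_id INTEGER REFERENCES strains(id),
    media_id INTEGER REFERENCES media(id),
    environment_id INTEGER REFERENCES environments(id),
    is_blank INTEGER NOT NULL DEFAULT 0,
    blank_corrected INTEGER NOT NULL DEFAULT 0);
CREATE TABLE IF NOT EXISTS experiment_membership (
    experiment_id INTEGER NOT NULL REFERENCES experiments(id),
    replicate_id INTEGER NOT NULL REFERENCES replicate_trials(id),
    UNIQUE(experiment_id, replicate_id));
CREATE TABLE IF NOT EXISTS single_trials (
    id INTEGER PRIMARY KEY, replicate_id INTEGER NOT NULL REFERENCES replicate_trials(id),
    identifier TEXT NOT NULL UNIQUE, replicate_index INTEGER);
CREATE TABLE IF NOT EXISTS analyte_courses (
    id INTEGER PRIMARY KEY, trial_id INTEGER NOT NULL REFERENCES single_trials(id),
    analyte_name TEXT NOT NULL, analyte_type TEXT NOT NULL, unit TEXT,
    UNIQUE(trial_id, analyte_name));
CREATE TABLE IF NOT EXISTS time_points (
    course_id INTEGER NOT NULL REFERENCES analyte_courses(id),
    time_h REAL NOT NULL, value REAL,
    UNIQUE(course_id, time_h));
"""


@contextmanager
def _connect(path: str | Path):
    conn = sqlite3.connect(str(path))
    try:
        conn.execute("PRAGMA foreign_keys = ON")
        yield conn
    finally:
        conn.close()


def _check_version(conn: sqlite3.Connection) -> None:
    conn.executescript(_DDL)
    row = conn.execute("SELECT version FROM schema_version").fetchone()
    if row is None:
        conn.execute("INSERT INTO schema_version VALUES (?)", (SCHEMA_VERSION,))
    elif row[0] != SCHEMA_VERSION:
        raise StoreError(
            f"store schema version {row[0]} incompatible with {SCHEMA_VERSION}; "
            "no write performed"
        )


def _upsert(conn, table: str, columns: tuple[str, ...], values: tuple) -> tuple[int, bool]:
    """Insert-or-ignore keyed on the table's UNIQUE constraint; return (id, inserted)."""
    placeholders = ",".join("?" * len(values))
    cur = conn.execute(
        f"INSERT OR IGNORE INTO {table} ({','.join(columns)}) VALUES ({placeholders})",
        values,
    )
    inserted = cur.rowcount > 0
    where = " AND ".join(
        f"{c} IS ?" for c in columns
    )
    row = conn.execute(f"SELECT id FROM {table} WHERE {where}", values).fetchone()
    return row[0], inserted


def save_experiment(e: Experiment, path: str | Path) -> dict[str, int]:
    """Persist an experiment; returns the number of rows inserted per table.

    Idempotent: saving the same experiment twice inserts nothing the second
    time. Missing values are stored as SQL NULL. Any failure (including a
    schema-version mismatch) rolls the whole transaction back.
    """
    counts = {t: 0 for t in (
        "experiments", "replicate_trials", "single_trials",
        "analyte_courses", "time_points", "experiment_membership",
    )}
    with _connect(path) as conn:
        try:
            _check_version(conn)
            exp_id, ins = _upsert(conn, "experiments", ("label",), (e.label,))
            counts["experiments"] += ins
            for rep in e.replicates:
                strain_id, _ = _upsert(
                    conn, "strains", ("name", "knockouts", "plasmids"),
                    (rep.identifier.strain.name,
                     "|".join(rep.identifier.strain.knockouts),
                     "|".join(rep.identifier.strain.plasmids)),
                )
                comp = ";".join(
                    f"{n}:{c}:{u}" for n, c, u in rep.identifier.media.components
                )
                media_id, _ = _upsert(
                    conn, "media", ("name", "components"), (rep.identifier.media.name, comp)
                )
                env = rep.identifier.environment
                env_id, _ = _upsert(
                    conn, "environments", ("labware", "temperature", "shaking_speed"),
                    (env.labware, env.temperature, env.shaking_speed),
                )
                rep_key = serialize_identifier(rep.identifier)
                cur = conn.execute(
                    "INSERT OR IGNORE INTO replicate_trials "
                    "(identifier, strain_id, media_id, environment_id, is_blank, blank_corrected) "
                    "VALUES (?,?,?,?,?,?)",
                    (rep_key, strain_id, media_id, env_id,
                     int(rep.identifier.is_blank), int(rep.blank_corrected)),
                )
                counts["replicate_trials"] += cur.rowcount > 0
                rep_id = conn.execute(
                    "SELECT id FROM replicate_trials WHERE identifier = ?", (rep_key,)
                ).fetchone()[0]
                cur = conn.execute(
                    "INSERT OR IGNORE INTO experiment_membership VALUES (?,?)",
                    (exp_id, rep_id),
                )
                counts["experiment_membership"] += cur.rowcount > 0
                for single in rep.singles:
                    skey = serialize_identifier(single.identifier)
                    cur = conn.execute(
                        "INSERT OR IGNORE INTO single_trials "
                        "(replicate_id, identifier, replicate_index) VALUES (?,?,?)",
                        (rep_id, skey, single.identifier.replicate_index),
                    )
                    counts["single_trials"] += cur.rowcount > 0
                    trial_id = conn.execute(
                        "SELECT id FROM single_trials WHERE identifier = ?", (skey,)
                    ).fetchone()[0]
                    for name in sorted(single.courses):
                        course = single.courses[name]
                        cur = conn.execute(
                            "INSERT OR IGNORE INTO analyte_courses "
                            "(trial_id, analyte_name, analyte_type, unit) VALUES (?,?,?,?)",
                            (trial_id, name, course.analyte_type, course.unit),
                        )
                        counts["analyte_courses"] += cur.rowcount > 0
                        course_id = conn.execute(
                            "SELECT id FROM analyte_courses "
                            "WHERE trial_id = ? AND analyte_name = ?",
                            (trial_id, name),
                        ).fetchone()[0]
                        for t, v in zip(course.times, course.values):
                            cur = conn.execute(
                                "INSERT OR IGNORE INTO time_points VALUES (?,?,?)",
                                (course_id, float(t),
                                 None if math.isnan(float(v)) else float(v)),
                            )
                            counts["time_points"] += cur.rowcount > 0
            conn.commit()
        except Exception:
            conn.rollback()
            raise
    return counts


def list_labels(path: str | Path) -> list[str]:
    """All experiment labels present in a store."""
    if not Path(path).exists():
        return []
    with _connect(path) as conn:
        _check_version(conn)
        return [r[0] for r in conn.execute("SELECT label FROM experiments ORDER BY label")]


def load_experiment(path: str | Path, label: str) -> Experiment:
    """Reconstruct an experiment from the store; ``load(save(e)) == e``.

    Missing values come back as NaN at their original time points. Unknown
    labels raise a :class:`~fermkit.errors.StoreError` listing what the
    store does contain.
    """
    if not Path(path).exists():
        raise StoreError(f"store {path} does not exist")
    with _connect(path) as conn:
        _check_version(conn)
        row = conn.execute("SELECT id FROM experiments WHERE label = ?", (label,)).fetchone()
        if row is None:
            available = [r[0] for r in conn.execute("SELECT label FROM experiments ORDER BY label")]
            raise StoreError(f"no experiment {label!r} in store; available: {available}")
        exp_id = row[0]
        e = Experiment(label=label)
        reps = conn.execute(
            "SELECT rt.id, rt.identifier, rt.blank_corrected FROM replicate_trials rt "
            "JOIN experiment_membership m ON m.replicate_id = rt.id "
            "WHERE m.experiment_id = ? ORDER BY rt.identifier",
            (exp_id,),
        ).fetchall()
        for rep_id, rep_key, corrected in reps:
            rep = ReplicateTrial(
                identifier=parse_identifier(rep_key), blank_corrected=bool(corrected)
            )
            singles = conn.execute(
                "SELECT id, identifier FROM single_trials WHERE replicate_id = ? "
                "ORDER BY identifier",
                (rep_id,),
            ).fetchall()
            for trial_id, skey in singles:
                single = SingleTrial(identifier=parse_identifier(skey))
                courses = conn.execute(
                    "SELECT id, analyte_name, analyte_type, unit FROM analyte_courses "
                    "WHERE trial_id = ? ORDER BY analyte_name",
                    (trial_id,),
                ).fetchall()
                for course_id, name, atype, unit in courses:
                    pts = conn.execute(
                        "SELECT time_h, value FROM time_points WHERE course_id = ? "
                        "ORDER BY time_h",
                        (course_id,),
                    ).fetchall()
                    times = np.array([p[0] for p in pts], dtype=float)
                    values = np.array(
                        [float("nan") if p[1] is None else p[1] for p in pts], dtype=float
                    )
                    single.courses[name] = AnalyteCourse(
                        identifier=replace(single.identifier, analyte_name=name),
                        analyte_type=atype, times=times, values=values, unit=unit or "",
                    )
                rep.singles.append(single)
            e.replicates.append(rep)
    return e
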