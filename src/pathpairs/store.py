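"""SQLite-backed results store.

CV results, tuning trials and importance reports are persisted in a single
SQL database file with tables ``runs``, ``iterations``, ``metrics``,
``trials`` and ``importance``, and every table is exportable as CSV.  The
serialized run configuration is embedded with each run so a stored result
round-trips to an identical re-run.
"""

from __future__ import annotations

import json
import sqlite3
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .evaluate import CVResults, TuneResult
from .importance import ImportanceReport

__all__ = ["ResultStore"]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    run_id INTEGER PRIMARY KEY AUTOINCREMENT,
    kind TEXT NOT NULL,
    backend TEXT,
    config_json TEXT,
    created_utc TEXT
);
CREATE TABLE IF NOT EXISTS iterations (
    run_id INTEGER, iteration INTEGER, seed INTEGER,
    PRIMARY KEY (run_id, iteration)
);
CREATE TABLE IF NOT EXISTS metrics (
    run_id INTEGER, iteration INTEGER, pathway_id TEXT,
    accuracy REAL, precision REAL, recall REAL, f1 REAL, mcc REAL,
    tp INTEGER, fp INTEGER, fn INTEGER, tn INTEGER
);
CREATE TABLE IF NOT EXISTS trials (
    run_id INTEGER, trial INTEGER, hyperparameters_json TEXT,
    median_mcc REAL, n_iterations INTEGER, pruned INTEGER
);
CREATE TABLE IF NOT EXISTS importance (
    run_id INTEGER, feature_id TEXT, origin TEXT, mean_importance REAL,
    rank INTEGER, pathway_rank INTEGER, metabolite_rank INTEGER,
    associated_pathways TEXT
);
"""


class ResultStore:
    """Thin wrapper over a sqlite3 results database."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "ResultStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _new_run(self, kind: str, backend: str | None, config: dict) -> int:
        cur = self.conn.execute(
            "INSERT INTO runs (kind, backend, config_json, created_utc) "
            "VALUES (?, ?, ?, ?)",
            (kind, backend, json.dumps(config, default=str),
             datetime.now(timezone.utc).isoformat()),
        )
        self.conn.commit()
        return int(cur.lastrowid)

    def run_config(self, run_id: int) -> dict:
        row = self.conn.execute(
            "SELECT config_json FROM runs WHERE run_id = ?", (run_id,)
        ).fetchone()
        if row is None:
            raise KeyError(f"no run {run_id}")
        return json.loads(row[0])

    def save_cv(self, results: CVResults, backend: str, config: dict) -> int:
        run_id = self._new_run("cv", backend, config)
        recs = results.records
        its = recs[["iteration", "seed"]].drop_duplicates()
        self.conn.executemany(
            "INSERT INTO iterations VALUES (?, ?, ?)",
            [(run_id, int(i), int(s)) for i, s in its.itertuples(index=False)],
        )
        self.conn.executemany(
            "INSERT INTO metrics VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            [
                (run_id, int(r.iteration), r.pathway_id, r.accuracy,
                 r.precision, r.recall, r.f1, r.mcc,
                 int(r.tp), int(r.fp), int(r.fn), int(r.tn))
                for r in recs.itertuples(index=False)
            ],
        )
        self.conn.commit()
        return run_id

    def save_tune(self, result: TuneResult, backend: str, config: dict) -> int:
        run_id = self._new_run("tune", backend, config)
        self.conn.executemany(
            "INSERT INTO trials VALUES (?, ?, ?, ?, ?, ?)",
            [
                (run_id, int(r.trial), json.dumps(r.hyperparameters),
                 float(r.median_mcc), int(r.n_iterations), int(r.pruned))
                for r in result.trials.itertuples(index=False)
            ],
        )
        self.conn.commit()
        return run_id

    def save_importance(self, report: ImportanceReport, run_id: int) -> None:
        t = report.table
        rows = []
        for r in t.itertuples(index=False):
            assoc = getattr(r, "associated_pathways", None)
            if isinstance(assoc, (set, frozenset)):
                assoc = ";".join(sorted(assoc))
            rows.append(
                (run_id, r.feature_id, r.origin, float(r.mean_importance),
                 int(r.rank),
                 None if pd.isna(getattr(r, "pathway_rank", None))
                 else int(r.pathway_rank),
                 None if pd.isna(getattr(r, "metabolite_rank", None))
                 else int(r.metabolite_rank),
                 assoc)
            )
        self.conn.executemany(
            "INSERT INTO importance VALUES (?, ?, ?, ?, ?, ?, ?, ?)", rows
        )
        self.conn.commit()

    def metrics_frame(self, run_id: int) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM metrics WHERE run_id = ?", self.conn, params=(run_id,)
        )

    def export_csv(self, table: str, path: str | Path) -> None:
        if table not in ("runs", "iterations", "metrics", "trials", "importance"):
            raise KeyError(f"unknown table {table!r}")
        pd.read_sql_query(f"SELECT * FROM {table}", self.conn).to_csv(
            path, index=False
        )

    def latest_run(self, kind: str = "cv") -> int:
        row = self.conn.execute(
            "SELECT MAX(run_id) FROM runs WHERE kind = ?", (kind,)
        ).fetchone()
        if row[0] is None:
            raise KeyError(f"no {kind} runs stored")
        return int(row[0])
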