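"""Persistent store for extracted rule models and its five queries.

Backing store is a single-file SQLite database with four tables —
``runs``, ``models``, ``conjunctions``, ``literals`` — linked by foreign
keys. Rejected models are stored for audit but are invisible to every
query. Exports are plain CSV (one file per query) or a single JSON dump
that re-imports to an equivalent knowledge base.

Queries:

* features list — genes and the number of accepted models they occur in;
* conjunctions — each stored conjunction with correct/incorrect training
  cover counts and percentages;
* rules — one row per accepted model with its scores;
* literal statistics — threshold aggregates per (gene, operator);
* feature pairs — gene pairs co-occurring in the same model.
"""

from __future__ import annotations

import csv
import itertools
import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Union

import numpy as np

from camur.expression_io import ExpressionMatrix, class_summary, matrix_fingerprint
from camur.engine import RunResult

_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    id INTEGER PRIMARY KEY,
    dataset_fingerprint TEXT NOT NULL,
    n_samples INTEGER NOT NULL,
    n_genes INTEGER NOT NULL,
    class_summary TEXT NOT NULL,          -- JSON [[label, count, pct], ...]
    mode TEXT NOT NULL,
    max_iterations INTEGER NOT NULL,
    min_f_measure REAL NOT NULL,
    seed INTEGER NOT NULL,
    stop_reason TEXT NOT NULL,
    manifest TEXT NOT NULL                -- JSON replay manifest
);
CREATE TABLE IF NOT EXISTS models (
    id INTEGER PRIMARY KEY,
    run_id INTEGER NOT NULL REFERENCES runs(id),
    iteration INTEGER NOT NULL,
    accepted INTEGER NOT NULL,
    positive_class TEXT NOT NULL,
    default_class TEXT NOT NULL,
    rule_text TEXT NOT NULL,
    precision REAL NOT NULL,
    recall REAL NOT NULL,
    f_measure REAL NOT NULL,
    accuracy REAL NOT NULL,
    UNIQUE (run_id, iteration)
);
CREATE TABLE IF NOT EXISTS conjunctions (
    id INTEGER PRIMARY KEY,
    model_id INTEGER NOT NULL REFERENCES models(id),
    ordinal INTEGER NOT NULL,
    text TEXT NOT NULL,
    correct INTEGER NOT NULL,
    incorrect INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS literals (
    id INTEGER PRIMARY KEY,
    conjunction_id INTEGER NOT NULL REFERENCES conjunctions(id),
    ordinal INTEGER NOT NULL,
    gene TEXT NOT NULL,
    op TEXT NOT NULL,
    threshold REAL NOT NULL
);
"""

QUERY_NAMES = ("features", "conjunctions", "rules", "literal-stats", "pairs")


@dataclass
class QueryResult:
    columns: list[str]
    rows: list[tuple]

    def to_csv(self, dest: Union[str, Path, IO[str]]) -> None:
        if hasattr(dest, "write"):
            self._write(dest)
        else:
            with open(dest, "w", newline="", encoding="utf-8") as fh:
                self._write(fh)

    def _write(self, fh: IO[str]) -> None:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(self.columns)
        writer.writerows(self.rows)

    def to_records(self) -> list[dict]:
        return [dict(zip(self.columns, row)) for row in self.rows]


class KnowledgeBase:
    """SQLite-backed store of runs, models, conjunctions and literals."""

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "KnowledgeBase":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writing ----------------------------------------------------------

    def add_run(self, run_result: RunResult, training_matrix: ExpressionMatrix,
                run_id: Optional[int] = None) -> int:
        """Store a run; accepted models become query-visible, rejected ones
        are flagged. Re-using an explicit run id raises."""
        summary = class_summary(training_matrix)
        cur = self._conn.cursor()
        try:
            cur.execute(
                "INSERT INTO runs (id, dataset_fingerprint, n_samples, n_genes,"
                " class_summary, mode, max_iterations, min_f_measure, seed,"
                " stop_reason, manifest) VALUES (?,?,?,?,?,?,?,?,?,?,?)",
                (
                    run_id,
                    matrix_fingerprint(training_matrix),
                    training_matrix.n_samples,
                    training_matrix.n_genes,
                    json.dumps([[c.label, c.count, c.percentage] for c in summary.classes]),
                    run_result.config.mode,
                    run_result.config.max_iterations,
                    run_result.config.min_f_measure,
                    run_result.config.seed,
                    run_result.stop_reason,
                    run_result.manifest_json(),
                ),
            )
        except sqlite3.IntegrityError as exc:
            raise ValueError(f"run id {run_id} already stored") from exc
        rid = cur.lastrowid if run_id is None else run_id

        key = None
        for rec in run_result.records:
            cur.execute(
                "INSERT INTO models (run_id, iteration, accepted, positive_class,"
                " default_class, rule_text, precision, recall, f_measure, accuracy)"
                " VALUES (?,?,?,?,?,?,?,?,?,?)",
                (
                    rid, rec.index, int(rec.accepted),
                    rec.model.positive_class, rec.model.default_class,
                    rec.model.text,
                    rec.cv_metrics.precision, rec.cv_metrics.recall,
                    rec.cv_metrics.f_measure, rec.cv_metrics.accuracy,
                ),
            )
            model_id = cur.lastrowid
            key = rec.model.positive_class.casefold()
            y = np.array([lab.casefold() == key for lab in training_matrix.labels])
            for ordinal, conj in enumerate(rec.model.conjunctions):
                mask = conj.covers_matrix(training_matrix)
                correct = int(np.count_nonzero(mask & y))
                incorrect = int(np.count_nonzero(mask & ~y))
                cur.execute(
                    "INSERT INTO conjunctions (model_id, ordinal, text, correct,"
                    " incorrect) VALUES (?,?,?,?,?)",
                    (model_id, ordinal, conj.text, correct, incorrect),
                )
                conj_id = cur.lastrowid
                for lit_ord, lit in enumerate(conj.literals):
                    cur.execute(
                        "INSERT INTO literals (conjunction_id, ordinal, gene, op,"
                        " threshold) VALUES (?,?,?,?,?)",
                        (conj_id, lit_ord, lit.gene, lit.op, lit.threshold),
                    )
        self._conn.commit()
        return rid

    # -- query helpers ----------------------------------------------------

    def _run_clause(self, run_id: Optional[int]) -> tuple[str, tuple]:
        if run_id is None:
            return "", ()
        return " AND m.run_id = ?", (run_id,)

    def run_ids(self) -> list[int]:
        return [r[0] for r in self._conn.execute("SELECT id FROM runs ORDER BY id")]

    def run_info(self, run_id: int) -> dict:
        row = self._conn.execute(
            "SELECT id, dataset_fingerprint, n_samples, n_genes, class_summary,"
            " mode, max_iterations, min_f_measure, seed, stop_reason, manifest"
            " FROM runs WHERE id = ?", (run_id,)
        ).fetchone()
        if row is None:
            raise KeyError(f"no run with id {run_id}")
        keys = ("id", "dataset_fingerprint", "n_samples", "n_genes",
                "class_summary", "mode", "max_iterations", "min_f_measure",
                "seed", "stop_reason", "manifest")
        info = dict(zip(keys, row))
        info["class_summary"] = json.loads(info["class_summary"])
        info["manifest"] = json.loads(info["manifest"])
        return info

    # -- the five queries -------------------------------------------------

    def query_features_list(self, run_id: Optional[int] = None) -> QueryResult:
        """Genes and how many accepted models they appear in (once per model)."""
        clause, args = self._run_clause(run_id)
        rows = self._conn.execute(
            "SELECT l.gene, COUNT(DISTINCT m.id) AS occ"
            " FROM literals l"
            " JOIN conjunctions c ON l.conjunction_id = c.id"
            " JOIN models m ON c.model_id = m.id"
            f" WHERE m.accepted = 1{clause}"
            " GROUP BY l.gene ORDER BY occ DESC, l.gene ASC",
            args,
        ).fetchall()
        return QueryResult(columns=["gene", "occurrences"], rows=[tuple(r) for r in rows])

    def query_conjunctions(self, run_id: Optional[int] = None) -> QueryResult:
        """Per-model conjunction rows with correct/incorrect cover counts,
        percentages over covered samples, and the number of accepted models
        sharing the identical conjunction text."""
        clause, args = self._run_clause(run_id)
        rows = self._conn.execute(
            "SELECT c.text, c.correct, c.incorrect,"
            " (SELECT COUNT(DISTINCT m2.id) FROM conjunctions c2"
            "   JOIN models m2 ON c2.model_id = m2.id"
            f"  WHERE m2.accepted = 1 AND c2.text = c.text{clause.replace('m.', 'm2.')})"
            " FROM conjunctions c JOIN models m ON c.model_id = m.id"
            f" WHERE m.accepted = 1{clause}"
            " ORDER BY c.text ASC, m.id ASC, c.ordinal ASC",
            args + args,
        ).fetchall()
        out = []
        for text, correct, incorrect, n_models in rows:
            covered = correct + incorrect
            pct_c = round(100.0 * correct / covered, 2) if covered else 0.0
            pct_i = round(100.0 * incorrect / covered, 2) if covered else 0.0
            out.append((text, correct, incorrect, pct_c, pct_i, n_models))
        return QueryResult(
            columns=["conjunction", "correct", "incorrect",
                     "pct_correct", "pct_incorrect", "n_models"],
            rows=out,
        )

    def query_rules(self, run_id: Optional[int] = None) -> QueryResult:
        """One row per accepted model, best F-measure first."""
        clause, args = self._run_clause(run_id)
        rows = self._conn.execute(
            "SELECT m.rule_text, m.precision, m.accuracy, m.f_measure"
            " FROM models m"
            f" WHERE m.accepted = 1{clause}"
            " ORDER BY m.f_measure DESC, m.rule_text ASC, m.id ASC",
            args,
        ).fetchall()
        return QueryResult(
            columns=["rule", "precision", "accuracy", "f_measure"],
            rows=[tuple(r) for r in rows],
        )

    def query_literal_stats(self, run_id: Optional[int] = None) -> QueryResult:
        """Literal counts and threshold min/mean/max grouped by (gene, op)."""
        clause, args = self._run_clause(run_id)
        rows = self._conn.execute(
            "SELECT l.gene, l.op, COUNT(*), MIN(l.threshold), AVG(l.threshold),"
            " MAX(l.threshold)"
            " FROM literals l"
            " JOIN conjunctions c ON l.conjunction_id = c.id"
            " JOIN models m ON c.model_id = m.id"
            f" WHERE m.accepted = 1{clause}"
            " GROUP BY l.gene, l.op ORDER BY l.gene ASC, l.op ASC",
            args,
        ).fetchall()
        return QueryResult(
            columns=["gene", "op", "n_literals", "min_threshold",
                     "mean_threshold", "max_threshold"],
            rows=[tuple(r) for r in rows],
        )

    def query_feature_pairs(self, run_id: Optional[int] = None) -> QueryResult:
        """Unordered gene pairs present in the same accepted model, counted
        per model, most frequent first."""
        clause, args = self._run_clause(run_id)
        rows = self._conn.execute(
            "SELECT m.id, l.gene FROM literals l"
            " JOIN conjunctions c ON l.conjunction_id = c.id"
            " JOIN models m ON c.model_id = m.id"
            f" WHERE m.accepted = 1{clause}"
            " GROUP BY m.id, l.gene",
            args,
        ).fetchall()
        genes_per_model: dict[int, set[str]] = {}
        for model_id, gene in rows:
            genes_per_model.setdefault(model_id, set()).add(gene)
        counts: dict[tuple[str, str], int] = {}
        for genes in genes_per_model.values():
            for a, b in itertools.combinations(sorted(genes), 2):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return QueryResult(
            columns=["gene1", "gene2", "co_occurrences"],
            rows=[(a, b, n) for (a, b), n in ordered],
        )

    def query(self, name: str, run_id: Optional[int] = None) -> QueryResult:
        dispatch = {
            "features": self.query_features_list,
            "conjunctions": self.query_conjunctions,
            "rules": self.query_rules,
            "literal-stats": self.query_literal_stats,
            "pairs": self.query_feature_pairs,
        }
        if name not in dispatch:
            raise KeyError(f"unknown query {name!r}; choose from {QUERY_NAMES}")
        return dispatch[name](run_id)

    # -- export / import --------------------------------------------------

    def export_csv(self, out_dir: Union[str, Path]) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in QUERY_NAMES:
            path = out_dir / f"{name.replace('-', '_')}.csv"
            self.query(name).to_csv(path)
            written.append(path)
        return written

    def export_json(self, dest: Union[str, Path, IO[str], None] = None) -> str:
        """Full dump: every run with its models, conjunctions and literals,
        plus all five query outputs. Deterministic for a given store."""
        doc = {"runs": [], "queries": {}}
        for rid in self.run_ids():
            info = self.run_info(rid)
            models = []
            for mid, iteration, accepted, pos, dflt, text, prec, rec, f, acc in \
                    self._conn.execute(
                        "SELECT id, iteration, accepted, positive_class,"
                        " default_class, rule_text, precision, recall, f_measure,"
                        " accuracy FROM models WHERE run_id = ? ORDER BY iteration",
                        (rid,)):
                conjs = []
                for cid, ordinal, ctext, correct, incorrect in self._conn.execute(
                        "SELECT id, ordinal, text, correct, incorrect"
                        " FROM conjunctions WHERE model_id = ? ORDER BY ordinal",
                        (mid,)):
                    lits = self._conn.execute(
                        "SELECT gene, op, threshold FROM literals"
                        " WHERE conjunction_id = ? ORDER BY ordinal", (cid,)
                    ).fetchall()
                    conjs.append({
                        "ordinal": ordinal, "text": ctext,
                        "correct": correct, "incorrect": incorrect,
                        "literals": [
                            {"gene": g, "op": o, "threshold": t} for g, o, t in lits
                        ],
                    })
                models.append({
                    "iteration": iteration, "accepted": bool(accepted),
                    "positive_class": pos, "default_class": dflt,
                    "rule_text": text,
                    "metrics": {"precision": prec, "recall": rec,
                                "f_measure": f, "accuracy": acc},
                    "conjunctions": conjs,
                })
            info["models"] = models
            doc["runs"].append(info)
        for name in QUERY_NAMES:
            result = self.query(name)
            doc["queries"][name] = {"columns": result.columns,
                                    "rows": [list(r) for r in result.rows]}
        text = json.dumps(doc, sort_keys=True, indent=2)
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)
            else:
                Path(dest).write_text(text, encoding="utf-8")
        return text


def import_json(source: Union[str, Path, IO[str]],
                path: Union[str, Path] = ":memory:") -> KnowledgeBase:
    """Rebuild a knowledge base from :meth:`KnowledgeBase.export_json` output."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    kb = KnowledgeBase(path)
    cur = kb._conn.cursor()
    for run in doc["runs"]:
        cur.execute(
            "INSERT INTO runs (id, dataset_fingerprint, n_samples, n_genes,"
            " class_summary, mode, max_iterations, min_f_measure, seed,"
            " stop_reason, manifest) VALUES (?,?,?,?,?,?,?,?,?,?,?)",
            (
                run["id"], run["dataset_fingerprint"], run["n_samples"],
                run["n_genes"], json.dumps(run["class_summary"]), run["mode"],
                run["max_iterations"], run["min_f_measure"], run["seed"],
                run["stop_reason"], json.dumps(run["manifest"], sort_keys=True,
                                               indent=2),
            ),
        )
        for model in run["models"]:
            met = model["metrics"]
            cur.execute(
                "INSERT INTO models (run_id, iteration, accepted, positive_class,"
                " default_class, rule_text, precision, recall, f_measure, accuracy)"
                " VALUES (?,?,?,?,?,?,?,?,?,?)",
                (run["id"], model["iteration"], int(model["accepted"]),
                 model["positive_class"], model["default_class"],
                 model["rule_text"], met["precision"], met["recall"],
                 met["f_measure"], met["accuracy"]),
            )
            mid = cur.lastrowid
            for conj in model["conjunctions"]:
                cur.execute(
                    "INSERT INTO conjunctions (model_id, ordinal, text, correct,"
                    " incorrect) VALUES (?,?,?,?,?)",
                    (mid, conj["ordinal"], conj["text"], conj["correct"],
                     conj["incorrect"]),
                )
                cid = cur.lastrowid
                for lit_ord, lit in enumerate(conj["literals"]):
                    cur.execute(
                        "INSERT INTO literals (conjunction_id, ordinal, gene, op,"
                        " threshold) VALUES (?,?,?,?,?)",
                        (cid, lit_ord, lit["gene"], lit["op"], lit["threshold"]),
                    )
    kb._conn.commit()
    return kb
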