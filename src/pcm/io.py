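"""CSV / JSON / YAML readers and writers.

Matrix dialect: a header row of disease ids, a first column of patient
ids, numeric cells, and empty cells for missing entries.  Index tables
serialize to JSON as ``{table_id: {patient_id: [W_1, ..., W_r]}}`` —
small integers only, the one artifact meant to cross the privacy
boundary.  Numbers are written with Python's shortest round-trip
representation so outputs are bit-stable across platforms.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .clustering import ClusterAssignment, ConsistencyError, SimilarityGraph
from .lsh import HYPERPLANE_DISTRIBUTIONS, IndexTable, LSHConfig
from .matrix import MISSING_POLICIES, PatientHealthMatrix


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


# ---------------------------------------------------------------------------
# matrix CSV


def read_matrix(path: str | Path) -> PatientHealthMatrix:
    """Read a patient-by-disease CSV (empty cell = missing)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ParseError(f"{path}: header must name at least one disease column")
        disease_ids = [h.strip() for h in header[1:]]
        n = len(disease_ids)
        patient_ids: list[str] = []
        rows: list[list[float]] = []
        for row_num, row in enumerate(reader, start=2):  # 1-based incl. header
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != n + 1:
                raise ParseError(
                    f"{path}: ragged row {row_num}: expected {n + 1} fields, got {len(row)}"
                )
            patient_ids.append(row[0].strip())
            vals = []
            for col_num, cell in enumerate(row[1:], start=2):
                cell = cell.strip()
                if cell == "":
                    vals.append(float("nan"))
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at row {row_num}, "
                        f"column {col_num} ({disease_ids[col_num - 2]!r})"
                    ) from None
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no patient rows")
    if len(set(patient_ids)) != len(patient_ids):
        dup = next(p for p in patient_ids if patient_ids.count(p) > 1)
        raise ParseError(f"{path}: duplicate patient id {dup!r}")
    if len(set(disease_ids)) != len(disease_ids):
        dup = next(d for d in disease_ids if disease_ids.count(d) > 1)
        raise ParseError(f"{path}: duplicate disease id {dup!r}")
    try:
        return PatientHealthMatrix(patient_ids, disease_ids, np.array(rows))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_matrix(matrix: PatientHealthMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", *matrix.disease_ids])
        for i, pid in enumerate(matrix.patient_ids):
            row: list[str] = [pid]
            for j in range(matrix.n):
                row.append(repr(float(matrix.values[i, j])) if matrix.observed_mask[i, j] else "")
            writer.writerow(row)


# ---------------------------------------------------------------------------
# index tables JSON


def serialize_tables(tables: Sequence[IndexTable], path: str | Path) -> None:
    payload = {
        str(t.table_id): {pid: list(key) for pid, key in t.entries.items()} for t in tables
    }
    # insertion order (= patient order) is preserved so that clustering from
    # the loaded file numbers groups exactly like clustering in memory
    Path(path).write_text(json.dumps(payload, indent=1))


def load_tables(path: str | Path) -> list[IndexTable]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON: {exc}") from None
    if not isinstance(payload, dict) or not payload:
        raise ParseError(f"{path}: expected a nonempty object of index tables")
    tables = []
    for table_id in sorted(payload, key=int):
        entries_raw = payload[table_id]
        if not isinstance(entries_raw, dict):
            raise ParseError(f"{path}: table {table_id} is not an object")
        entries = {}
        for pid, key in entries_raw.items():
            if not isinstance(key, list) or not all(isinstance(w, int) for w in key):
                raise ParseError(
                    f"{path}: key for patient {pid!r} in table {table_id} "
                    "must be a list of integers"
                )
            entries[str(pid)] = tuple(key)
        tables.append(IndexTable(table_id=int(table_id), entries=entries))
    first = set(tables[0].entries)
    for t in tables[1:]:
        missing = first ^ set(t.entries)
        if missing:
            raise ConsistencyError(
                f"{path}: table {t.table_id} patient set differs from table "
                f"{tables[0].table_id} (e.g. {sorted(missing)[0]!r})"
            )
    return tables


# ---------------------------------------------------------------------------
# clustering outputs


def write_clusters(assignment: ClusterAssignment, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "group_id"])
        for pid, gid in assignment.labels.items():
            writer.writerow([pid, gid])


def write_edges(graph: SimilarityGraph, path: str | Path) -> None:
    order = {pid: i for i, pid in enumerate(graph.patient_ids)}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_a", "patient_b"])
        for a, b in sorted(graph.edges, key=lambda e: (order[e[0]], order[e[1]])):
            writer.writerow([a, b])


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a full run (hashing plus evaluation)."""

    lsh: LSHConfig = field(default_factory=LSHConfig)
    missing_policy: str = "zero"
    mask_fraction: float = 0.2
    methods: tuple[str, ...] = ("pcm", "upcc")
    seeds: tuple[int, ...] = (0,)
    top_n: int = 10
    log_level: str = "INFO"


_LSH_KEYS = {"c", "r", "k", "seed", "hyperplane_distribution"}
_RUN_KEYS = {"missing_policy", "mask_fraction", "methods", "seeds", "top_n", "log_level"}


def config_from_mapping(data: dict[str, Any], source: str = "<config>") -> RunConfig:
    if not isinstance(data, dict):
        raise ParseError(f"{source}: configuration must be a mapping")
    unknown = set(data) - _LSH_KEYS - _RUN_KEYS
    if unknown:
        raise ParseError(
            f"{source}: unknown configuration key(s) {sorted(unknown)}; "
            f"expected keys from {sorted(_LSH_KEYS | _RUN_KEYS)}"
        )
    lsh_kwargs = {key: data[key] for key in _LSH_KEYS if key in data}
    if "hyperplane_distribution" in lsh_kwargs and (
        lsh_kwargs["hyperplane_distribution"] not in HYPERPLANE_DISTRIBUTIONS
    ):
        raise ParseError(
            f"{source}: hyperplane_distribution must be one of {HYPERPLANE_DISTRIBUTIONS}"
        )
    run_kwargs: dict[str, Any] = {key: data[key] for key in _RUN_KEYS if key in data}
    if "methods" in run_kwargs:
        run_kwargs["methods"] = tuple(run_kwargs["methods"])
    if "seeds" in run_kwargs:
        seeds = run_kwargs["seeds"]
        run_kwargs["seeds"] = tuple(int(s) for s in (seeds if isinstance(seeds, list) else [seeds]))
    if run_kwargs.get("missing_policy") not in (None, *MISSING_POLICIES):
        raise ParseError(f"{source}: missing_policy must be one of {MISSING_POLICIES}")
    try:
        return RunConfig(lsh=LSHConfig(**lsh_kwargs), **run_kwargs)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{source}: {exc}") from None


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration, rejecting unknown keys."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: malformed config: {exc}") from None
    return config_from_mapping(data, source=str(path))
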