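"""Patient clustering from index tables alone.

Two patients have similarity degree 1 when their full index keys are
equal in at least one of the k tables.  That pairwise relation is not
transitive, so "put similar patients in the same group" is realized as
the transitive closure: clusters are the connected components of the
collision graph, computed with union-find.  Everything here consumes
only ``IndexTable`` / ``SimilarityGraph`` objects — raw health values
never enter this module, which is the method's privacy boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .lsh import IndexTable, LSHConfig, index_patients
from .matrix import PatientHealthMatrix


class ConsistencyError(ValueError):
    """Index tables do not cover the same patient set."""


@dataclass(frozen=True)
class SimilarityGraph:
    """Undirected collision graph: an edge per patient pair with S = 1.

    Edges are stored once, ordered by patient position; no self-loops.
    """

    patient_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class ClusterAssignment:
    """Group labels: patient id -> contiguous group id starting at 0.

    Groups are numbered by the position of their first patient, so the
    labeling is reproducible for a fixed patient order.
    """

    labels: dict[str, int]
    n_groups: int

    def groups(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_groups)]
        for pid, g in self.labels.items():
            out[g].append(pid)
        return out


def _check_same_patients(tables: Sequence[IndexTable]) -> tuple[str, ...]:
    if not tables:
        raise ConsistencyError("at least one index table is required")
    patients = tuple(tables[0].entries)
    pset = set(patients)
    for t in tables[1:]:
        if set(t.entries) != pset:
            raise ConsistencyError(
                f"table {t.table_id} covers a different patient set than table {tables[0].table_id}"
            )
    return patients


def similarity_degree(tables: Sequence[IndexTable], p_i: str, p_j: str) -> int:
    """1 iff the two patients' keys are equal in any table, else 0."""
    for table in tables:
        if table.key_of(p_i) == table.key_of(p_j):
            return 1
    return 0


def candidate_pairs(tables: Sequence[IndexTable]) -> SimilarityGraph:
    """All pairs with S = 1, found by enumerating within-bucket pairs.

    Equivalent to the all-pairs similarity scan, but touches only
    patients that actually share a bucket.
    """
    patients = _check_same_patients(tables)
    order = {pid: i for i, pid in enumerate(patients)}
    edges: set[tuple[str, str]] = set()
    for table in tables:
        for members in table.buckets.values():
            if len(members) < 2:
                continue
            ranked = sorted(members, key=order.__getitem__)
            for a in range(len(ranked)):
                for b in range(a + 1, len(ranked)):
                    edges.add((ranked[a], ranked[b]))
    return SimilarityGraph(patient_ids=patients, edges=frozenset(edges))


class _UnionFind:
    """Disjoint sets over 0..n-1 with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def cluster_patients(graph: SimilarityGraph) -> ClusterAssignment:
    """Connected components of the collision graph, via union-find."""
    patients = graph.patient_ids
    if not patients:
        raise ValueError("graph must cover at least one patient")
    order = {pid: i for i, pid in enumerate(patients)}
    uf = _UnionFind(len(patients))
    for a, b in graph.edges:
        uf.union(order[a], order[b])
    root_to_group: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, pid in enumerate(patients):
        root = uf.find(i)
        if root not in root_to_group:
            root_to_group[root] = len(root_to_group)
        labels[pid] = root_to_group[root]
    return ClusterAssignment(labels=labels, n_groups=len(root_to_group))


def cluster_from_tables(tables: Sequence[IndexTable]) -> ClusterAssignment:
    """Clusters straight from index tables (hashes only; no raw data)."""
    return cluster_patients(candidate_pairs(tables))


def pcm_pipeline(
    matrix: PatientHealthMatrix,
    config: LSHConfig,
    missing_policy: str = "zero",
) -> ClusterAssignment:
    """End-to-end PCM: sample hyperplanes, index, collide, cluster."""
    tables = index_patients(matrix, config, missing_policy=missing_policy)
    return cluster_from_tables(tables)
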