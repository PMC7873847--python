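"""The typed, weighted tumor-biomarker knowledge graph and its
explanation-path enumeration.

Nodes carry one of four types (tumor, biomarker, drug, adr); undirected
edges connect nodes of *different* types and are weighted by the
naive-Bayes importance of the relation.  Larger weight means stronger
association; weights are never inverted into metric distances.
Explanation paths are simple drug-to-ADR paths whose interior nodes are
mechanistic intermediates (biomarkers or tumors), found by bounded
depth-first search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .corpus import NODE_TYPES
from .exceptions import (
    ConflictError,
    FormatError,
    UnknownEntityError,
    ValidationError,
)
from .naive_bayes import ImportanceScore

#: Node types allowed in the interior of an explanation path.
INTERIOR_TYPES = frozenset({"biomarker", "tumor"})


@dataclass(frozen=True)
class ExplanationPath:
    """A simple path from a drug to an ADR with per-step edge weights."""

    nodes: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.weights) + 1:
            raise ValidationError("path needs one weight per edge")

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    @property
    def bottleneck(self) -> float:
        """The weakest edge on the path (its explanatory bottleneck)."""
        return min(self.weights)


class TBKG:
    """Typed weighted undirected graph over tumor/biomarker/drug/adr nodes.

    Thin wrapper around :class:`networkx.Graph` that enforces the type
    discipline: no self loops, no same-type edges, at most one edge per
    pair, and idempotent re-insertion at equal weight.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_entity(self, concept_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValidationError(f"unknown node type {node_type!r}")
        existing = self._g.nodes.get(concept_id)
        if existing is not None and existing["node_type"] != node_type:
            raise ValidationError(
                f"node {concept_id!r} already present with type "
                f"{existing['node_type']!r}, cannot re-add as {node_type!r}"
            )
        self._g.add_node(concept_id, node_type=node_type)

    def add_relation(
        self, u: str, u_type: str, v: str, v_type: str, weight: float
    ) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r} rejected")
        if u_type == v_type:
            raise ValidationError(
                f"edge {u!r}-{v!r} connects two {u_type!r} nodes; "
                "edges must join distinct types"
            )
        self.add_entity(u, u_type)
        self.add_entity(v, v_type)
        if self._g.has_edge(u, v):
            old = self._g.edges[u, v]["weight"]
            if not math.isclose(old, weight, rel_tol=1e-9, abs_tol=1e-12):
                raise ConflictError(
                    f"edge {u!r}-{v!r} inserted with conflicting weights "
                    f"{old!r} and {weight!r}"
                )
            return
        self._g.add_edge(u, v, weight=float(weight))

    # -- queries ----------------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node_type(self, concept_id: str) -> str:
        if concept_id not in self._g:
            raise UnknownEntityError(f"node {concept_id!r} not in graph")
        return self._g.nodes[concept_id]["node_type"]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(
            n for n, t in self._g.nodes(data="node_type") if t == node_type
        )

    def edge_weight(self, u: str, v: str) -> float | None:
        if self._g.has_edge(u, v):
            return float(self._g.edges[u, v]["weight"])
        return None

    def neighbors(self, n: str) -> list[str]:
        return sorted(self._g.neighbors(n))

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u, v, w in self._g.edges(data="weight"):
            a, b = sorted((u, v))
            out.append((a, b, float(w)))
        return sorted(out)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TBKG):
            return NotImplemented
        return (
            dict(self._g.nodes(data="node_type")) == dict(other._g.nodes(data="node_type"))
            and self.edges() == other.edges()
        )

    # -- path enumeration -------------------------------------------------

    def enumerate_paths(
        self, drug: str, adr: str, max_len: int = 3
    ) -> list[ExplanationPath]:
        """All simple drug-to-ADR paths of at most *max_len* edges whose
        interior nodes are biomarkers or tumors.

        Depth-first search with the type constraint applied during
        expansion; output is deterministic: shorter paths first, then
        lexicographic on node ids.
        """
        for node, role in ((drug, "drug"), (adr, "adr")):
            if node not in self._g:
                raise UnknownEntityError(f"{role} node {node!r} not in graph")
        found: list[tuple[str, ...]] = []
        path = [drug]
        on_path = {drug}

        def dfs(current: str) -> None:
            if len(path) - 1 >= max_len:
                return
            for nxt in sorted(self._g.neighbors(current)):
                if nxt in on_path:
                    continue
                if nxt == adr:
                    found.append(tuple(path) + (adr,))
                    continue
                if self._g.nodes[nxt]["node_type"] not in INTERIOR_TYPES:
                    continue
                path.append(nxt)
                on_path.add(nxt)
                dfs(nxt)
                on_path.discard(nxt)
                path.pop()

        dfs(drug)
        found.sort(key=lambda p: (len(p), p))
        return [
            ExplanationPath(
                nodes=p,
                weights=tuple(
                    float(self._g.edges[p[i], p[i + 1]]["weight"])
                    for i in range(len(p) - 1)
                ),
            )
            for p in found
        ]

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write nodes.tsv / edges.tsv; weights keep full precision."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            sorted(self._g.nodes(data="node_type")),
            columns=["concept_id", "node_type"],
        )
        nodes.to_csv(directory / "nodes.tsv", sep="\t", index=False)
        with open(directory / "edges.tsv", "w", encoding="utf-8") as fh:
            fh.write("source_id\tsource_type\ttarget_id\ttarget_type\tweight\n")
            for u, v, w in self.edges():
                fh.write(
                    f"{u}\t{self.node_type(u)}\t{v}\t{self.node_type(v)}\t{w!r}\n"
                )

    @classmethod
    def load(cls, directory: str | Path) -> "TBKG":
        directory = Path(directory)
        g = cls()
        try:
            nodes = pd.read_csv(directory / "nodes.tsv", sep="\t", dtype=str)
            edges = pd.read_csv(directory / "edges.tsv", sep="\t", dtype=str)
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise FormatError(f"malformed graph directory {directory}: {exc}") from exc
        for col in ("concept_id", "node_type"):
            if col not in nodes.columns:
                raise FormatError(f"nodes.tsv missing column {col!r}")
        for _, row in nodes.iterrows():
            g.add_entity(row["concept_id"], row["node_type"])
        needed = {"source_id", "source_type", "target_id", "target_type", "weight"}
        if not needed <= set(edges.columns):
            raise FormatError(f"edges.tsv missing columns {sorted(needed - set(edges.columns))}")
        for _, row in edges.iterrows():
            try:
                w = float(row["weight"])
            except ValueError as exc:
                raise FormatError(f"bad edge weight {row['weight']!r}") from exc
            g.add_relation(
                row["source_id"], row["source_type"],
                row["target_id"], row["target_type"], w,
            )
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self._g, str(path))


def assemble_graph(
    relations: Iterable[Sequence[ImportanceScore] | ImportanceScore],
) -> TBKG:
    """Assemble the knowledge graph from per-type-pair relation lists.

    Accepts either a flat iterable of :class:`ImportanceScore` or an
    iterable of lists (one per type pair).  Each surviving score becomes
    one weighted edge; duplicate insertions must agree in weight.
    """
    g = TBKG()
    for item in relations:
        scores = [item] if isinstance(item, ImportanceScore) else item
        for s in scores:
            g.add_relation(
                s.target_id, s.target_type, s.feature_id, s.feature_type, s.value
            )
    return g
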