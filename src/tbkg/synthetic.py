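"""Planted-truth synthetic corpora for end-to-end testing.

The generator emulates the statistical structure the relation model
assumes: a typed graph with known conditional probabilities is planted,
then abstracts are sampled as entity bags from it, so every pipeline
stage (tagging, matrix construction, model fitting, graph assembly,
path ranking) can be checked against exact ground truth without any
external corpus or licensed dictionary.

Planted structure
-----------------
The planted graph is a **two-level forest**:

* *roots* are anchor entities that appear in each document
  independently with ``anchor_rate``;
* every *leaf* has exactly one root parent and appears with
  ``p_present`` when its parent is present in the document, otherwise
  with ``p_absent``;
* each root parents children of a single node type;
* *background* entities are linked to nothing and appear with
  ``background_rate``.

Under this structure every planted edge's conditionals are exactly
``(p_present, p_absent)`` — its importance is exactly
``log2(p_present/p_absent)`` — and no unplanted cross-type pair carries
any correlation, so recovery experiments have unambiguous truth.  The
type hierarchy tumor -> drug -> biomarker -> adr orders parents before
children, covering all six relationship classes.

Documents are entity bags: every present entity contributes one fixed
carrier sentence, which exercises the dictionary tagger without
simulating prose (the generator tests counting, not language).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .corpus import (
    AbstractRecord,
    DocEntityMatrix,
    EntityLexicon,
    build_lexicon,
    matrix_from_dense,
    write_corpus_jsonl,
    write_lexicon,
)
from .exceptions import ConfigurationError, ValidationError
from .graph import TBKG

DEFAULT_SIZES: dict[str, int] = {"tumor": 3, "drug": 4, "biomarker": 5, "adr": 5}
DEFAULT_EFFECT: tuple[float, float] = (0.3, 0.03)
DEFAULT_ANCHOR_RATE = 0.3
DEFAULT_BACKGROUND_RATE = 0.02
DEFAULT_N_BACKGROUND = 2

#: topological order of the type hierarchy (parents precede children)
TYPE_ORDER = ("tumor", "drug", "biomarker", "adr")

#: semantic category assigned per node type in the emitted lexicon
_CATEGORY_OF_TYPE = {"tumor": "T191", "drug": "T200", "biomarker": "T116", "adr": "WHO"}

_PREFIX = {"tumor": "TUM", "drug": "DRG", "biomarker": "BIO", "adr": "ADR"}

_FILLER = (
    "This synthetic abstract was generated from a planted knowledge graph "
    "and lists planted entity mentions for end-to-end pipeline testing."
)


@dataclass(frozen=True)
class PlantedEdge:
    parent: str
    child: str
    p_present: float
    p_absent: float

    @property
    def importance(self) -> float:
        return math.log2(self.p_present) - math.log2(self.p_absent)


@dataclass
class PlantedGraph:
    """A planted two-level typed forest with known edge conditionals."""

    node_types: dict[str, str]
    terms: dict[str, str]
    roles: dict[str, str]  # "root" | "leaf" | "background"
    parent_of: dict[str, str]
    effect: tuple[float, float]
    anchor_rate: float
    background_rate: float
    seed: int | None
    sizes: dict[str, int] = field(default_factory=dict)

    @property
    def edges(self) -> list[PlantedEdge]:
        p1, p0 = self.effect
        return [
            PlantedEdge(parent=r, child=c, p_present=p1, p_absent=p0)
            for c, r in sorted(self.parent_of.items())
        ]

    @property
    def planted_importance(self) -> float:
        p1, p0 = self.effect
        return math.log2(p1 / p0)

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Planted edges as unordered concept-id pairs."""
        return {tuple(sorted((e.parent, e.child))) for e in self.edges}

    def concept_ids(self) -> list[str]:
        return sorted(self.node_types)

    def marginal(self, cid: str) -> float:
        """Marginal presence probability of an entity per document."""
        role = self.roles[cid]
        if role == "root":
            return self.anchor_rate
        if role == "background":
            return self.background_rate
        p1, p0 = self.effect
        return self.anchor_rate * p1 + (1 - self.anchor_rate) * p0

    def to_lexicon(self) -> EntityLexicon:
        rows = [
            (self.terms[cid], cid, _CATEGORY_OF_TYPE[self.node_types[cid]])
            for cid in self.concept_ids()
        ]
        return build_lexicon(rows)

    def expected_tbkg(self) -> TBKG:
        """The graph the pipeline should assemble: planted edges weighted
        by the exact planted importance."""
        g = TBKG()
        for e in self.edges:
            g.add_relation(
                e.parent, self.node_types[e.parent],
                e.child, self.node_types[e.child],
                e.importance,
            )
        return g

    # -- closed-form accuracy of the optimal classifier -------------------

    def bayes_accuracy(self, target_type: str, feature_type: str) -> float:
        """Exact accuracy of the Bayes-optimal classifier predicting each
        *target_type* entity's presence from all *feature_type* indicators,
        averaged over targets.

        Because the forest is two-level and each root parents a single
        child type, the only features informative about a target are its
        own children (if the target is a root) or its parent (if it is a
        leaf and the parent has the feature type); everything else is
        independent of the target and ignored by the optimal rule.
        """
        p1, p0 = self.effect
        r = self.anchor_rate
        accs = []
        for t in sorted(self.concept_ids()):
            if self.node_types[t] != target_type:
                continue
            role = self.roles[t]
            if role == "root":
                children = sorted(
                    c for c, par in self.parent_of.items()
                    if par == t and self.node_types[c] == feature_type
                )
                k = len(children)
                if k == 0:
                    accs.append(max(r, 1 - r))
                    continue
                acc = 0.0
                for x in itertools.product((0, 1), repeat=k):
                    l1 = math.prod(p1 if xi else 1 - p1 for xi in x)
                    l0 = math.prod(p0 if xi else 1 - p0 for xi in x)
                    acc += max(r * l1, (1 - r) * l0)
                accs.append(acc)
            elif role == "leaf" and self.node_types[self.parent_of[t]] == feature_type:
                # observe the parent; predict the leaf
                acc = r * max(p1, 1 - p1) + (1 - r) * max(p0, 1 - p0)
                accs.append(acc)
            else:
                m = self.marginal(t)
                accs.append(max(m, 1 - m))
        if not accs:
            raise ValueError(f"no {target_type!r} entities in planted graph")
        return float(np.mean(accs))


def generate_graph(
    sizes: dict[str, int] | None = None,
    edge_density: float = 0.6,
    effect: tuple[float, float] = DEFAULT_EFFECT,
    anchor_rate: float = DEFAULT_ANCHOR_RATE,
    background_rate: float = DEFAULT_BACKGROUND_RATE,
    n_background: int = DEFAULT_N_BACKGROUND,
    seed: int | None = None,
) -> PlantedGraph:
    """Plant a typed two-level forest.

    Parameters
    ----------
    sizes
        Entities per node type (defaults: 3 tumors, 4 drugs,
        5 biomarkers, 5 ADRs).
    edge_density
        Probability that an eligible leaf is attached to a parent.
    effect
        ``(p_present, p_absent)`` conditionals shared by all planted
        edges; must satisfy 0 < p_absent < p_present < 1.
    anchor_rate, background_rate
        Per-document marginal rates of root and unlinked entities.
    n_background
        Extra ADR-typed entities linked to nothing (pure noise terms).
    """
    sizes = dict(DEFAULT_SIZES if sizes is None else sizes)
    for t in TYPE_ORDER:
        if sizes.get(t, 0) < 1:
            raise ValidationError(f"need at least one {t} entity, got {sizes.get(t, 0)}")
    p1, p0 = effect
    if not (0.0 < p0 < p1 < 1.0):
        raise ValidationError(
            f"effect must satisfy 0 < p_absent < p_present < 1, got {effect!r}"
        )
    if not 0.0 < edge_density <= 1.0:
        raise ValidationError("edge_density must be in (0, 1]")
    for name, rate in (("anchor_rate", anchor_rate), ("background_rate", background_rate)):
        if not 0.0 < rate < 1.0:
            raise ValidationError(f"{name} must be in (0, 1)")
    rng = np.random.default_rng(seed)

    node_types: dict[str, str] = {}
    terms: dict[str, str] = {}
    for t in TYPE_ORDER:
        n = sizes[t] + (n_background if t == "adr" else 0)
        for i in range(n):
            cid = f"C{_PREFIX[t]}{i:03d}"
            node_types[cid] = t
            terms[cid] = f"{t} entity {i:03d}"
    ids_of = {t: sorted(c for c, ty in node_types.items() if ty == t) for t in TYPE_ORDER}

    roles: dict[str, str] = {}
    child_type_of_root: dict[str, str] = {}
    # tumors: all roots; designated child types cycle through all three
    # descendant types (shuffled) so every leaf type has a possible parent.
    tumor_child_cycle = ["drug", "biomarker", "adr"]
    rng.shuffle(tumor_child_cycle)
    for i, cid in enumerate(ids_of["tumor"]):
        roles[cid] = "root"
        child_type_of_root[cid] = tumor_child_cycle[i % 3]
    # half of drugs / biomarkers are roots (at least one each)
    for t, child_types in (("drug", ["biomarker", "adr"]), ("biomarker", ["adr"])):
        ids = list(ids_of[t])
        rng.shuffle(ids)
        n_roots = max(1, len(ids) // 2)
        rng.shuffle(child_types)
        for i, cid in enumerate(ids):
            if i < n_roots:
                roles[cid] = "root"
                child_type_of_root[cid] = child_types[i % len(child_types)]
            else:
                roles[cid] = "leaf"
    for cid in ids_of["adr"]:
        roles[cid] = "leaf"
    # the last n_background ADR ids are dedicated background noise
    for cid in ids_of["adr"][len(ids_of["adr"]) - n_background:] if n_background else []:
        roles[cid] = "background"

    parent_of: dict[str, str] = {}
    for t in ("drug", "biomarker", "adr"):
        for cid in ids_of[t]:
            if roles[cid] != "leaf":
                continue
            compatible = sorted(
                rt for rt, ct in child_type_of_root.items() if ct == t
            )
            if not compatible or rng.random() >= edge_density:
                # unattached drugs/biomarkers stay independent anchors;
                # unattached ADRs are pure background noise
                roles[cid] = "background" if t == "adr" else "root"
                continue
            parent_of[cid] = compatible[rng.integers(len(compatible))]

    return PlantedGraph(
        node_types=node_types,
        terms=terms,
        roles=roles,
        parent_of=parent_of,
        effect=(float(p1), float(p0)),
        anchor_rate=float(anchor_rate),
        background_rate=float(background_rate),
        seed=seed,
        sizes=sizes,
    )


@dataclass
class SyntheticCorpus:
    """A sampled corpus with its exact incidence matrix and truth tables."""

    graph: PlantedGraph
    records: list[AbstractRecord]
    matrix: DocEntityMatrix
    truth_tables: dict[tuple[str, str], tuple[int, int, int, int]]
    lexicon: EntityLexicon

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            (p, c, *t) for (p, c), t in sorted(self.truth_tables.items())
        ]
        return pd.DataFrame(
            rows, columns=["parent", "child", "n11", "n10", "n01", "n00"]
        )

    def write(self, directory: str | Path) -> None:
        """Emit the dialects the pipeline reads: corpus.jsonl, lexicon.tsv,
        the exact matrix, and truth TSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_corpus_jsonl(self.records, directory / "corpus.jsonl")
        write_lexicon(self.lexicon, directory / "lexicon.tsv")
        self.matrix.save(directory / "matrix_exact")
        self.truth_frame().to_csv(directory / "truth_tables.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (e.parent, self.graph.node_types[e.parent],
                 e.child, self.graph.node_types[e.child],
                 e.p_present, e.p_absent, e.importance)
                for e in self.graph.edges
            ],
            columns=["parent", "parent_type", "child", "child_type",
                     "p_present", "p_absent", "importance"],
        ).to_csv(directory / "truth_edges.tsv", sep="\t", index=False)


def generate_corpus(
    graph: PlantedGraph, n_docs: int, seed: int | None = None
) -> SyntheticCorpus:
    """Sample *n_docs* entity-bag abstracts from a planted graph.

    Entities are sampled in type order (roots before their children) so
    each leaf's conditional given its parent is exact.  Returns the
    records, the exact document-entity matrix, and the true 2x2
    contingency table of every planted edge, all bookkept during
    sampling.
    """
    if n_docs < 1:
        raise ConfigurationError("n_docs must be >= 1")
    rng = np.random.default_rng(seed)
    p1, p0 = graph.effect
    cids = graph.concept_ids()
    presence: dict[str, np.ndarray] = {}
    # roots and background first (type order irrelevant for them)
    for cid in cids:
        role = graph.roles[cid]
        if role == "root":
            presence[cid] = rng.random(n_docs) < graph.anchor_rate
        elif role == "background":
            presence[cid] = rng.random(n_docs) < graph.background_rate
    # leaves in type order, conditioning on the sampled parent
    for t in TYPE_ORDER:
        for cid in cids:
            if graph.node_types[cid] != t or graph.roles[cid] != "leaf":
                continue
            par = presence[graph.parent_of[cid]]
            u = rng.random(n_docs)
            presence[cid] = np.where(par, u < p1, u < p0)

    dense = np.column_stack([presence[c] for c in cids]).astype(np.uint8)
    doc_ids = [f"SYN{i:05d}" for i in range(n_docs)]
    matrix = matrix_from_dense(
        doc_ids, cids, [graph.node_types[c] for c in cids], dense
    )

    records = []
    col_of = {c: j for j, c in enumerate(cids)}
    for i, doc_id in enumerate(doc_ids):
        sentences = [_FILLER]
        for c in cids:
            if dense[i, col_of[c]]:
                sentences.append(f"This abstract mentions {graph.terms[c]}.")
        records.append(
            AbstractRecord(doc_id=doc_id, title=f"Synthetic abstract {doc_id}",
                           body=" ".join(sentences), year=2020)
        )

    truth: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    for e in graph.edges:
        par, ch = presence[e.parent], presence[e.child]
        truth[(e.parent, e.child)] = (
            int((par & ch).sum()),
            int((par & ~ch).sum()),
            int((~par & ch).sum()),
            int((~par & ~ch).sum()),
        )

    return SyntheticCorpus(
        graph=graph,
        records=records,
        matrix=matrix,
        truth_tables=truth,
        lexicon=graph.to_lexicon(),
    )
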