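"""Corpus ingestion, entity lexicon, dictionary tagging, and the binary
document-entity matrix.

The pipeline's raw material is a set of literature abstracts.  Each
abstract is reduced to a bag of typed entity mentions (tumor, biomarker,
drug, adverse drug reaction) found by exact longest-match lookup against
a lexicon of surface terms, with a small negation filter so that entities
mentioned only negatively ("no interstitial lung disease") do not count
as present.  Non-negated mentions are binarized into a documents x
entities incidence matrix; rare entities (document frequency below a
configurable minimum, 50 by default) are dropped.

Node types follow the UMLS semantic-category convention used throughout
the package:

=========  ==========================================
category   node type
=========  ==========================================
T191       tumor
T121,T200  drug
T109,T114,T116,T123,T125,T126,T129,T130,T192,T195
           biomarker
WHO        adr (terms drawn from the WHO adverse-reaction
           source vocabulary)
=========  ==========================================
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from lxml import etree

from .exceptions import FormatError, UnknownEntityError, ValidationError

NODE_TYPES = ("tumor", "biomarker", "drug", "adr")

#: UMLS semantic category -> node type (13 categories + WHO ADR source list).
CATEGORY_TO_NODE_TYPE: dict[str, str] = {
    "T109": "biomarker",  # Organic Chemical
    "T114": "biomarker",  # Nucleic Acid, Nucleoside, or Nucleotide
    "T116": "biomarker",  # Amino Acid, Peptide, or Protein
    "T121": "drug",       # Pharmacologic Substance
    "T123": "biomarker",  # Biologically Active Substance
    "T125": "biomarker",  # Hormone
    "T126": "biomarker",  # Enzyme
    "T129": "biomarker",  # Immunologic Factor
    "T130": "biomarker",  # Indicator, Reagent, or Diagnostic Aid
    "T191": "tumor",      # Neoplastic Process
    "T192": "biomarker",  # Receptor
    "T195": "biomarker",  # Antibiotic
    "T200": "drug",       # Clinical Drug
    "WHO": "adr",         # designated adverse-reaction source list
}

#: Negation cues; a mention is negated iff a cue occurs within the three
#: tokens immediately preceding it.
NEGATION_UNIGRAMS = frozenset({"no", "not", "without", "denies"})
NEGATION_BIGRAMS = frozenset({("absence", "of"), ("negative", "for")})
NEGATION_WINDOW = 3

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*")


@dataclass(frozen=True)
class AbstractRecord:
    """One literature abstract: id, title, free text, publication year."""

    doc_id: str
    title: str
    body: str
    year: int | None = None

    @property
    def full_text(self) -> str:
        return f"{self.title}\n{self.body}"


@dataclass(frozen=True)
class LexiconEntry:
    tokens: tuple[str, ...]
    concept_id: str
    semantic_category: str
    node_type: str

    @property
    def term(self) -> str:
        return " ".join(self.tokens)


@dataclass
class EntityLexicon:
    """Surface term -> concept lookup with typed concepts.

    ``n_rejected`` counts input rows dropped because their semantic
    category is outside the recognized set (or the term duplicated an
    earlier row).
    """

    entries: list[LexiconEntry]
    n_rejected: int = 0
    _index: dict[tuple[str, ...], LexiconEntry] = field(default_factory=dict, repr=False)
    _max_len: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.tokens:
                raise ValidationError("lexicon entry with empty surface term")
            self._index[e.tokens] = e
            self._max_len = max(self._max_len, len(e.tokens))

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, tokens: tuple[str, ...]) -> LexiconEntry | None:
        return self._index.get(tokens)

    @property
    def max_term_tokens(self) -> int:
        return self._max_len

    def node_type_of(self, concept_id: str) -> str:
        for e in self.entries:
            if e.concept_id == concept_id:
                return e.node_type
        raise UnknownEntityError(f"concept {concept_id!r} not in lexicon")

    def resolve(self, term_or_id: str) -> str | None:
        """Resolve a surface term or a concept id to a concept id."""
        toks = tuple(_tokenize_str(term_or_id))
        hit = self._index.get(toks)
        if hit is not None:
            return hit.concept_id
        for e in self.entries:
            if e.concept_id == term_or_id:
                return e.concept_id
        return None


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    concept_id: str
    node_type: str
    span: tuple[int, int]  # character offsets into title+"\n"+body
    negated: bool


# ---------------------------------------------------------------------------
# corpus readers / writers


def _finish_record(doc_id, title, body, year, seen: set, out: list, min_body_chars: int):
    if doc_id in seen:
        raise ValidationError(f"duplicate doc_id {doc_id!r}")
    seen.add(doc_id)
    if len(body) < min_body_chars:
        return
    out.append(AbstractRecord(doc_id=doc_id, title=title, body=body, year=year))


def read_corpus(path: str | Path, format: str = "jsonl", min_body_chars: int = 100) -> list[AbstractRecord]:
    """Read abstracts, dropping those with a body shorter than *min_body_chars*.

    Parameters
    ----------
    path
        Input file.
    format
        ``"medline-xml"`` (minimal citation fields: PMID, ArticleTitle,
        AbstractText, PubDate/Year) or ``"jsonl"`` (one object per line
        with keys ``doc_id``/``title``/``body`` and optional ``year``).
    min_body_chars
        Short-abstract cutoff; records below it are removed.
    """
    path = Path(path)
    if format == "medline-xml":
        return _read_medline_xml(path, min_body_chars)
    if format == "jsonl":
        return _read_jsonl(path, min_body_chars)
    raise ValueError(f"unknown corpus format {format!r}")


def _read_medline_xml(path: Path, min_body_chars: int) -> list[AbstractRecord]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not well-formed MEDLINE XML: {path}: {exc}") from exc
    records: list[AbstractRecord] = []
    seen: set[str] = set()
    citations = tree.iter("MedlineCitation")
    for i, cit in enumerate(citations):
        pmid = cit.findtext("PMID")
        if pmid is None or not pmid.strip():
            raise FormatError(f"citation #{i + 1} in {path} has no PMID")
        title = (cit.findtext(".//ArticleTitle") or "").strip()
        abstract_parts = [t.text or "" for t in cit.iterfind(".//Abstract/AbstractText")]
        body = " ".join(p.strip() for p in abstract_parts if p.strip())
        year_text = cit.findtext(".//PubDate/Year")
        year = int(year_text) if year_text and year_text.strip().isdigit() else None
        _finish_record(pmid.strip(), title, body, year, seen, records, min_body_chars)
    return records


def _read_jsonl(path: Path, min_body_chars: int) -> list[AbstractRecord]:
    records: list[AbstractRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON record: {exc}") from exc
            if not isinstance(obj, dict) or "doc_id" not in obj or "body" not in obj:
                raise FormatError(f"{path}:{lineno}: record missing doc_id/body")
            year = obj.get("year")
            _finish_record(
                str(obj["doc_id"]), str(obj.get("title", "")), str(obj["body"]),
                int(year) if year is not None else None, seen, records, min_body_chars,
            )
    return records


def write_corpus_jsonl(records: Iterable[AbstractRecord], path: str | Path) -> None:
    """Write records in the JSONL dialect ``read_corpus`` reads back."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            obj = {"doc_id": r.doc_id, "title": r.title, "body": r.body}
            if r.year is not None:
                obj["year"] = r.year
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# lexicon


def load_lexicon(path: str | Path, strict: bool = False) -> EntityLexicon:
    """Load a TSV lexicon with columns (term, concept_id, semantic_category).

    Rows whose category is outside the recognized mapping are rejected
    (counted in ``n_rejected``); in *strict* mode they raise instead.
    Duplicate surface terms keep the first occurrence.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot read lexicon TSV {path}: {exc}") from exc
    missing = {"term", "concept_id", "semantic_category"} - set(df.columns)
    if missing:
        raise FormatError(f"lexicon {path} missing columns: {sorted(missing)}")
    return build_lexicon(df.itertuples(index=False), strict=strict)


def build_lexicon(rows: Iterable, strict: bool = False) -> EntityLexicon:
    """Build an :class:`EntityLexicon` from (term, concept_id, category) rows."""
    entries: list[LexiconEntry] = []
    seen_terms: set[tuple[str, ...]] = set()
    n_rejected = 0
    for row in rows:
        term, concept_id, category = row[0], row[1], row[2]
        node_type = CATEGORY_TO_NODE_TYPE.get(str(category))
        if node_type is None:
            if strict:
                raise ValidationError(f"unknown semantic category {category!r} for term {term!r}")
            n_rejected += 1
            continue
        tokens = tuple(_tokenize_str(str(term)))
        if not tokens:
            raise ValidationError(f"lexicon entry {concept_id!r} has empty surface term")
        if tokens in seen_terms:
            n_rejected += 1
            continue
        seen_terms.add(tokens)
        entries.append(LexiconEntry(tokens, str(concept_id), str(category), node_type))
    return EntityLexicon(entries=entries, n_rejected=n_rejected)


def write_lexicon(lexicon: EntityLexicon, path: str | Path) -> None:
    pd.DataFrame(
        [(e.term, e.concept_id, e.semantic_category) for e in lexicon.entries],
        columns=["term", "concept_id", "semantic_category"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tagging


def _tokenize_str(text: str) -> list[str]:
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


def _tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _is_negated(tokens: Sequence[str], i: int) -> bool:
    lo = max(0, i - NEGATION_WINDOW)
    window = tokens[lo:i]
    if any(t in NEGATION_UNIGRAMS for t in window):
        return True
    return any((window[j], window[j + 1]) in NEGATION_BIGRAMS for j in range(len(window) - 1))


def tag_entities(record: AbstractRecord, lexicon: EntityLexicon) -> list[EntityMention]:
    """Case-insensitive longest-match dictionary tagging over title+body.

    Scanning is greedy left-to-right: at each token the longest lexicon
    term starting there wins and shorter overlapping matches are
    suppressed.  A match preceded (within three tokens) by a negation cue
    is flagged ``negated``.
    """
    text = record.full_text
    toks = _tokenize_with_spans(text)
    words = [t[0] for t in toks]
    mentions: list[EntityMention] = []
    i = 0
    n = len(toks)
    max_len = lexicon.max_term_tokens
    while i < n:
        hit = None
        hit_len = 0
        for k in range(min(max_len, n - i), 0, -1):
            entry = lexicon.lookup(tuple(words[i : i + k]))
            if entry is not None:
                hit, hit_len = entry, k
                break
        if hit is None:
            i += 1
            continue
        span = (toks[i][1], toks[i + hit_len - 1][2])
        mentions.append(
            EntityMention(
                doc_id=record.doc_id,
                concept_id=hit.concept_id,
                node_type=hit.node_type,
                span=span,
                negated=_is_negated(words, i),
            )
        )
        i += hit_len
    return mentions


def tag_corpus(records: Iterable[AbstractRecord], lexicon: EntityLexicon) -> list[EntityMention]:
    out: list[EntityMention] = []
    for r in records:
        out.extend(tag_entities(r, lexicon))
    return out


# ---------------------------------------------------------------------------
# document-entity matrix


@dataclass
class DocEntityMatrix:
    """Binary documents x entities incidence matrix.

    ``X`` is sparse CSC with strictly 0/1 entries; ``doc_ids`` gives row
    order; ``entities`` is a DataFrame with columns ``concept_id`` and
    ``node_type`` in column order (sorted by concept id).  Cell (d, e) is
    1 iff entity *e* is mentioned positively at least once in document *d*
    — these are the indicator variables the naive-Bayes relation model
    conditions on.
    """

    doc_ids: list[str]
    entities: pd.DataFrame
    X: sp.csc_array

    def __post_init__(self) -> None:
        data = self.X.data
        if data.size and not np.isin(data, (0, 1)).all():
            raise ValidationError("matrix cells must be 0/1")

    @property
    def n_docs(self) -> int:
        return self.X.shape[0]

    @property
    def n_entities(self) -> int:
        return self.X.shape[1]

    def column_index(self, concept_id: str) -> int:
        idx = self.entities.index[self.entities["concept_id"] == concept_id]
        if len(idx) == 0:
            raise UnknownEntityError(f"entity {concept_id!r} not in matrix")
        return int(idx[0])

    def column(self, concept_id: str) -> np.ndarray:
        """Dense boolean presence vector for one entity."""
        j = self.column_index(concept_id)
        return np.asarray(self.X[:, [j]].todense()).ravel().astype(bool)

    def columns_of_type(self, node_type: str) -> pd.DataFrame:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        return self.entities[self.entities["node_type"] == node_type]

    def doc_frequency(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    # -- persistence: MatrixMarket triplets + two TSV sidecars ------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_array(self.X))
        pd.DataFrame({"doc_id": self.doc_ids}).to_csv(directory / "docs.tsv", sep="\t", index=False)
        self.entities.to_csv(directory / "entities.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "DocEntityMatrix":
        directory = Path(directory)
        try:
            X = sp.csc_array(scipy.io.mmread(str(directory / "matrix.mtx")))
            docs = pd.read_csv(directory / "docs.tsv", sep="\t", dtype=str)
            entities = pd.read_csv(directory / "entities.tsv", sep="\t", dtype=str)
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise FormatError(f"malformed matrix directory {directory}: {exc}") from exc
        X = sp.csc_array((X.data.astype(np.uint8), X.indices, X.indptr), shape=X.shape)
        return cls(doc_ids=list(docs["doc_id"]), entities=entities.reset_index(drop=True), X=X)


def build_matrix(
    records: Sequence[AbstractRecord],
    mentions: Iterable[EntityMention],
    min_entity_freq: int = 50,
) -> DocEntityMatrix:
    """Binarize non-negated mentions and drop rare entity columns.

    Entities whose document frequency is below *min_entity_freq* are
    removed.  Column order is deterministic (sorted by concept id); row
    order follows *records*.
    """
    doc_ids = [r.doc_id for r in records]
    doc_pos = {d: i for i, d in enumerate(doc_ids)}
    cells: set[tuple[str, str]] = set()
    node_type: dict[str, str] = {}
    for m in mentions:
        if m.doc_id not in doc_pos:
            raise ValidationError(f"mention references unknown doc_id {m.doc_id!r}")
        if m.negated:
            continue
        cells.add((m.doc_id, m.concept_id))
        node_type[m.concept_id] = m.node_type

    freq: dict[str, int] = {}
    for _, cid in cells:
        freq[cid] = freq.get(cid, 0) + 1
    kept = sorted(cid for cid, f in freq.items() if f >= min_entity_freq)
    col_pos = {c: j for j, c in enumerate(kept)}

    rows, cols = [], []
    for doc_id, cid in cells:
        j = col_pos.get(cid)
        if j is not None:
            rows.append(doc_pos[doc_id])
            cols.append(j)
    X = sp.csc_array(
        (np.ones(len(rows), dtype=np.uint8), (rows, cols)),
        shape=(len(doc_ids), len(kept)),
    )
    entities = pd.DataFrame(
        {"concept_id": kept, "node_type": [node_type[c] for c in kept]}
    )
    return DocEntityMatrix(doc_ids=doc_ids, entities=entities, X=X)


def matrix_from_dense(
    doc_ids: Sequence[str],
    concept_ids: Sequence[str],
    node_types: Sequence[str],
    dense: np.ndarray,
) -> DocEntityMatrix:
    """Build a matrix directly from a dense 0/1 array (column order is
    re-sorted by concept id)."""
    dense = np.asarray(dense)
    order = np.argsort(np.asarray(concept_ids, dtype=object))
    entities = pd.DataFrame(
        {
            "concept_id": np.asarray(concept_ids, dtype=object)[order],
            "node_type": np.asarray(node_types, dtype=object)[order],
        }
    ).reset_index(drop=True)
    X = sp.csc_array(dense[:, order].astype(np.uint8))
    return DocEntityMatrix(doc_ids=list(doc_ids), entities=entities, X=X)
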