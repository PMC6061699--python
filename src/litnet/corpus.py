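"""Corpus ingestion: PubTator annotations, CoNLL-U parses, dependency paths.

The unit of analysis is a *dependency path*: the chain of
(governor, relation, dependent) triples along the unique tree path between
two entity tokens in a sentence's dependency parse.  This module reads
PubTator-format entity annotations and pre-parsed sentences, aligns mentions
to parse tokens, and enumerates one path record per typed entity pair per
sentence.

Conventions
-----------
* Character offsets are 0-based, end-exclusive, into the document text
  formed as ``title + " " + abstract``.
* Multi-word mentions are concatenated with underscores before alignment
  ("cytochrome p450 3A4" -> "cytochrome_p450_3A4"); the mention then maps
  to exactly one parse token.
* Paths are oriented chemical->gene, chemical->disease, gene->disease;
  gene-gene sentences yield a path in both directions because that
  relationship type has no natural orientation.
* Paths containing a coordinating-conjunction dependency (``conj`` or any
  ``conj:*`` subtype) are discarded: parsers represent lists with these
  edges and the resulting paths rarely describe a relationship.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .normalize import normalize_entity_string

logger = logging.getLogger(__name__)

START_PLACEHOLDER = "START_ENTITY"
END_PLACEHOLDER = "END_ENTITY"

ENTITY_TYPES = ("chemical", "gene", "disease")

#: Canonical orientation for asymmetric type pairs; gene-gene is emitted in
#: both directions.
ORIENTED_PAIR_TYPES = {
    ("chemical", "gene"): "chemical-gene",
    ("chemical", "disease"): "chemical-disease",
    ("gene", "disease"): "gene-disease",
    ("gene", "gene"): "gene-gene",
}

PAIR_TYPES = tuple(ORIENTED_PAIR_TYPES.values())

_WS_RUN = re.compile(r"\s+")


class AlignmentError(ValueError):
    """A mention's recorded surface string does not match the document text."""


class PathExtractionError(ValueError):
    """The requested endpoints do not admit a valid dependency path."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityMention:
    """A typed entity annotation with document-level character offsets."""

    start: int
    end: int
    surface: str
    entity_type: str
    db_id: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad mention offsets {self.start}..{self.end}")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")

    @property
    def formatted(self) -> str:
        """Surface with whitespace runs replaced by underscores (case kept)."""
        return _WS_RUN.sub("_", self.surface)


@dataclass
class DependencyGraph:
    """A sentence parse: ordered tokens plus tree-shaped dependency edges.

    ``tokens`` holds (index, form, lemma) with 1-based indices as in
    CoNLL-U; ``edges`` holds (governor index, relation, dependent index).
    """

    tokens: list[tuple[int, str, str]]
    edges: list[tuple[int, str, int]]
    root: int

    @property
    def forms(self) -> list[str]:
        return [form for _, form, _ in self.tokens]

    def lemma(self, index: int) -> str:
        for idx, _, lemma in self.tokens:
            if idx == index:
                return lemma
        raise KeyError(index)

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(idx for idx, _, _ in self.tokens)
        for gov, rel, dep in self.edges:
            g.add_edge(gov, dep, gov=gov, rel=rel, dep=dep)
        return g


@dataclass
class SentenceParse:
    """A parsed sentence attached to a document position."""

    sentence_number: int  # 0 = title
    graph: DependencyGraph | None
    text: str  # concatenated (underscored) sentence text


@dataclass
class AnnotatedDocument:
    """A PubTator abstract with its mentions and (optionally) its parses."""

    doc_id: str
    title: str
    abstract: str
    mentions: list[EntityMention] = field(default_factory=list)
    sentences: list[SentenceParse] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Title followed by a single space then abstract."""
        if self.abstract:
            return self.title + " " + self.abstract
        return self.title


@dataclass(frozen=True)
class DependencyPath:
    """An ordered chain of dependency triples between two masked entities."""

    triples: tuple[tuple[str, str, str], ...]
    pair_type: str | None = None

    def __post_init__(self):
        if not self.triples:
            raise ValueError("a dependency path needs at least one triple")
        joined = [t for triple in self.triples for t in triple]
        if joined.count(START_PLACEHOLDER) != 1 or joined.count(END_PLACEHOLDER) != 1:
            raise ValueError("path must contain exactly one START_ENTITY and one END_ENTITY")

    @property
    def formatted(self) -> str:
        """Canonical string form: space-joined ``gov|rel|dep`` triples."""
        return " ".join("|".join(triple) for triple in self.triples)

    @classmethod
    def parse(cls, formatted: str, pair_type: str | None = None) -> "DependencyPath":
        triples = []
        for chunk in formatted.split(" "):
            parts = chunk.split("|")
            if len(parts) != 3:
                raise ValueError(f"malformed path triple {chunk!r}")
            triples.append(tuple(parts))
        return cls(tuple(triples), pair_type)

    @property
    def relations(self) -> tuple[str, ...]:
        return tuple(rel for _, rel, _ in self.triples)

    def __len__(self) -> int:
        return len(self.triples)


@dataclass
class PathRecord:
    """One sentence-level relationship instance (a Part II row).

    Field order mirrors the distribution format: identifiers, both
    entities' formatted names / raw-text locations / raw strings / database
    ids / types, the formatted dependency path, and the tokenized sentence.
    """

    doc_id: str
    sentence_number: int
    entity1_formatted: str
    entity1_start: int
    entity1_end: int
    entity2_formatted: str
    entity2_start: int
    entity2_end: int
    entity1_raw: str
    entity2_raw: str
    entity1_db_id: str
    entity2_db_id: str
    entity1_type: str  # capitalized, e.g. "Chemical"
    entity2_type: str
    path: str
    sentence: str

    @property
    def pair_type(self) -> str:
        return ORIENTED_PAIR_TYPES[
            (self.entity1_type.lower(), self.entity2_type.lower())
        ]

    @property
    def pair_key(self) -> tuple[str, str]:
        """Normalized (entity1, entity2) strings used as the network node pair."""
        return (
            normalize_entity_string(self.entity1_formatted),
            normalize_entity_string(self.entity2_formatted),
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_pubtator(source: str | Path) -> list[AnnotatedDocument]:
    """Read a PubTator-format file into documents (without parses).

    The format is blocks separated by blank lines::

        <pmid>|t|<title>
        <pmid>|a|<abstract>
        <pmid>\\t<start>\\t<end>\\t<surface>\\t<type>\\t<db id>

    Mentions whose recorded surface disagrees with the text at their
    offsets raise :class:`AlignmentError` (the reader validates rather than
    guesses).
    """
    text = Path(source).read_text(encoding="utf-8")
    docs: list[AnnotatedDocument] = []
    for block in re.split(r"\n\s*\n", text.strip()):
        if not block.strip():
            continue
        docs.append(_parse_pubtator_block(block))
    return docs


def _parse_pubtator_block(block: str) -> AnnotatedDocument:
    doc_id = title = abstract = None
    mentions: list[EntityMention] = []
    for line in block.splitlines():
        if not line.strip():
            continue
        if "|t|" in line and title is None:
            doc_id, _, title = line.partition("|t|")
        elif "|a|" in line and abstract is None:
            _, _, abstract = line.partition("|a|")
        else:
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"malformed PubTator mention line: {line!r}")
            _, start, end, surface, etype = parts[:5]
            db_id = parts[5] if len(parts) > 5 else ""
            etype = etype.strip().lower()
            if etype not in ENTITY_TYPES:
                logger.warning("skipping mention with unsupported type %r", etype)
                continue
            mentions.append(
                EntityMention(int(start), int(end), surface, etype, db_id)
            )
    if doc_id is None or title is None:
        raise ValueError("PubTator block lacks a title line")
    doc = AnnotatedDocument(doc_id, title, abstract or "", mentions)
    for m in doc.mentions:
        observed = doc.text[m.start : m.end]
        if observed != m.surface:
            raise AlignmentError(
                f"doc {doc.doc_id}: mention at {m.start}..{m.end} reads "
                f"{observed!r}, annotation says {m.surface!r}"
            )
    return doc


def read_conllu(source: str | Path) -> dict[str, tuple[DependencyGraph, str]]:
    """Read CoNLL-U sentences into ``sent_id -> (graph, sentence text)``.

    Only the columns this pipeline uses are interpreted: ID, FORM, LEMMA,
    HEAD and DEPREL.  Multi-word-token ranges and empty nodes are ignored.
    ``# sent_id`` and ``# text`` metadata are required per sentence.
    """
    out: dict[str, tuple[DependencyGraph, str]] = {}
    blocks = re.split(r"\n\s*\n", Path(source).read_text(encoding="utf-8").strip())
    for block in blocks:
        if not block.strip():
            continue
        sent_id = sent_text = None
        tokens: list[tuple[int, str, str]] = []
        edges: list[tuple[int, str, int]] = []
        root = None
        for line in block.splitlines():
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                key = key.strip()
                if key == "sent_id":
                    sent_id = value.strip()
                elif key == "text":
                    sent_text = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) < 8 or "-" in cols[0] or "." in cols[0]:
                continue
            idx = int(cols[0])
            form, lemma = cols[1], cols[2]
            head, deprel = int(cols[6]), cols[7]
            tokens.append((idx, form, lemma))
            if head == 0:
                root = idx
            else:
                edges.append((head, deprel, idx))
        if sent_id is None or sent_text is None:
            raise ValueError("CoNLL-U sentence lacks # sent_id or # text metadata")
        if root is None:
            raise ValueError(f"CoNLL-U sentence {sent_id} has no root")
        out[sent_id] = (DependencyGraph(tokens, edges, root), sent_text)
    return out


def read_sentence_map(source: str | Path) -> list[tuple[str, int, str]]:
    """Read the sidecar mapping ``doc_id\\tsentence_number\\tsent_id``."""
    rows = []
    for ln, line in enumerate(Path(source).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"sentence map line {ln}: expected 3 columns")
        rows.append((parts[0], int(parts[1]), parts[2]))
    return rows


def attach_parses(
    docs: Sequence[AnnotatedDocument],
    parses: dict[str, tuple[DependencyGraph, str]],
    sentence_map: Iterable[tuple[str, int, str]],
) -> list[AnnotatedDocument]:
    """Attach parsed sentences to documents via the sidecar mapping."""
    by_doc: dict[str, list[SentenceParse]] = {}
    for doc_id, snum, sent_id in sentence_map:
        if sent_id not in parses:
            logger.warning("doc %s sentence %d: parse %s missing; skipped", doc_id, snum, sent_id)
            continue
        graph, text = parses[sent_id]
        by_doc.setdefault(doc_id, []).append(SentenceParse(snum, graph, text))
    out = []
    for doc in docs:
        sents = sorted(by_doc.get(doc.doc_id, []), key=lambda s: s.sentence_number)
        out.append(replace(doc, sentences=sents))
    return out


# ---------------------------------------------------------------------------
# mention handling
# ---------------------------------------------------------------------------


def resolve_overlaps(mentions: Sequence[EntityMention]) -> list[EntityMention]:
    """Drop overlapping mentions, keeping the longest (ties: earliest start)."""
    kept: list[EntityMention] = []
    for m in sorted(mentions, key=lambda m: (-(m.end - m.start), m.start, m.end)):
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def concatenate_entity_tokens(
    text: str, mentions: Sequence[EntityMention], doc_id: str = "?"
) -> tuple[str, list[EntityMention]]:
    """Replace internal whitespace of each mention with underscores.

    Returns the transformed text and mentions with offsets recomputed into
    it.  Mentions must be non-overlapping and must match the text at their
    offsets (:class:`AlignmentError` otherwise).  Whitespace runs collapse
    to a single underscore, so downstream offsets can shift.
    """
    ordered = sorted(mentions, key=lambda m: m.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"doc {doc_id}: overlapping mentions at {a.start} and {b.start}")
    pieces: list[str] = []
    new_mentions: list[EntityMention] = []
    cursor = 0
    out_len = 0
    for m in ordered:
        observed = text[m.start : m.end]
        if observed != m.surface:
            raise AlignmentError(
                f"doc {doc_id}: mention at offset {m.start} reads {observed!r}, "
                f"annotation says {m.surface!r}"
            )
        gap = text[cursor : m.start]
        pieces.append(gap)
        out_len += len(gap)
        concatenated = _WS_RUN.sub("_", m.surface)
        pieces.append(concatenated)
        new_mentions.append(
            replace(m, start=out_len, end=out_len + len(concatenated), surface=concatenated)
        )
        out_len += len(concatenated)
        cursor = m.end
    pieces.append(text[cursor:])
    return "".join(pieces), new_mentions


# ---------------------------------------------------------------------------
# path extraction
# ---------------------------------------------------------------------------


def _sanitize_lemma(lemma: str) -> str:
    return _WS_RUN.sub("_", lemma).replace("|", "/").lower()


def extract_path(
    graph: DependencyGraph,
    start_token_index: int,
    end_token_index: int,
    pair_type: str | None = None,
) -> DependencyPath:
    """Extract the dependency path between two tokens of a parse tree.

    The path is the unique undirected tree path from ``start_token_index``
    to ``end_token_index``.  Each edge on it contributes one
    (governor lemma, relation, dependent lemma) triple, keeping the edge's
    original direction; the two endpoint lemmas are masked as
    ``START_ENTITY`` / ``END_ENTITY`` and every other lemma is lowercased.
    """
    if start_token_index == end_token_index:
        raise PathExtractionError("degenerate path: identical endpoints")
    g = graph.to_undirected()
    if start_token_index not in g or end_token_index not in g:
        raise PathExtractionError("endpoint is not a node of the graph")
    try:
        node_path = nx.shortest_path(g, start_token_index, end_token_index)
    except nx.NetworkXNoPath:
        raise PathExtractionError("endpoints are not connected") from None

    def render(idx: int) -> str:
        if idx == start_token_index:
            return START_PLACEHOLDER
        if idx == end_token_index:
            return END_PLACEHOLDER
        return _sanitize_lemma(graph.lemma(idx))

    triples = []
    for u, v in zip(node_path, node_path[1:]):
        data = g.edges[u, v]
        triples.append((render(data["gov"]), data["rel"], render(data["dep"])))
    return DependencyPath(tuple(triples), pair_type)


def passes_conj_filter(path: DependencyPath) -> bool:
    """True unless the path crosses a coordinating-conjunction dependency."""
    return not any(rel == "conj" or rel.startswith("conj:") for rel in path.relations)


# ---------------------------------------------------------------------------
# sentence alignment and pair enumeration
# ---------------------------------------------------------------------------


def _align_sentences(doc: AnnotatedDocument):
    """Yield (sentence, [(original mention, token index), ...]) per parse.

    Alignment strategy: the document text is underscore-concatenated, each
    sentence's ``# text`` is located in it sequentially, and mentions inside
    a sentence's span are matched to parse tokens by form equality
    (transformed surface == token FORM), assigning repeated surfaces in
    textual order.  Mentions that cannot be matched to exactly one token
    (e.g. the tokenizer split them) are skipped with a warning.
    """
    mentions = resolve_overlaps(doc.mentions)
    original_by_key = {(m.start, m.end): m for m in mentions}
    keys = [(m.start, m.end) for m in mentions]
    text, tmentions = concatenate_entity_tokens(doc.text, mentions, doc.doc_id)
    cursor = 0
    for sent in doc.sentences:
        if sent.graph is None:
            logger.warning("doc %s sentence %d lacks a parse; skipped", doc.doc_id, sent.sentence_number)
            continue
        pos = text.find(sent.text, cursor)
        if pos < 0:
            logger.warning(
                "doc %s sentence %d: sentence text not found in document; skipped",
                doc.doc_id,
                sent.sentence_number,
            )
            continue
        span = (pos, pos + len(sent.text))
        cursor = span[1]
        local = [
            (orig_key, tm)
            for orig_key, tm in zip(keys, tmentions)
            if tm.start >= span[0] and tm.end <= span[1]
        ]
        forms = sent.graph.forms
        indices = [idx for idx, _, _ in sent.graph.tokens]
        used: set[int] = set()
        aligned = []
        for orig_key, tm in sorted(local, key=lambda item: item[1].start):
            token_idx = None
            for pos_i, form in enumerate(forms):
                if form == tm.surface and indices[pos_i] not in used:
                    token_idx = indices[pos_i]
                    break
            if token_idx is None:
                logger.warning(
                    "doc %s sentence %d: mention %r has no matching token; skipped",
                    doc.doc_id,
                    sent.sentence_number,
                    tm.surface,
                )
                continue
            used.add(token_idx)
            aligned.append((original_by_key[orig_key], token_idx))
        yield sent, aligned


def _make_record(
    doc: AnnotatedDocument,
    sent: SentenceParse,
    first: tuple[EntityMention, int],
    second: tuple[EntityMention, int],
) -> PathRecord | None:
    m1, t1 = first
    m2, t2 = second
    pair_type = ORIENTED_PAIR_TYPES[(m1.entity_type, m2.entity_type)]
    path = extract_path(sent.graph, t1, t2, pair_type)
    if not passes_conj_filter(path):
        return None
    return PathRecord(
        doc_id=doc.doc_id,
        sentence_number=sent.sentence_number,
        entity1_formatted=m1.formatted,
        entity1_start=m1.start,
        entity1_end=m1.end,
        entity2_formatted=m2.formatted,
        entity2_start=m2.start,
        entity2_end=m2.end,
        entity1_raw=m1.surface,
        entity2_raw=m2.surface,
        entity1_db_id=m1.db_id,
        entity2_db_id=m2.db_id,
        entity1_type=m1.entity_type.capitalize(),
        entity2_type=m2.entity_type.capitalize(),
        path=path.formatted,
        sentence=" ".join(sent.graph.forms),
    )


def enumerate_pair_paths(document: AnnotatedDocument) -> list[PathRecord]:
    """Emit one record per typed entity pair per parsed sentence.

    Asymmetric type pairs are oriented canonically (chemical->gene,
    chemical->disease, gene->disease); gene-gene pairs are emitted in both
    directions.  Records whose path crosses a ``conj`` dependency are
    dropped.
    """
    records: list[PathRecord] = []
    for sent, aligned in _align_sentences(document):
        by_type: dict[str, list[tuple[EntityMention, int]]] = {t: [] for t in ENTITY_TYPES}
        for mention, tok in aligned:
            by_type[mention.entity_type].append((mention, tok))
        for t1, t2 in (("chemical", "gene"), ("chemical", "disease"), ("gene", "disease")):
            for a in by_type[t1]:
                for b in by_type[t2]:
                    if a[1] == b[1]:
                        continue
                    rec = _make_record(document, sent, a, b)
                    if rec is not None:
                        records.append(rec)
        genes = by_type["gene"]
        for a in genes:
            for b in genes:
                if a[1] == b[1]:
                    continue
                rec = _make_record(document, sent, a, b)
                if rec is not None:
                    records.append(rec)
    return records


def extract_corpus(
    pubtator: str | Path,
    conllu: str | Path,
    sentence_map: str | Path,
) -> list[PathRecord]:
    """Full ingest: read the three input files and enumerate all records."""
    docs = read_pubtator(pubtator)
    parses = read_conllu(conllu)
    mapping = read_sentence_map(sentence_map)
    records: list[PathRecord] = []
    for doc in attach_parses(docs, parses, mapping):
        records.extend(enumerate_pair_paths(doc))
    logger.info("extracted %d path records from %d documents", len(records), len(docs))
    return records
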