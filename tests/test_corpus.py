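"""Corpus ingestion: concatenation, path extraction, pair enumeration."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from litnet.corpus import (
    AlignmentError,
    AnnotatedDocument,
    DependencyGraph,
    DependencyPath,
    EntityMention,
    PathExtractionError,
    SentenceParse,
    concatenate_entity_tokens,
    enumerate_pair_paths,
    extract_path,
    passes_conj_filter,
    resolve_overlaps,
)


# ---------------------------------------------------------------------------
# entity concatenation
# ---------------------------------------------------------------------------


class TestConcatenation:
    def test_multiword_mention_is_underscored(self):
        text = "binds cytochrome p450 3A4 strongly"
        mention = EntityMention(6, 25, "cytochrome p450 3A4", "gene")
        new_text, new_mentions = concatenate_entity_tokens(text, [mention])
        assert new_text == "binds cytochrome_p450_3A4 strongly"
        assert new_mentions[0].surface == "cytochrome_p450_3A4"

    def test_empty_mention_list_is_identity(self):
        assert concatenate_entity_tokens("any text", []) == ("any text", [])

    def test_downstream_offsets_shift(self):
        text = "aspirin eases heart  failure symptoms"
        mentions = [
            EntityMention(0, 7, "aspirin", "chemical"),
            EntityMention(14, 28, "heart  failure", "disease"),
        ]
        new_text, new_mentions = concatenate_entity_tokens(text, mentions)
        # the double space collapses to one underscore, shortening the text
        assert new_text == "aspirin eases heart_failure symptoms"
        for m in new_mentions:
            assert new_text[m.start : m.end] == m.surface
        assert new_mentions[1].surface == "heart_failure"

    def test_offsets_match_prefix_scan_oracle(self, rng):
        """Recompute every transformed offset by an independent prefix scan."""
        words = ["alpha", "beta kinase", "x", "some disease", "gamma delta epsilon"]
        for _ in range(50):
            chosen = rng.choice(len(words), size=rng.integers(1, 4), replace=False)
            parts, mentions, pos = [], [], 0
            for k, w in enumerate(["lead-in"] + [words[i] for i in sorted(chosen)]):
                if k > 0:
                    surface = w
                    mentions.append(
                        EntityMention(pos, pos + len(surface), surface, "chemical")
                    )
                parts.append(w)
                pos += len(w) + 1
            text = " ".join(parts)
            new_text, new_mentions = concatenate_entity_tokens(text, mentions)
            # oracle: replay the replacement left to right, tracking the shift
            shift = 0
            for old, new in zip(mentions, new_mentions):
                underscored = "_".join(old.surface.split())
                assert new.start == old.start + shift
                assert new.surface == underscored
                shift += len(underscored) - (old.end - old.start)
                assert new_text[new.start : new.end] == underscored

    def test_surface_mismatch_raises_with_location(self):
        with pytest.raises(AlignmentError, match="doc pmid9.*offset 0"):
            concatenate_entity_tokens(
                "actual text", [EntityMention(0, 6, "wrong!", "gene")], doc_id="pmid9"
            )

    def test_overlap_resolution_keeps_longest_then_earliest(self):
        a = EntityMention(0, 10, "0123456789", "gene")
        b = EntityMention(5, 12, "5678901", "gene")
        c = EntityMention(20, 27, "animals", "disease")
        kept = resolve_overlaps([b, a, c])
        assert kept == [a, c]


# ---------------------------------------------------------------------------
# path extraction
# ---------------------------------------------------------------------------


class TestExtractPath:
    def test_published_example_path(self, example_graph):
        """The appositive trial/inhibitor sentence yields the printed path."""
        path = extract_path(example_graph, 11, 8)
        assert path.formatted == (
            "trial|appos|START_ENTITY trial|nmod|inhibitor inhibitor|amod|END_ENTITY"
        )

    def test_adjacent_entities_give_single_triple(self):
        g = DependencyGraph(
            tokens=[(1, "EGFR", "egfr"), (2, "binds", "bind")],
            edges=[(2, "nsubj", 1)],
            root=2,
        )
        path = extract_path(g, 1, 2)
        assert path.formatted == "END_ENTITY|nsubj|START_ENTITY"
        assert len(path) == 1

    def test_identical_endpoints_rejected(self, example_graph):
        with pytest.raises(PathExtractionError, match="degenerate"):
            extract_path(example_graph, 4, 4)

    def test_disconnected_graph_rejected(self):
        g = DependencyGraph(
            tokens=[(1, "a", "a"), (2, "b", "b"), (3, "c", "c")],
            edges=[(2, "dep", 1)],
            root=2,
        )
        with pytest.raises(PathExtractionError):
            extract_path(g, 1, 3)

    def test_matches_bfs_oracle_on_random_trees(self, rng):
        """Triple sequences equal the path found by an independent BFS."""
        rels = ["nsubj", "obj", "nmod", "amod", "advcl", "xcomp"]
        for trial in range(200):
            n = int(rng.integers(3, 12))
            tree = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
            tokens = [(i + 1, f"w{i}", f"w{i}") for i in range(n)]
            edges = []
            for u, v in tree.edges:
                gov, dep = (u + 1, v + 1) if rng.random() < 0.5 else (v + 1, u + 1)
                edges.append((gov, rels[rng.integers(len(rels))], dep))
            g = DependencyGraph(tokens, edges, root=1)
            s, e = rng.choice(n, size=2, replace=False) + 1
            path = extract_path(g, int(s), int(e))

            # oracle: BFS over an adjacency map built straight from edges
            adj = {}
            for gov, rel, dep in edges:
                adj.setdefault(gov, []).append((dep, (gov, rel, dep)))
                adj.setdefault(dep, []).append((gov, (gov, rel, dep)))
            parent = {int(s): None}
            queue = [int(s)]
            while queue:
                node = queue.pop(0)
                for nbr, edge in adj.get(node, []):
                    if nbr not in parent:
                        parent[nbr] = (node, edge)
                        queue.append(nbr)
            hops = []
            node = int(e)
            while parent[node] is not None:
                prev, edge = parent[node]
                hops.append(edge)
                node = prev
            hops.reverse()

            assert len(path) == len(hops)

            def mask(idx):
                if idx == int(s):
                    return "START_ENTITY"
                if idx == int(e):
                    return "END_ENTITY"
                return f"w{idx - 1}"

            expected = tuple((mask(g_), r, mask(d)) for g_, r, d in hops)
            assert path.triples == expected

            # reversing the endpoints reverses the traversal and swaps masks
            back = extract_path(g, int(e), int(s))
            swapped = tuple(
                tuple(
                    {"START_ENTITY": "END_ENTITY", "END_ENTITY": "START_ENTITY"}.get(x, x)
                    for x in triple
                )
                for triple in reversed(path.triples)
            )
            assert back.triples == swapped


class TestConjFilter:
    @pytest.mark.parametrize(
        "relations,expected",
        [
            (("nsubj", "conj", "obj"), False),
            (("nsubj", "obj"), True),
            (("conj:and",), False),
        ],
    )
    def test_conj_relations_rejected(self, relations, expected):
        triples = [("w", rel, "v") for rel in relations]
        triples[0] = ("w", relations[0], "START_ENTITY")
        triples[-1] = (triples[-1][0], triples[-1][1], "END_ENTITY")
        if len(triples) == 1:
            triples = [("END_ENTITY", relations[0], "START_ENTITY")]
        path = DependencyPath(tuple(triples))
        assert passes_conj_filter(path) is expected


@given(
    st.lists(
        st.tuples(
            st.text(alphabet="abcxyz_", min_size=1, max_size=6),
            st.sampled_from(["nsubj", "obj", "nmod", "conj:and"]),
            st.text(alphabet="abcxyz_", min_size=1, max_size=6),
        ),
        min_size=1,
        max_size=5,
    )
)
def test_formatted_path_round_trips(triples):
    """format(parse(formatted)) == formatted for any well-formed path."""
    triples = list(triples)
    g0, r0, _ = triples[0]
    triples[0] = (g0, r0, "START_ENTITY")
    if len(triples) == 1:
        triples[0] = ("END_ENTITY", r0, "START_ENTITY")
    else:
        gl, rl, dl = triples[-1]
        triples[-1] = (gl, rl, "END_ENTITY")
    path = DependencyPath(tuple(triples))
    assert DependencyPath.parse(path.formatted).formatted == path.formatted


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------


def _doc_with_sentence(mention_specs):
    """Title-only document: '<e1> links <e2> [links2 <e3>] .' with a star parse."""
    words, mentions, pos = [], [], 0
    tokens, edges = [], []
    idx = 0
    for k, (surface, etype) in enumerate(mention_specs):
        idx += 1
        tokens.append((idx, surface, surface))
        edges.append(None)  # placeholder, heads fixed below
        words.append(surface)
        mentions.append(EntityMention(pos, pos + len(surface), surface, etype, f"id{k}"))
        pos += len(surface) + 1
        if k < len(mention_specs) - 1:
            idx += 1
            tokens.append((idx, f"links{k}", f"links{k}"))
            words.append(f"links{k}")
            pos += len(f"links{k}") + 1
    # chain parse: every token depends on the first linking verb (or token 1)
    root = 2 if len(tokens) > 1 else 1
    edges = [
        (root, "dep", i) for i, _, _ in tokens if i != root
    ]
    title = " ".join(words) + " ."
    tokens.append((idx + 1, ".", "."))
    edges.append((root, "punct", idx + 1))
    graph = DependencyGraph(tokens, edges, root=root)
    return AnnotatedDocument(
        doc_id="d1",
        title=title,
        abstract="",
        mentions=mentions,
        sentences=[SentenceParse(0, graph, title)],
    )


class TestEnumeratePairPaths:
    def test_two_genes_give_both_directions(self):
        doc = _doc_with_sentence([("brca1", "gene"), ("tp53", "gene")])
        records = enumerate_pair_paths(doc)
        assert len(records) == 2
        assert {(r.entity1_formatted, r.entity2_formatted) for r in records} == {
            ("brca1", "tp53"),
            ("tp53", "brca1"),
        }

    def test_chemical_gene_disease_gives_three_oriented_records(self):
        doc = _doc_with_sentence(
            [("aspirin", "chemical"), ("ptgs2", "gene"), ("pain", "disease")]
        )
        records = enumerate_pair_paths(doc)
        assert len(records) == 3
        assert {(r.entity1_type, r.entity2_type) for r in records} == {
            ("Chemical", "Gene"),
            ("Chemical", "Disease"),
            ("Gene", "Disease"),
        }

    def test_single_mention_gives_no_records(self):
        doc = _doc_with_sentence([("aspirin", "chemical")])
        assert enumerate_pair_paths(doc) == []

    def test_conj_paths_are_dropped(self):
        doc = _doc_with_sentence([("aspirin", "chemical"), ("ptgs2", "gene")])
        graph = doc.sentences[0].graph
        graph.edges = [
            (e[0], "conj:and", e[2]) if e[2] == 3 else e for e in graph.edges
        ]
        assert enumerate_pair_paths(doc) == []

    def test_sentence_without_parse_is_skipped(self):
        doc = _doc_with_sentence([("aspirin", "chemical"), ("ptgs2", "gene")])
        doc.sentences[0] = SentenceParse(0, None, doc.sentences[0].text)
        assert enumerate_pair_paths(doc) == []

    def test_emitted_records_carry_raw_offsets_and_ids(self):
        doc = _doc_with_sentence([("aspirin", "chemical"), ("ptgs2", "gene")])
        (rec,) = enumerate_pair_paths(doc)
        assert doc.text[rec.entity1_start : rec.entity1_end] == rec.entity1_raw
        assert rec.entity1_db_id == "id0"
        assert passes_conj_filter(DependencyPath.parse(rec.path))
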