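"""Synthetic corpora with known latent theme structure.

Every stage of the pipeline is testable without downloading anything: the
generator invents latent relationship *themes*, gives each theme a set of
dependency-path templates (distinct lemma/relation chains) and a set of
typed entity pairs, and emits sentences realizing (pair, template)
sightings as PubTator-format documents with gold CoNLL-U parses written
alongside.  With cross-theme noise 0 the resulting pair x path incidence
is exactly block-diagonal under the gold ordering; with noise epsilon each
sighting additionally connects its pair to a random other-theme template
with probability epsilon.

Sentences are template realizations with pre-written parses, not parser
output: the point is statistical structure (which paths connect which
pairs), not linguistic realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enrichment import ReferenceRelationSet
from .matrix import PairKey

logger = logging.getLogger(__name__)

_TYPE_PREFIX = {"chemical": "chem", "gene": "gene", "disease": "malady"}
_TYPE_DB = {"chemical": "MESH:C", "gene": "GID:", "disease": "MESH:D"}


@dataclass
class SyntheticConfig:
    """Latent structure and noise of a generated corpus."""

    n_themes: int = 4
    paths_per_theme: int = 10
    pairs_per_theme: int = 30
    sightings_per_pair: int = 3
    noise: float = 0.05  # per-sighting probability of a cross-theme extra sentence
    relationship_type: str = "chemical-gene"
    n_entities_type1: int = 120
    n_entities_type2: int = 120
    sentences_per_doc: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        for name in ("n_themes", "paths_per_theme", "pairs_per_theme", "sightings_per_pair"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.relationship_type not in (
            "chemical-gene",
            "chemical-disease",
            "gene-disease",
            "gene-gene",
        ):
            raise ValueError(f"unknown relationship type {self.relationship_type!r}")

    @property
    def entity_types(self) -> tuple[str, str]:
        t1, t2 = self.relationship_type.split("-")
        return t1, t2


@dataclass
class GoldLabels:
    """Ground truth: which theme generated each path template and pair."""

    relationship_type: str
    path_theme: dict[str, str]
    pair_theme: dict[PairKey, str]

    def theme_symbols(self) -> list[str]:
        return sorted(set(self.path_theme.values()))

    def pairs_of(self, theme: str) -> list[PairKey]:
        return sorted(p for p, t in self.pair_theme.items() if t == theme)


@dataclass
class SyntheticCorpus:
    """Generated input files (as text) plus the gold labels."""

    pubtator: str
    conllu: str
    sentence_map: list[tuple[str, int, str]]
    gold: GoldLabels
    config: SyntheticConfig

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the three pipeline inputs plus gold labels to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "pubtator": directory / "corpus.pubtator.txt",
            "conllu": directory / "corpus.conllu",
            "sentence_map": directory / "corpus.sentences.tsv",
            "gold_paths": directory / "gold.path_themes.tsv",
            "gold_pairs": directory / "gold.pair_themes.tsv",
        }
        paths["pubtator"].write_text(self.pubtator, encoding="utf-8")
        paths["conllu"].write_text(self.conllu, encoding="utf-8")
        with open(paths["sentence_map"], "w", encoding="utf-8") as fh:
            for doc_id, snum, sid in self.sentence_map:
                fh.write(f"{doc_id}\t{snum}\t{sid}\n")
        with open(paths["gold_paths"], "w", encoding="utf-8") as fh:
            for path, theme in sorted(self.gold.path_theme.items()):
                fh.write(f"{path}\t{theme}\n")
        with open(paths["gold_pairs"], "w", encoding="utf-8") as fh:
            for (e1, e2), theme in sorted(self.gold.pair_theme.items()):
                fh.write(f"{e1}\t{e2}\t{theme}\n")
        return paths


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Template:
    """One sentence frame with its gold parse and dependency path."""

    theme: str
    keyword: str
    frame: str  # "verb" or "noun"

    def realize(
        self, e1: str, e2: str
    ) -> tuple[str, list[tuple[str, str, int, str]], int, int]:
        """Return (raw sentence text, token table, e1 offset, e2 offset).

        The token table rows are (form, lemma, head, deprel) over the
        *concatenated* sentence; e1/e2 are raw surfaces (may contain
        spaces) and the offsets locate them in the raw sentence text.
        """
        u1, u2 = e1.replace(" ", "_"), e2.replace(" ", "_")
        if self.frame == "verb":
            tokens = [
                (u1, u1, 2, "nsubj"),
                (self.keyword, self.keyword, 0, "root"),
                (u2, u2, 2, "obj"),
                (".", ".", 2, "punct"),
            ]
            e1_pos, e2_pos = 0, 2
        else:
            tokens = [
                (u1, u1, 4, "nsubj"),
                ("is", "be", 4, "cop"),
                ("a", "a", 4, "det"),
                (self.keyword, self.keyword, 0, "root"),
                ("of", "of", 6, "case"),
                (u2, u2, 4, "nmod"),
                (".", ".", 4, "punct"),
            ]
            e1_pos, e2_pos = 0, 5
        raw_tokens = [
            e1 if i == e1_pos else (e2 if i == e2_pos else form)
            for i, (form, _, _, _) in enumerate(tokens)
        ]
        raw = " ".join(raw_tokens)
        offsets = []
        cursor = 0
        for tok in raw_tokens:
            offsets.append(cursor)
            cursor += len(tok) + 1
        return raw, tokens, offsets[e1_pos], offsets[e2_pos]

    @property
    def forward_path(self) -> str:
        if self.frame == "verb":
            return f"{self.keyword}|nsubj|START_ENTITY {self.keyword}|obj|END_ENTITY"
        return f"{self.keyword}|nsubj|START_ENTITY {self.keyword}|nmod|END_ENTITY"

    @property
    def reverse_path(self) -> str:
        """The path seen when extraction runs from the second entity back."""
        if self.frame == "verb":
            return f"{self.keyword}|obj|START_ENTITY {self.keyword}|nsubj|END_ENTITY"
        return f"{self.keyword}|nmod|START_ENTITY {self.keyword}|nsubj|END_ENTITY"


def _make_templates(config: SyntheticConfig) -> dict[str, list[_Template]]:
    out: dict[str, list[_Template]] = {}
    for t in range(config.n_themes):
        theme = f"T{t + 1}"
        templates = []
        for k in range(config.paths_per_theme):
            if k % 2 == 0:
                templates.append(_Template(theme, f"affects{t + 1}x{k}", "verb"))
            else:
                templates.append(_Template(theme, f"modulator{t + 1}x{k}", "noun"))
        out[theme] = templates
    return out


def _entity_vocab(prefix: str, n: int) -> list[str]:
    """Entity surfaces; every fourth one is multi-word to exercise
    underscore concatenation."""
    vocab = []
    for i in range(n):
        if i % 4 == 3:
            vocab.append(f"{prefix} complex {i}")
        else:
            vocab.append(f"{prefix}{i}")
    return vocab


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def generate_theme_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a corpus whose pair-path incidence has planted theme blocks.

    Deterministic per ``config.seed``.  Each pair of a theme is connected
    by a random subset of ``sightings_per_pair`` of its theme's templates;
    each sighting additionally emits a random other-theme sentence for the
    same pair with probability ``noise``.
    """
    rng = np.random.default_rng(config.seed)
    t1, t2 = config.entity_types
    vocab1 = _entity_vocab(_TYPE_PREFIX[t1], config.n_entities_type1)
    vocab2 = _entity_vocab(_TYPE_PREFIX[t2], config.n_entities_type2)

    n_pairs = config.n_themes * config.pairs_per_theme
    max_pairs = len(vocab1) * len(vocab2)
    if t1 == t2:
        max_pairs = len(vocab1) * (len(vocab1) - 1)
    if n_pairs > max_pairs:
        raise ValueError(
            f"vocabulary too small: {n_pairs} pairs requested, {max_pairs} possible"
        )

    templates = _make_templates(config)
    themes = sorted(templates)

    # sample globally unique pairs and deal them to themes
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(pairs) < n_pairs:
        e1 = vocab1[rng.integers(len(vocab1))]
        e2 = vocab2[rng.integers(len(vocab2))]
        if t1 == t2 and e1 == e2:
            continue
        if (e1, e2) in seen or (t1 == t2 and (e2, e1) in seen):
            continue
        seen.add((e1, e2))
        pairs.append((e1, e2))
    pair_theme_raw: dict[tuple[str, str], str] = {}
    for i, pair in enumerate(pairs):
        pair_theme_raw[pair] = themes[i // config.pairs_per_theme]

    # plan sightings: (raw_e1, raw_e2, template); each pair draws a random
    # subset of its theme's templates so that any two templates of a theme
    # co-occur on some pairs (the property the co-clustering relies on)
    sightings: list[tuple[str, str, _Template]] = []
    for theme in themes:
        for e1, e2 in (p for p in pairs if pair_theme_raw[p] == theme):
            k = min(config.sightings_per_pair, config.paths_per_theme)
            chosen = rng.choice(config.paths_per_theme, size=k, replace=False)
            for idx in chosen:
                tpl = templates[theme][idx]
                sightings.append((e1, e2, tpl))
                if config.noise > 0 and rng.random() < config.noise:
                    other = themes[
                        (themes.index(theme) + 1 + rng.integers(config.n_themes - 1))
                        % config.n_themes
                    ]
                    noisy = templates[other][rng.integers(config.paths_per_theme)]
                    sightings.append((e1, e2, noisy))

    return _emit(config, sightings, pair_theme_raw, templates)


def _emit(config, sightings, pair_theme_raw, templates) -> SyntheticCorpus:
    t1, t2 = config.entity_types
    vocab_index1: dict[str, int] = {}
    vocab_index2: dict[str, int] = {}

    def db_id(etype: str, surface: str, index: dict[str, int]) -> str:
        if surface not in index:
            index[surface] = len(index)
        return f"{_TYPE_DB[etype]}{index[surface]:05d}"

    pubtator_blocks: list[str] = []
    conllu_blocks: list[str] = []
    sentence_map: list[tuple[str, int, str]] = []

    docs = [
        sightings[i : i + config.sentences_per_doc]
        for i in range(0, len(sightings), config.sentences_per_doc)
    ]
    for d, doc_sightings in enumerate(docs):
        pmid = str(9000000 + d)
        title = f"Synthetic abstract {d} ."
        title_tokens = [
            ("Synthetic", "synthetic", 2, "amod"),
            ("abstract", "abstract", 0, "root"),
            (str(d), str(d), 2, "nummod"),
            (".", ".", 2, "punct"),
        ]
        sent_texts: list[str] = []
        mention_lines: list[str] = []
        conllu_blocks.append(_conllu_block(f"{pmid}.0", title, title_tokens))
        sentence_map.append((pmid, 0, f"{pmid}.0"))

        offset = len(title) + 1  # abstract starts after "title + space"
        for s, (e1, e2, tpl) in enumerate(doc_sightings, start=1):
            raw, tokens, off1, off2 = tpl.realize(e1, e2)
            sent_texts.append(raw)
            concatenated = " ".join(form for form, _, _, _ in tokens)
            sid = f"{pmid}.{s}"
            conllu_blocks.append(_conllu_block(sid, concatenated, tokens))
            sentence_map.append((pmid, s, sid))
            start1 = offset + off1
            mention_lines.append(
                f"{pmid}\t{start1}\t{start1 + len(e1)}\t{e1}\t{t1.capitalize()}\t"
                f"{db_id(t1, e1, vocab_index1)}"
            )
            start2 = offset + off2
            mention_lines.append(
                f"{pmid}\t{start2}\t{start2 + len(e2)}\t{e2}\t{t2.capitalize()}\t"
                f"{db_id(t2, e2, vocab_index2)}"
            )
            offset += len(raw) + 1
        abstract = " ".join(sent_texts)
        block = [f"{pmid}|t|{title}", f"{pmid}|a|{abstract}"] + mention_lines
        pubtator_blocks.append("\n".join(block))

    # gold labels over normalized pair keys and formatted paths
    path_theme: dict[str, str] = {}
    for theme, tpls in templates.items():
        for tpl in tpls:
            path_theme[tpl.forward_path] = theme
            if t1 == t2:
                path_theme[tpl.reverse_path] = theme
    pair_theme: dict[PairKey, str] = {}
    for (e1, e2), theme in pair_theme_raw.items():
        key = (e1.replace(" ", "_").lower(), e2.replace(" ", "_").lower())
        pair_theme[key] = theme
        if t1 == t2:
            pair_theme[(key[1], key[0])] = theme

    return SyntheticCorpus(
        pubtator="\n\n".join(pubtator_blocks) + "\n",
        conllu="\n\n".join(conllu_blocks) + "\n",
        sentence_map=sentence_map,
        gold=GoldLabels(config.relationship_type, path_theme, pair_theme),
        config=config,
    )


def _conllu_block(sent_id: str, text: str, tokens) -> str:
    lines = [f"# sent_id = {sent_id}", f"# text = {text}"]
    for i, (form, lemma, head, deprel) in enumerate(tokens, start=1):
        lines.append(f"{i}\t{form}\t{lemma}\t_\t_\t_\t{head}\t{deprel}\t_\t_")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# planted matrices and reference databases
# ---------------------------------------------------------------------------


def generate_planted_matrix(
    n_rows: int,
    n_cols: int,
    K: int,
    L: int,
    flip_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A K x L block-constant binary matrix with independent cell flips.

    The block pattern is redrawn until its block-rows and block-columns
    are pairwise distinct and no margin is all-zero, so the planted
    structure is identifiable.  Returns (matrix, gold row blocks, gold
    column blocks).
    """
    if K > n_rows or L > n_cols:
        raise ValueError("K and L cannot exceed the matrix dimensions")
    rng = np.random.default_rng(seed)
    while True:
        pattern = rng.integers(0, 2, size=(K, L))
        rows_ok = len({tuple(r) for r in pattern}) == K and pattern.sum(axis=1).min() > 0
        cols_ok = len({tuple(c) for c in pattern.T}) == L and pattern.sum(axis=0).min() > 0
        if rows_ok and cols_ok:
            break
    row_blocks = np.sort(np.arange(n_rows) % K)
    col_blocks = np.sort(np.arange(n_cols) % L)
    m = pattern[np.ix_(row_blocks, col_blocks)].copy()
    if flip_noise > 0:
        flips = rng.random(m.shape) < flip_noise
        m = np.where(flips, 1 - m, m)
    return m.astype(int), row_blocks, col_blocks


def generate_reference_db(
    gold: GoldLabels, theme: str, positive_fraction: float = 1.0, seed: int = 0
) -> ReferenceRelationSet:
    """A reference relation set drawn from one latent theme's pairs."""
    pairs = gold.pairs_of(theme)
    if not pairs:
        raise KeyError(f"theme {theme!r} has no pairs in the gold labels")
    rng = np.random.default_rng(seed)
    n = int(round(positive_fraction * len(pairs)))
    n = max(1, min(n, len(pairs)))
    idx = sorted(rng.choice(len(pairs), size=n, replace=False))
    return ReferenceRelationSet(
        name=f"synthetic-{theme}",
        relationship_type=gold.relationship_type,
        positives={pairs[i] for i in idx},
    )


def label_clusters_by_gold(cluster_set, gold: GoldLabels) -> dict[str, str]:
    """Label each cluster with the majority gold theme of its member paths.

    Paths without a gold label are ignored; ties break toward the
    lexicographically smallest theme symbol.  Useful as a stand-in for the
    human annotation step when running on synthetic corpora.
    """
    labels: dict[str, str] = {}
    for cid, paths in cluster_set.clusters.items():
        votes: dict[str, int] = {}
        for p in paths:
            theme = gold.path_theme.get(p)
            if theme is not None:
                votes[theme] = votes.get(theme, 0) + 1
        if votes:
            labels[cid] = min(votes, key=lambda t: (-votes[t], t))
    return labels
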