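"""End-to-end orchestration of the network construction stages.

Glue only: each step lives in its own module.  The flow mirrors the
intended use — extract path records, build the clustering matrix for one
relationship type, run the co-clustering ensemble, build and cut the
dendrogram, label clusters (by hand on real corpora, by gold labels on
synthetic ones), then score every corpus path against the flagship sets.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import dendrogram as dg
from .corpus import PathRecord, extract_corpus
from .ebc import EBCConfig, EnsembleCocluster, run_ensemble
from .matrix import (
    MatrixConfig,
    PairPathIncidence,
    build_full_incidence,
    build_incidence,
    eligible_pairs,
    path_frequencies,
    sample_pairs,
    select_paths,
)
from .scoring import build_flagship_sets, compute_supports, normalize_supports
from .simulate import GoldLabels, SyntheticCorpus, label_clusters_by_gold

logger = logging.getLogger(__name__)


def extract_synthetic(corpus: SyntheticCorpus) -> list[PathRecord]:
    """Run the file-based ingest on an in-memory synthetic corpus."""
    with tempfile.TemporaryDirectory() as tmp:
        paths = corpus.write(tmp)
        return extract_corpus(paths["pubtator"], paths["conllu"], paths["sentence_map"])


@dataclass
class ClusteringResult:
    """Artifacts of the matrix -> ensemble -> dendrogram -> cut chain."""

    incidence: PairPathIncidence
    ensemble: EnsembleCocluster
    tree: dg.MergeTree
    clusters: dg.ClusterSet

    def cluster_of(self) -> dict[str, str]:
        return {
            path: cid for cid, paths in self.clusters.clusters.items() for path in paths
        }


def cluster_paths(
    records: list[PathRecord],
    matrix_config: MatrixConfig,
    ebc_config: EBCConfig,
    n_clusters: int = dg.DEFAULT_N_CLUSTERS,
) -> ClusteringResult:
    """Vocabulary selection through dendrogram cut for one relationship type."""
    freq = path_frequencies(records)
    vocabulary = select_paths(freq, matrix_config)
    pairs = sample_pairs(eligible_pairs(records, vocabulary), matrix_config)
    incidence = build_incidence(records, vocabulary, pairs)
    ensemble = run_ensemble(incidence.matrix, ebc_config)
    dist = dg.counts_to_distance(ensemble, incidence.paths)
    tree = dg.minimax_linkage(dist)
    clusters = dg.cut_tree(tree, min(n_clusters, tree.n_leaves))
    return ClusteringResult(incidence, ensemble, tree, clusters)


@dataclass
class ScoredCorpus:
    """Theme supports and normalized scores over the full corpus."""

    full_incidence: PairPathIncidence
    flagships: dict[str, set[str]]
    supports: pd.DataFrame
    scores: pd.DataFrame


def score_records(
    records: list[PathRecord],
    clustering: ClusteringResult,
    cluster_labels: dict[str, str],
    sign_overrides: dict[str, str] | None = None,
) -> ScoredCorpus:
    """Score every corpus path against the labeled clusters' flagship sets."""
    flagships = build_flagship_sets(clustering.clusters, cluster_labels, sign_overrides)
    full = build_full_incidence(records)
    supports = compute_supports(full, flagships)
    scores = normalize_supports(supports)
    return ScoredCorpus(full, flagships, supports, scores)


def run_synthetic_pipeline(
    corpus: SyntheticCorpus,
    n_runs: int = 50,
    base_seed: int = 0,
    n_clusters: int | None = None,
) -> tuple[ClusteringResult, ScoredCorpus, GoldLabels]:
    """Extract, cluster at the gold theme count, gold-label, and score.

    The cluster-labeling step (human annotation on real corpora) is
    replaced by majority gold-theme labeling.  K and L are set to the gold
    theme count.
    """
    gold = corpus.gold
    records = extract_synthetic(corpus)
    n_themes = len(gold.theme_symbols())
    matrix_config = MatrixConfig(
        top_n_paths=len(gold.path_theme),
        min_path_occurrence=1,
        n_pairs_sampled=max(len(gold.pair_theme), 1),
        seed=base_seed,
    )
    ebc_config = EBCConfig(K=n_themes, L=n_themes, n_runs=n_runs, base_seed=base_seed)
    clustering = cluster_paths(
        records, matrix_config, ebc_config, n_clusters or n_themes
    )
    labels = label_clusters_by_gold(clustering.clusters, gold)
    scored = score_records(records, clustering, labels)
    return clustering, scored, gold
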