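"""Theme dendrograms: correlation distance, minimax linkage, cuts, review.

Two dependency paths that were co-assigned by the co-clustering ensemble at
similar rates across *all* other paths behave like synonyms, so the
distance between paths i and j is 1 - Pearson correlation of their
co-clustering frequency rows.  Minimax linkage is used for the hierarchy:
the distance between two clusters is the smallest achievable radius

    d(G, H) = min_{c in G u H}  max_{x in G u H}  d(c, x),

so every cluster in the tree has a concrete *prototype* path within merge
height of all members — a property that makes clusters reviewable by
reading the prototype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import PathRecord
from .ebc import EnsembleCocluster

logger = logging.getLogger(__name__)

#: Each dendrogram is cut to this many clusters before review.
DEFAULT_N_CLUSTERS = 30
#: Clusters with at most this many paths are not examined further.
DEFAULT_MIN_CLUSTER_SIZE = 10
#: Review sheets sample this many paths per cluster.
DEFAULT_REVIEW_PATHS = 10


@dataclass
class PathDistanceMatrix:
    labels: list[str]
    distances: np.ndarray

    def __post_init__(self):
        d = self.distances
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape disagrees with labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")


@dataclass
class MergeTree:
    """Agglomerative merge history in linkage-table form.

    ``merges`` has one row per merge: (cluster id a, cluster id b, height,
    new size), with leaves numbered 0..n-1 and the i-th merge creating
    cluster id n+i.  ``prototypes`` records, per merge, the leaf index
    whose max distance to the merged cluster's members equals the height.
    """

    merges: np.ndarray
    labels: list[str]
    prototypes: list[int] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_sets(self) -> list[set[int]]:
        """Leaf membership of every cluster id (leaves then merged)."""
        sets = [{i} for i in range(self.n_leaves)]
        for a, b, _, _ in self.merges:
            sets.append(sets[int(a)] | sets[int(b)])
        return sets


@dataclass
class ClusterSet:
    """A partition of retained dendrogram leaves into labeled clusters."""

    clusters: dict[str, list[str]]
    provenance: dict[str, dict] = field(default_factory=dict)

    def sizes(self) -> dict[str, int]:
        return {cid: len(paths) for cid, paths in self.clusters.items()}


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def counts_to_distance(ensemble: EnsembleCocluster, labels: Sequence[str]) -> PathDistanceMatrix:
    """1 - Pearson correlation of co-clustering frequency rows.

    The self-column of each frequency row is 1 by construction (a path
    always co-clusters with itself), which shifts all correlations equally
    and is kept.  A constant frequency row carries no information; its
    correlations are set to 0 (distance 1) and logged.
    """
    f = ensemble.frequencies
    n = f.shape[0]
    if n < 2:
        raise ValueError("need at least two paths to build a distance matrix")
    if len(labels) != n:
        raise ValueError("labels disagree with ensemble size")
    sd = f.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        logger.info("%d constant frequency rows; their correlations set to 0", constant.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(f)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return PathDistanceMatrix(list(labels), dist)


# ---------------------------------------------------------------------------
# minimax linkage
# ---------------------------------------------------------------------------


def _minimax_height(d: np.ndarray, members: np.ndarray) -> tuple[float, int]:
    """Smallest covering radius of ``members`` and its prototype."""
    sub = d[np.ix_(members, members)]
    radii = sub.max(axis=1)
    best = int(np.argmin(radii))
    return float(radii[best]), int(members[best])


def minimax_linkage(distance: PathDistanceMatrix | np.ndarray) -> MergeTree:
    """Agglomerative clustering with minimax (prototype) linkage.

    At every step the pair of active clusters whose union has the smallest
    covering radius is merged; ties break toward the smallest (id a, id b)
    pair.  Heights are reported as computed — minimax linkage is not
    guaranteed monotone, and no reordering is applied.
    """
    if isinstance(distance, PathDistanceMatrix):
        d = distance.distances
        labels = list(distance.labels)
    else:
        d = np.asarray(distance, dtype=float)
        labels = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    active: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    merges = np.zeros((n - 1, 4))
    prototypes: list[int] = []
    # cache of candidate merge heights keyed by (id a, id b), a < b
    heights: dict[tuple[int, int], tuple[float, int]] = {}
    for a in range(n):
        for b in range(a + 1, n):
            heights[(a, b)] = _minimax_height(d, np.array([a, b]))
    next_id = n
    for step in range(n - 1):
        (a, b), (h, proto) = min(heights.items(), key=lambda kv: (kv[1][0], kv[0]))
        union = np.concatenate([active[a], active[b]])
        merges[step] = (a, b, h, len(union))
        prototypes.append(proto)
        del active[a], active[b]
        heights = {k: v for k, v in heights.items() if a not in k and b not in k}
        for other, members in active.items():
            key = (min(other, next_id), max(other, next_id))
            heights[key] = _minimax_height(d, np.concatenate([members, union]))
        active[next_id] = union
        next_id += 1
    return MergeTree(merges, labels, prototypes)


def to_linkage_table(tree: MergeTree) -> np.ndarray:
    """The merge history as a standard (n-1, 4) linkage array."""
    return tree.merges.copy()


def to_newick(tree: MergeTree) -> str:
    """Serialize the merge tree as Newick with escaped leaf names."""

    def escape(label: str) -> str:
        return "'" + label.replace("'", "''") + "'"

    reps: dict[int, str] = {
        i: escape(lbl) for i, lbl in enumerate(tree.labels)
    }
    n = tree.n_leaves
    for step, (a, b, h, _) in enumerate(tree.merges):
        reps[n + step] = f"({reps[int(a)]},{reps[int(b)]}):{h:.6g}"
    return reps[n + len(tree.merges) - 1] + ";"


# ---------------------------------------------------------------------------
# cutting and pruning
# ---------------------------------------------------------------------------


def _partition_by_merges(
    n_items: int, merge_pairs: Sequence[tuple[int, int]], n_apply: int, offset: int
) -> list[list[int]]:
    """Union-find application of the first ``n_apply`` merges."""
    parent = list(range(n_items))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    groups: dict[int, int] = {i: i for i in range(n_items)}  # cluster id -> representative
    for step, (a, b) in enumerate(merge_pairs[:n_apply]):
        ra, rb = find(groups[a]), find(groups[b])
        parent[rb] = ra
        groups[offset + step] = ra
    out: dict[int, list[int]] = {}
    for i in range(n_items):
        out.setdefault(find(i), []).append(i)
    return sorted(out.values(), key=lambda g: g[0])


def cut_tree(tree: MergeTree, n_clusters: int = DEFAULT_N_CLUSTERS) -> ClusterSet:
    """Cut the dendrogram into exactly ``n_clusters`` clusters.

    The cut undoes the last ``n_clusters - 1`` merges, i.e. applies merges
    in their recorded order until that many clusters remain; this is
    well defined even where the linkage heights are non-monotone.
    Cluster ids are "1".."k", ordered by each cluster's first leaf.
    """
    n = tree.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in 1..{n}")
    pairs = [(int(a), int(b)) for a, b, _, _ in tree.merges]
    groups = _partition_by_merges(n, pairs, n - n_clusters, offset=n)
    clusters = {
        str(cid): [tree.labels[i] for i in group]
        for cid, group in enumerate(groups, start=1)
    }
    provenance = {cid: {"cut_level": n_clusters} for cid in clusters}
    return ClusterSet(clusters, provenance)


def prune_small(cluster_set: ClusterSet, min_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> ClusterSet:
    """Drop clusters with ``min_size`` or fewer paths (default 10)."""
    kept, removed = {}, []
    for cid, paths in cluster_set.clusters.items():
        if len(paths) <= min_size:
            removed.append(cid)
        else:
            kept[cid] = list(paths)
    if removed:
        logger.info("pruned %d small clusters: %s", len(removed), ", ".join(removed))
    prov = {cid: dict(cluster_set.provenance.get(cid, {})) for cid in kept}
    return ClusterSet(kept, prov)


def subcut(
    cluster_set: ClusterSet, cluster_id: str, n_subclusters: int, tree: MergeTree
) -> ClusterSet:
    """Split one cluster into ``n_subclusters`` at the appropriate sub-cut.

    Replays the merges internal to the cluster's leaves and undoes the last
    ``n_subclusters - 1`` of them.  Children are named
    ``"<cluster_id>.1"``.. and record their parent in the provenance.
    """
    if cluster_id not in cluster_set.clusters:
        raise KeyError(f"unknown cluster id {cluster_id!r}")
    leaves = cluster_set.clusters[cluster_id]
    if not 1 <= n_subclusters <= len(leaves):
        raise ValueError("n_subclusters must be between 1 and the cluster size")
    if n_subclusters == 1:
        return cluster_set
    label_to_leaf = {lbl: i for i, lbl in enumerate(tree.labels)}
    leaf_ids = {label_to_leaf[lbl] for lbl in leaves}
    leaf_sets = tree.leaf_sets()
    internal = [
        (int(a), int(b))
        for a, b, _, _ in tree.merges
        if leaf_sets[int(a)] <= leaf_ids and leaf_sets[int(b)] <= leaf_ids
    ]
    # re-index the cluster's leaves locally; merge operands are mapped to a
    # representative leaf (the smallest leaf of their set), so union-find
    # runs purely over leaves
    local = {leaf: i for i, leaf in enumerate(sorted(leaf_ids))}
    pairs = [
        (local[min(leaf_sets[a])], local[min(leaf_sets[b])]) for a, b in internal
    ]
    groups = _partition_by_merges(len(local), pairs, len(local) - n_subclusters, offset=len(local))
    inv = {i: leaf for leaf, i in local.items()}
    clusters = {cid: list(paths) for cid, paths in cluster_set.clusters.items() if cid != cluster_id}
    prov = {cid: dict(cluster_set.provenance.get(cid, {})) for cid in clusters}
    for child, group in enumerate(groups, start=1):
        child_id = f"{cluster_id}.{child}"
        clusters[child_id] = [tree.labels[inv[i]] for i in group]
        prov[child_id] = {"parent": cluster_id, "sub_cut": n_subclusters}
    return ClusterSet(clusters, prov)


# ---------------------------------------------------------------------------
# review sheets
# ---------------------------------------------------------------------------


def sample_review_sheet(
    cluster_set: ClusterSet,
    part2_records: Sequence[PathRecord],
    n_paths: int = DEFAULT_REVIEW_PATHS,
    n_sentences: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample paths and example sentences per cluster for human labeling.

    Per cluster, up to ``n_paths`` paths are drawn without replacement,
    each with up to ``n_sentences`` corpus sentences containing it.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_path: dict[str, list[PathRecord]] = {}
    for rec in part2_records:
        by_path.setdefault(rec.path, []).append(rec)
    rows = []
    for cid in sorted(cluster_set.clusters, key=_cluster_sort_key):
        paths = sorted(cluster_set.clusters[cid])
        take = min(n_paths, len(paths))
        chosen = [paths[i] for i in sorted(rng.choice(len(paths), size=take, replace=False))]
        for path in chosen:
            examples = by_path.get(path, [])
            k = min(n_sentences, len(examples))
            if examples:
                picked = [examples[i] for i in sorted(rng.choice(len(examples), size=k, replace=False))]
            else:
                picked = []
            if not picked:
                rows.append({"cluster": cid, "path": path, "doc_id": "", "sentence": ""})
            for rec in picked:
                rows.append(
                    {"cluster": cid, "path": path, "doc_id": rec.doc_id, "sentence": rec.sentence}
                )
    return pd.DataFrame(rows, columns=["cluster", "path", "doc_id", "sentence"])


def _cluster_sort_key(cid: str):
    return tuple(int(part) if part.isdigit() else part for part in cid.split("."))
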