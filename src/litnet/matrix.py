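"""Binary entity-pair x dependency-path incidence matrices.

The clustering substrate is a binary matrix with one row per typed entity
pair and one column per formatted dependency path: cell (i, j) is 1 iff
path j connects pair i anywhere in the corpus.  Only the most frequent
paths are clustered (the dendrograms must stay reviewable), and a fixed
number of entity pairs is sampled from those connected by at least one
vocabulary path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus import PathRecord

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]


@dataclass
class MatrixConfig:
    """Vocabulary and sampling knobs for matrix construction.

    ``top_n_paths`` caps the clustered path vocabulary (~700 per
    relationship type by default), ``min_path_occurrence`` drops rare paths
    before the cap is applied, and ``n_pairs_sampled`` rows are drawn
    uniformly without replacement from the eligible pairs.
    """

    top_n_paths: int = 700
    min_path_occurrence: int = 50
    n_pairs_sampled: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.top_n_paths < 1 or self.n_pairs_sampled < 1:
            raise ValueError("top_n_paths and n_pairs_sampled must be >= 1")


@dataclass
class PairPathIncidence:
    """Binary incidence between typed entity pairs and dependency paths."""

    pairs: list[PairKey]
    paths: list[str]
    matrix: sp.csr_matrix
    pair_type: str | None = None

    def __post_init__(self):
        if self.matrix.shape != (len(self.pairs), len(self.paths)):
            raise ValueError("matrix shape disagrees with labels")

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense(), dtype=float)

    @property
    def pair_index(self) -> dict[PairKey, int]:
        return {p: i for i, p in enumerate(self.pairs)}

    @property
    def path_index(self) -> dict[str, int]:
        return {p: j for j, p in enumerate(self.paths)}


def path_frequencies(records: Sequence[PathRecord]) -> pd.Series:
    """Occurrence count (sentence-level record count) per formatted path."""
    counts = pd.Series([r.path for r in records]).value_counts()
    counts.index.name = "path"
    return counts


def select_paths(path_frequency_table: pd.Series | dict, config: MatrixConfig) -> list[str]:
    """Pick the most frequent paths, at most ``top_n_paths`` of them.

    Paths below ``min_path_occurrence`` are ineligible.  Frequency ties are
    broken lexicographically so the vocabulary is deterministic.
    """
    freq = pd.Series(path_frequency_table)
    if (freq <= 0).any():
        raise ValueError("path frequencies must be positive integers")
    freq = freq[freq >= config.min_path_occurrence]
    ordered = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) < config.top_n_paths:
        logger.warning(
            "only %d paths eligible (requested %d); keeping all",
            len(ordered),
            config.top_n_paths,
        )
    return [path for path, _ in ordered[: config.top_n_paths]]


def eligible_pairs(records: Sequence[PathRecord], vocabulary: Iterable[str]) -> list[PairKey]:
    """Pairs connected by at least one vocabulary path, in sorted order."""
    vocab = set(vocabulary)
    return sorted({r.pair_key for r in records if r.path in vocab})


def sample_pairs(eligible: Sequence[PairKey], config: MatrixConfig) -> list[PairKey]:
    """Uniform sample without replacement of ``n_pairs_sampled`` pairs.

    Reproducible under ``config.seed``; returns the whole population when
    it is smaller than the requested sample.
    """
    if not eligible:
        raise ValueError("no eligible entity pairs to sample from")
    population = sorted(eligible)
    if len(population) <= config.n_pairs_sampled:
        return population
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(len(population), size=config.n_pairs_sampled, replace=False)
    return sorted(population[i] for i in idx)


def build_incidence(
    path_records: Sequence[PathRecord],
    vocabulary: Sequence[str],
    pair_sample: Sequence[PairKey] | None = None,
) -> PairPathIncidence:
    """Assemble the binary incidence matrix.

    Repeated sightings of the same (pair, path) still give a single 1.
    Rows and columns that end up all-zero are dropped (with a logged
    count) so the co-clustering input has no empty margins.
    """
    pair_types = {r.pair_type for r in path_records}
    if len(pair_types) > 1:
        raise ValueError(f"records mix relationship types: {sorted(pair_types)}")
    pair_type = pair_types.pop() if pair_types else None

    vocab_index = {p: j for j, p in enumerate(vocabulary)}
    if pair_sample is None:
        pair_sample = sorted({r.pair_key for r in path_records})
    pair_index = {p: i for i, p in enumerate(pair_sample)}

    rows, cols = [], []
    seen: set[tuple[int, int]] = set()
    for r in path_records:
        i = pair_index.get(r.pair_key)
        j = vocab_index.get(r.path)
        if i is None or j is None or (i, j) in seen:
            continue
        seen.add((i, j))
        rows.append(i)
        cols.append(j)
    m = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(pair_sample), len(vocabulary)),
    )
    row_keep = np.flatnonzero(m.getnnz(axis=1) > 0)
    col_keep = np.flatnonzero(m.getnnz(axis=0) > 0)
    dropped_rows = m.shape[0] - len(row_keep)
    dropped_cols = m.shape[1] - len(col_keep)
    if dropped_rows or dropped_cols:
        logger.info("dropped %d all-zero rows and %d all-zero columns", dropped_rows, dropped_cols)
    m = m[row_keep][:, col_keep].tocsr()
    return PairPathIncidence(
        pairs=[pair_sample[i] for i in row_keep],
        paths=[vocabulary[j] for j in col_keep],
        matrix=m,
        pair_type=pair_type,
    )


def build_full_incidence(records: Sequence[PathRecord]) -> PairPathIncidence:
    """Incidence over ALL corpus paths and pairs of one relationship type.

    This is the substrate for theme-support counting, which must see every
    path, not just the clustered vocabulary.
    """
    vocabulary = sorted({r.path for r in records})
    return build_incidence(records, vocabulary)


# ---------------------------------------------------------------------------
# sparse triplet persistence
# ---------------------------------------------------------------------------


def write_incidence(incidence: PairPathIncidence, prefix: str | Path) -> None:
    """Write the matrix as triplet TSV plus row/column label files."""
    prefix = Path(prefix)
    coo = incidence.matrix.tocoo()
    with open(f"{prefix}.triplets.tsv", "w", encoding="utf-8") as fh:
        fh.write("row\tcol\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{int(v)}\n")
    with open(f"{prefix}.rows.tsv", "w", encoding="utf-8") as fh:
        fh.write("entity1\tentity2\tpair_type\n")
        for e1, e2 in incidence.pairs:
            fh.write(f"{e1}\t{e2}\t{incidence.pair_type or ''}\n")
    with open(f"{prefix}.cols.tsv", "w", encoding="utf-8") as fh:
        fh.write("path\n")
        for p in incidence.paths:
            fh.write(p + "\n")


def read_incidence(prefix: str | Path) -> PairPathIncidence:
    prefix = Path(prefix)
    pairs: list[PairKey] = []
    pair_type = None
    with open(f"{prefix}.rows.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            e1, e2, pt = line.rstrip("\n").split("\t")
            pairs.append((e1, e2))
            pair_type = pt or None
    with open(f"{prefix}.cols.tsv", encoding="utf-8") as fh:
        next(fh)
        paths = [line.rstrip("\n") for line in fh]
    rows, cols, vals = [], [], []
    with open(f"{prefix}.triplets.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            i, j, v = line.split("\t")
            rows.append(int(i))
            cols.append(int(j))
            vals.append(int(v))
    m = sp.csr_matrix((vals, (rows, cols)), shape=(len(pairs), len(paths)), dtype=np.int8)
    return PairPathIncidence(pairs, paths, m, pair_type)
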