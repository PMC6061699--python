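"""Flagship path sets and theme supports.

Only the clustered high-frequency vocabulary ever receives a theme label
directly; those labeled paths are the *flagship paths* of each theme.
Every other corpus path is scored against them by co-occurrence: the
support of path p for theme t is the number of (entity pair, flagship
path f) combinations with f in t's flagship set, f != p, and both p and f
connecting that pair.  Normalizing a path's supports across themes (they
then sum to 1) keeps rare paths from being swamped by common ones; paths
with zero total support cannot be scored and are excluded from the
network's path-theme table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import PairPathIncidence
from .schema import ThemeSchema

logger = logging.getLogger(__name__)

FlagshipSets = dict[str, set[str]]


def read_label_file(source: str | Path) -> dict[str, str]:
    """Read a cluster->theme label TSV (``cluster_id\\ttheme_symbol``)."""
    labels: dict[str, str] = {}
    for ln, line in enumerate(Path(source).read_text("utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"label file line {ln}: expected 2 columns")
        labels[parts[0]] = parts[1]
    return labels


def read_sign_overrides(source: str | Path) -> dict[str, str]:
    """Read a path->signed-symbol override TSV (``path\\tsigned_symbol``)."""
    overrides: dict[str, str] = {}
    for ln, line in enumerate(Path(source).read_text("utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"sign override file line {ln}: expected 2 columns")
        path, symbol = parts
        if path in overrides and overrides[path] != symbol:
            raise ValueError(f"path {path!r} assigned two signs")
        overrides[path] = symbol
    return overrides


def build_flagship_sets(
    cluster_set,
    labels: Mapping[str, str],
    sign_overrides: Mapping[str, str] | None = None,
) -> FlagshipSets:
    """Union labeled clusters into per-theme flagship path sets.

    ``labels`` maps cluster ids to theme symbols; several clusters may
    share a theme.  ``sign_overrides`` moves individual paths between the
    sign variants of a theme family (e.g. from E to E-): the path is
    removed from every same-family set it was placed in and added to the
    override's signed set.
    """
    flagships: FlagshipSets = {}
    for cid, symbol in labels.items():
        if cid not in cluster_set.clusters:
            raise KeyError(f"label references unknown cluster {cid!r}")
        flagships.setdefault(symbol, set()).update(cluster_set.clusters[cid])
    if sign_overrides:
        seen: dict[str, str] = {}
        for path, symbol in sign_overrides.items():
            if path in seen and seen[path] != symbol:
                raise ValueError(f"path {path!r} assigned two signs")
            seen[path] = symbol
            family = symbol.rstrip("+-")
            for other, paths in flagships.items():
                if other.rstrip("+-") == family:
                    paths.discard(path)
            flagships.setdefault(symbol, set()).add(path)
    flagships = {sym: paths for sym, paths in flagships.items() if paths}
    return flagships


def compute_supports(
    incidence: PairPathIncidence, flagship_sets: FlagshipSets
) -> pd.DataFrame:
    """Raw theme supports for every corpus path.

    ``incidence`` must cover the full corpus of the relationship type (all
    paths, all pairs), not just the clustered vocabulary.  Returns a frame
    indexed by path with one integer ``support_<symbol>`` column and one
    0/1 ``flagship_<symbol>`` column per theme.  A flagship path does not
    count itself as a co-occurring flagship.
    """
    if not flagship_sets or all(not s for s in flagship_sets.values()):
        raise ValueError("flagship sets are empty; label clusters first")
    M = incidence.matrix.astype(np.int64).tocsc()
    path_index = incidence.path_index
    n_paths = len(incidence.paths)
    out = pd.DataFrame(index=pd.Index(incidence.paths, name="path"))
    col_pair_counts = np.asarray(M.sum(axis=0)).ravel()  # pairs per path
    for symbol in sorted(flagship_sets):
        fvec = np.zeros(n_paths, dtype=np.int64)
        missing = 0
        for f in flagship_sets[symbol]:
            j = path_index.get(f)
            if j is None:
                missing += 1
                continue
            fvec[j] = 1
        if missing:
            logger.warning(
                "theme %s: %d flagship paths absent from the incidence", symbol, missing
            )
        per_pair = M @ fvec  # flagship paths of this theme on each pair
        support = M.T @ per_pair
        support = np.asarray(support).ravel()
        # self-exclusion: a flagship path p counted itself once per pair it connects
        support = support - fvec * col_pair_counts
        out[f"support_{symbol}"] = support.astype(np.int64)
        out[f"flagship_{symbol}"] = fvec
    return out


def normalize_supports(supports: pd.DataFrame) -> pd.DataFrame:
    """Per-path normalized theme scores (fractions summing to 1).

    Rows whose total support is zero cannot be normalized; they are
    dropped (these are the paths excluded from the path-theme table).
    """
    support_cols = [c for c in supports.columns if c.startswith("support_")]
    raw = supports[support_cols].to_numpy(dtype=float)
    totals = raw.sum(axis=1)
    keep = totals > 0
    if (~keep).any():
        logger.info("%d paths have zero total support and are excluded", int((~keep).sum()))
    scores = raw[keep] / totals[keep, None]
    out = pd.DataFrame(
        scores,
        index=supports.index[keep],
        columns=[c.replace("support_", "score_") for c in support_cols],
    )
    return out


def score_table(
    incidence: PairPathIncidence,
    flagship_sets: FlagshipSets,
    schema: ThemeSchema | None = None,
    relationship_type: str | None = None,
) -> pd.DataFrame:
    """Supports ordered by the schema's theme order for one relationship type."""
    supports = compute_supports(incidence, flagship_sets)
    if schema is not None and relationship_type is not None:
        ordered = []
        for sym in schema.symbols(relationship_type):
            if f"support_{sym}" in supports.columns:
                ordered += [f"support_{sym}", f"flagship_{sym}"]
        extras = [c for c in supports.columns if c not in ordered]
        supports = supports[ordered + extras]
    return supports
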