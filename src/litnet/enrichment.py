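"""Bootstrap-AUC enrichment of themes against reference relation sets.

A curated database contributes a set of positive entity pairs; all other
corpus pairs of the same relationship type (with at least one scoreable
path) form the negative background.  Per bootstrap replicate both sets are
resampled with replacement, every dependency path connecting a sampled
pair is collected (once per drawn pair, so pairs drawn twice contribute
their paths twice), path instances are ranked by their normalized score
for the theme under test, and the AUC against the positive/background
labels is computed.  A theme is *enriched* for the database when its mean
AUC across replicates exceeds 0.5 by more than one standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import PairKey, PairPathIncidence
from .normalize import normalize_entity_string
from .schema import ThemeSchema

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 100


@dataclass
class ReferenceRelationSet:
    """Positive entity pairs from one curated relation source."""

    name: str
    relationship_type: str
    positives: set[PairKey]

    def filtered_to(self, incidence: PairPathIncidence) -> "ReferenceRelationSet":
        present = self.positives & set(incidence.pairs)
        if not present:
            raise ValueError(
                f"reference set {self.name!r}: no positive pair occurs in the corpus"
            )
        return ReferenceRelationSet(self.name, self.relationship_type, present)


@dataclass
class EnrichmentResult:
    theme: str
    aucs: np.ndarray
    n_redraws: int = 0

    @property
    def mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.aucs) > 1 else 0.0

    @property
    def enriched(self) -> bool:
        """Mean AUC more than one standard deviation above 0.5 (strict)."""
        return self.mean > 0.5 + self.sd


def read_reference_tsv(
    source: str | Path, name: str | None = None, relationship_type: str = ""
) -> ReferenceRelationSet:
    """Read a two-column entity-pair TSV ('#' comments allowed)."""
    positives: set[PairKey] = set()
    for ln, line in enumerate(Path(source).read_text("utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"reference file line {ln}: expected 2 columns")
        positives.add((normalize_entity_string(parts[0]), normalize_entity_string(parts[1])))
    return ReferenceRelationSet(name or Path(source).stem, relationship_type, positives)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC of ``scores`` ranking positives over negatives.

    Ties contribute 0.5 per tied pair.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both a positive and a negative class")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 credit
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _scoreable_pairs(
    incidence: PairPathIncidence, score_index: Mapping[str, int]
) -> dict[PairKey, np.ndarray]:
    """Map each pair to the score-row indices of its scoreable paths."""
    csr = incidence.matrix.tocsr()
    out: dict[PairKey, np.ndarray] = {}
    for i, pair in enumerate(incidence.pairs):
        cols = csr.indices[csr.indptr[i] : csr.indptr[i + 1]]
        idx = [
            score_index[incidence.paths[j]]
            for j in cols
            if incidence.paths[j] in score_index
        ]
        if idx:
            out[pair] = np.asarray(idx, dtype=int)
    return out


def bootstrap_theme_auc(
    theme: str,
    scores_by_path: pd.Series,
    incidence: PairPathIncidence,
    positives: set[PairKey],
    background: set[PairKey],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    max_redraws: int = 1000,
) -> EnrichmentResult:
    """Bootstrap the AUC of ranking path instances by one theme's scores.

    ``scores_by_path`` holds the normalized theme-score fraction per
    scoreable path.  A replicate that happens to draw a single class is
    redrawn (and counted) so exactly ``n_boot`` AUCs are reported.
    """
    if not positives or not background:
        raise ValueError("positives and background must both be non-empty")
    if positives & background:
        raise ValueError("positives and background must be disjoint")
    score_index = {p: i for i, p in enumerate(scores_by_path.index)}
    score_values = scores_by_path.to_numpy(dtype=float)
    pair_paths = _scoreable_pairs(incidence, score_index)
    pos = sorted(p for p in positives if p in pair_paths)
    neg = sorted(p for p in background if p in pair_paths)
    if not pos or not neg:
        raise ValueError("no scoreable paths for one of the classes")

    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    redraws = 0
    for rep in range(n_boot):
        for _attempt in range(max_redraws):
            sampled_pos = rng.choice(len(pos), size=len(pos), replace=True)
            sampled_neg = rng.choice(len(neg), size=len(neg), replace=True)
            idx_chunks, labels = [], []
            for i in sampled_pos:
                idx_chunks.append(pair_paths[pos[i]])
                labels.append(np.ones(len(pair_paths[pos[i]]), dtype=int))
            for i in sampled_neg:
                idx_chunks.append(pair_paths[neg[i]])
                labels.append(np.zeros(len(pair_paths[neg[i]]), dtype=int))
            label_vec = np.concatenate(labels)
            if label_vec.min() == label_vec.max():
                redraws += 1
                continue
            aucs[rep] = auc(score_values[np.concatenate(idx_chunks)], label_vec)
            break
        else:
            raise RuntimeError("exceeded max redraws for a degenerate replicate")
    if redraws:
        logger.info("theme %s: %d degenerate replicates redrawn", theme, redraws)
    return EnrichmentResult(theme, aucs, redraws)


def evaluate_all_themes(
    reference: ReferenceRelationSet,
    scores: pd.DataFrame,
    incidence: PairPathIncidence,
    schema: ThemeSchema | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> dict[str, EnrichmentResult]:
    """Bootstrap every theme of the reference's relationship type.

    ``scores`` is the normalized score table (``score_<symbol>`` columns).
    The background is every corpus pair of the type not in the reference
    set; an empty background is an error (the reference cannot cover the
    whole corpus).
    """
    if incidence.pair_type and reference.relationship_type and (
        incidence.pair_type != reference.relationship_type
    ):
        raise ValueError(
            f"reference type {reference.relationship_type!r} does not match "
            f"corpus type {incidence.pair_type!r}"
        )
    ref = reference.filtered_to(incidence)
    background = set(incidence.pairs) - ref.positives
    if not background:
        raise ValueError("reference set covers every corpus pair; empty background")
    symbols = [c.replace("score_", "") for c in scores.columns if c.startswith("score_")]
    if schema is not None and reference.relationship_type:
        known = set(schema.symbols(reference.relationship_type))
        unknown = [s for s in symbols if s not in known]
        if unknown:
            raise KeyError(f"themes absent from schema: {unknown}")
    results: dict[str, EnrichmentResult] = {}
    for i, symbol in enumerate(symbols):
        results[symbol] = bootstrap_theme_auc(
            symbol,
            scores[f"score_{symbol}"],
            incidence,
            ref.positives,
            background,
            n_boot=n_boot,
            seed=seed + i,
        )
    return results


def results_frame(results: Mapping[str, EnrichmentResult]) -> pd.DataFrame:
    """Summary table: theme, mean AUC, sd, enriched flag."""
    rows = [
        {"theme": r.theme, "mean_auc": r.mean, "sd_auc": r.sd, "enriched": r.enriched}
        for r in results.values()
    ]
    return pd.DataFrame(rows, columns=["theme", "mean_auc", "sd_auc", "enriched"])
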