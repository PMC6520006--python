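"""Pathway-level views of differential variability.

Two complementary summaries of per-gene dvar scores over a gene-set
collection (e.g. KEGG pathways):

* **Distribution study** — per-set quartiles of the member genes' dvar
  values and, collection-wide, the fraction of sets whose median dvar is
  strictly positive plus the mean of the per-set medians.

* **Preranked GSEA** — the classic weighted Kolmogorov-Smirnov-like running
  sum: genes ranked by decreasing score, hit increments proportional to
  |score|^weight (normalized to sum 1 within the set), miss decrements
  1/(N - set size); the enrichment score (ES) is the running sum's maximum
  deviation from zero. Significance by gene-label permutation, NES by
  normalizing against the mean magnitude of same-sign permutation scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, quantile
from .types import GeneSetCollection

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySummary:
    set_id: str
    n_scored: int
    median_dvar: float
    q1_dvar: float
    q3_dvar: float


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    q_value: float
    n_perm: int
    n_genes: int


def filter_sets(collection: GeneSetCollection, min_size: int, max_size: int,
                universe) -> GeneSetCollection:
    """Intersect each set with the scored universe, then filter on size.

    The intersected size (genes that actually carry a score) is what the
    size window applies to.
    """
    universe = set(universe)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for sid, members in collection:
        kept = [g for g in members if g in universe]
        if min_size <= len(kept) <= max_size:
            sets[sid] = kept
            descriptions[sid] = collection.descriptions.get(sid, "")
    dropped = len(collection) - len(sets)
    if dropped:
        log.info("filter_sets: dropped %d sets outside [%d, %d]",
                 dropped, min_size, max_size)
    if not sets:
        log.warning("filter_sets: no gene sets survive filtering")
    return GeneSetCollection(sets, descriptions)


def pathway_distribution(dvar: pd.Series, sets: GeneSetCollection
                         ) -> tuple[list[PathwaySummary], float, float]:
    """Per-set dvar quartiles, sorted by ascending median.

    Returns (summaries, fraction of sets with median strictly > 0,
    mean of the per-set medians).
    """
    if len(sets) == 0:
        raise ValueError("pathway_distribution needs at least one gene set")
    summaries = []
    for sid, members in sets:
        vals = dvar.reindex(members).dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        summaries.append(PathwaySummary(
            set_id=sid, n_scored=vals.size,
            median_dvar=quantile(vals, 0.5),
            q1_dvar=quantile(vals, 0.25),
            q3_dvar=quantile(vals, 0.75)))
    if not summaries:
        raise ValueError("no gene set has any scored member")
    summaries.sort(key=lambda s: (s.median_dvar, s.set_id))
    medians = np.array([s.median_dvar for s in summaries])
    return summaries, float(np.mean(medians > 0)), float(medians.mean())


def _running_es(deltas: np.ndarray) -> float:
    """Extremum (by magnitude, signed) of the cumulative running sum."""
    cum = np.cumsum(deltas)
    return float(cum[np.argmax(np.abs(cum))])


def enrichment_score(ranked_scores: np.ndarray, hit_mask: np.ndarray,
                     weight: float = 1.0) -> float:
    """ES of one set given scores sorted in ranking order and a hit mask."""
    nh = int(hit_mask.sum())
    n = ranked_scores.size
    if nh == 0 or nh == n:
        raise ValueError("set must hit a strict subset of the ranking")
    w = np.abs(ranked_scores) ** weight
    nr = w[hit_mask].sum()
    if nr == 0:
        raise ValueError("all member scores are zero: ES undefined")
    deltas = np.where(hit_mask, w / nr, -1.0 / (n - nh))
    return _running_es(deltas)


def gsea_preranked(scores: pd.Series, sets: GeneSetCollection,
                   n_perm: int = 1000, weight: float = 1.0,
                   seed: int = 0) -> list[EnrichmentResult]:
    """Preranked gene-set enrichment over all sets in the collection.

    ``scores`` is a per-gene Series (unique index). Ranking is by decreasing
    score with ties broken by gene id for determinism. The null permutes
    gene labels: each permutation assigns the set to a random same-size
    subset of positions. The empirical p uses the add-one correction among
    same-sign permutation scores; q-values are BH across sets. Sets whose
    member scores are all zero (weight > 0) are skipped with a warning.
    """
    if scores.index.has_duplicates:
        raise ValueError("gene ids in scores must be unique")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("scores must be finite")
    order = sorted(scores.index, key=lambda g: (-scores[g], str(g)))
    ranked = scores.reindex(order).to_numpy(dtype=float)
    pos_of = {g: i for i, g in enumerate(order)}
    n = ranked.size
    rng = np.random.default_rng(seed)
    abs_w = np.abs(ranked) ** weight

    kept: list[tuple[str, float, int]] = []
    for sid, members in sets:
        hit = np.zeros(n, dtype=bool)
        hit[[pos_of[g] for g in members if g in pos_of]] = True
        nh = int(hit.sum())
        if nh == 0 or nh == n:
            log.warning("gsea: set %s hits no strict subset, skipped", sid)
            continue
        if abs_w[hit].sum() == 0:
            log.warning("gsea: set %s has all-zero member scores, skipped", sid)
            continue
        kept.append((sid, enrichment_score(ranked, hit, weight), nh))

    results: list[EnrichmentResult] = []
    pvals = []
    null_cache: dict[int, np.ndarray] = {}
    for sid, es, nh in kept:
        if nh not in null_cache:
            null_es = np.empty(n_perm)
            miss = -1.0 / (n - nh)
            for b in range(n_perm):
                hit_pos = rng.choice(n, size=nh, replace=False)
                w_hit = abs_w[hit_pos]
                nr = w_hit.sum()
                deltas = np.full(n, miss)
                if nr == 0:
                    null_es[b] = 0.0
                    continue
                deltas[hit_pos] = w_hit / nr
                null_es[b] = _running_es(deltas)
            null_cache[nh] = null_es
        null_es = null_cache[nh]
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same_sign.size == 0:
            nes = float("nan")
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.abs(same_sign).mean()
            p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + same_sign.size)
        pvals.append(p)
        results.append(EnrichmentResult(set_id=sid, es=es, nes=float(nes),
                                        p_value=float(p), q_value=float("nan"),
                                        n_perm=n_perm, n_genes=nh))
    if results:
        qvals = bh_fdr(pvals)
        results = [EnrichmentResult(r.set_id, r.es, r.nes, r.p_value,
                                    float(q), r.n_perm, r.n_genes)
                   for r, q in zip(results, qvals)]
    return results


def pathway_table(summaries: list[PathwaySummary]) -> pd.DataFrame:
    return pd.DataFrame({
        "set_id": [s.set_id for s in summaries],
        "n_scored": [s.n_scored for s in summaries],
        "median_dvar": [s.median_dvar for s in summaries],
        "q1_dvar": [s.q1_dvar for s in summaries],
        "q3_dvar": [s.q3_dvar for s in summaries],
    })


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "set_id": [r.set_id for r in results],
        "es": [r.es for r in results],
        "nes": [r.nes for r in results],
        "p_value": [r.p_value for r in results],
        "q_value": [r.q_value for r in results],
        "n_perm": [r.n_perm for r in results],
        "n_genes": [r.n_genes for r in results],
    })
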