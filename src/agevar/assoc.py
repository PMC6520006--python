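"""Secondary association analyses.

Checks that contextualize the differential-variability results: whether
changes in expression level and changes in variability are associated
(sign-concordance Fisher test), how strongly two gene lists overlap
(Jaccard + Fisher against a universe), whether dvar correlates with an
external per-gene score (e.g. a variation-intolerance percentile), and the
extraction of cell-type-specific genes from a labelled reference expression
matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .stats import TestResult, fisher_2x2, spearman
from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_common: int
    universe_size: int
    jaccard: float
    fisher: TestResult


def mean_var_association(expr: ExpressionMatrix, meta: SampleMetadata,
                         young_range: tuple[float, float] = (20.0, 40.0),
                         old_range: tuple[float, float] = (60.0, 80.0),
                         B: int = 10_000, seed: int = 0,
                         exhaustive_limit: int = 50_000
                         ) -> tuple[pd.DataFrame, TestResult]:
    """Sign concordance of per-gene mean change and IQR change.

    For each gene, delta_mean = mean_old - mean of young-subsample means and
    delta_iqr = IQR_old - mean of young-subsample IQRs (subsamples of the
    old group's size, shared across genes). Genes are cross-tabulated by the
    signs of the two deltas (exact zeros counted as non-positive, logged)
    and association is tested with Fisher's exact test. Independence of
    level change and variability change gives an odds ratio near 1.
    """
    if expr.sample_ids != meta.sample_ids:
        raise ValueError("mean_var_association requires aligned inputs")
    age = meta.age
    young = np.flatnonzero((age >= young_range[0]) & (age <= young_range[1]))
    old = np.flatnonzero((age >= old_range[0]) & (age <= old_range[1]))
    if young.size == 0 or old.size == 0:
        raise ValueError("both age groups must be non-empty")
    x = expr.values
    y_young, y_old = x[:, young], x[:, old]
    if math.comb(young.size, old.size) <= exhaustive_limit:
        idx = np.array(list(combinations(range(young.size), old.size)))
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((B, young.size)), axis=1)[:, :old.size]
    sub = y_young[:, idx]                                    # genes x B x n_old
    young_mean = sub.mean(axis=2).mean(axis=1)
    q25, q75 = np.quantile(sub, [0.25, 0.75], axis=2, method="linear")
    young_iqr = (q75 - q25).mean(axis=1)
    q25o, q75o = np.quantile(y_old, [0.25, 0.75], axis=1, method="linear")
    delta_mean = y_old.mean(axis=1) - young_mean
    delta_iqr = (q75o - q25o) - young_iqr

    n_zero = int(np.sum(delta_mean == 0) + np.sum(delta_iqr == 0))
    if n_zero:
        log.info("mean_var_association: %d exact-zero deltas counted as "
                 "non-positive", n_zero)
    mean_up = delta_mean > 0
    iqr_up = delta_iqr > 0
    table = np.array([
        [int(np.sum(mean_up & iqr_up)), int(np.sum(mean_up & ~iqr_up))],
        [int(np.sum(~mean_up & iqr_up)), int(np.sum(~mean_up & ~iqr_up))],
    ])
    fisher = fisher_2x2(table)
    if fisher.degenerate:
        log.warning("mean_var_association: degenerate sign table %s",
                    table.tolist())
    per_gene = pd.DataFrame({
        "gene_id": expr.gene_ids,
        "delta_mean": delta_mean,
        "delta_iqr": delta_iqr,
    })
    return per_gene, fisher


def overlap_test(list_a, list_b, universe) -> OverlapResult:
    """Jaccard similarity and Fisher's exact test of two gene lists."""
    a, b, u = set(list_a), set(list_b), set(universe)
    offenders = sorted((a | b) - u)
    if offenders:
        raise ValueError(f"genes outside the universe: {offenders[:10]}")
    common = a & b
    union = a | b
    jaccard = len(common) / len(union) if union else 0.0
    table = [[len(common), len(a - b)],
             [len(b - a), len(u - union)]]
    return OverlapResult(n_a=len(a), n_b=len(b), n_common=len(common),
                         universe_size=len(u), jaccard=jaccard,
                         fisher=fisher_2x2(table))


def score_correlation(dvar: pd.Series, external_score: pd.Series,
                      use_absolute: bool = False) -> TestResult:
    """Spearman correlation between dvar and an external per-gene score."""
    shared = dvar.index.intersection(external_score.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared genes, got {len(shared)}")
    x = dvar.reindex(shared).to_numpy(dtype=float)
    if use_absolute:
        x = np.abs(x)
    return spearman(x, external_score.reindex(shared).to_numpy(dtype=float))


def celltype_specific_genes(celltype_expr: ExpressionMatrix,
                            celltype_labels: pd.Series,
                            threshold: float = 2.0) -> dict[str, list[str]]:
    """Genes specific to one cell type in a labelled reference matrix.

    Expression is z-standardized per gene across samples; a cell type's
    effect size for a gene is the mean standardized expression over its
    samples. Genes with effect size > threshold are assigned to that cell
    type; with the default threshold the lists are expected to be disjoint
    (checked, warned otherwise). Constant genes are skipped.
    """
    labels = celltype_labels.reindex(celltype_expr.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a cell-type label")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    x = celltype_expr.values
    sd = x.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        log.info("celltype_specific_genes: skipped %d constant genes",
                 int(constant.sum()))
    z = np.zeros_like(x)
    ok = ~constant
    z[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    gene_ids = np.array(celltype_expr.gene_ids)
    out: dict[str, list[str]] = {}
    assigned = np.zeros(len(gene_ids), dtype=int)
    for t in types:
        mask = (labels == t).to_numpy()
        effect = z[:, mask].mean(axis=1)
        hits = ok & (effect > threshold)
        assigned += hits.astype(int)
        out[str(t)] = list(gene_ids[hits])
    if np.any(assigned > 1):
        log.warning("celltype_specific_genes: %d genes assigned to more "
                    "than one cell type at threshold %g",
                    int(np.sum(assigned > 1)), threshold)
    return out
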