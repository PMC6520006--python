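"""Preprocessing: age filtering, probe summarization, quantile normalization
and supervised covariate correction.

Two correction recipes are supported downstream: quantile normalization
alone, and quantile normalization followed by regressing out known
covariates (batch, sex, race, PMI, RIN, pH). Unsupervised corrections such
as ComBat or surrogate-variable analysis are not reimplemented; a matrix
corrected by any external tool enters the pipeline through the ordinary
expression reader.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)


def filter_age(expr: ExpressionMatrix, meta: SampleMetadata,
               min_age: float = 20.0, max_age: float = 80.0
               ) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Keep samples with min_age <= age <= max_age (both bounds inclusive)."""
    if expr.sample_ids != meta.sample_ids:
        raise ValueError("filter_age requires aligned inputs")
    keep = [s for s, a in zip(meta.sample_ids, meta.age)
            if min_age <= a <= max_age]
    if not keep:
        raise ValueError(
            f"no samples left after age filter [{min_age}, {max_age}]")
    dropped = len(meta.sample_ids) - len(keep)
    if dropped:
        log.info("filter_age: dropped %d samples outside [%g, %g]",
                 dropped, min_age, max_age)
    return expr.subset_samples(keep), meta.subset(keep)


def summarize_probes(probe_expr: ExpressionMatrix,
                     pmap: dict[str, set[str]]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to more than one gene are discarded; a gene's expression
    is the arithmetic mean of its remaining probes, per sample.
    """
    missing = [p for p in probe_expr.gene_ids if p not in pmap]
    if missing:
        raise ValueError(f"probes absent from the probe map: {missing[:10]}")
    multi = [p for p in probe_expr.gene_ids if len(pmap[p]) > 1]
    if multi:
        log.info("summarize_probes: removed %d multi-gene probes", len(multi))
    keep = [p for p in probe_expr.gene_ids if len(pmap[p]) == 1]
    if not keep:
        raise ValueError("no probes survive multi-gene filtering")
    gene_of = {p: next(iter(pmap[p])) for p in keep}
    df = probe_expr.data.loc[keep]
    out = df.groupby([gene_of[p] for p in keep], sort=True).mean()
    out.index.name = "gene_id"
    return ExpressionMatrix(out)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the common reference distribution.

    The reference is the across-sample mean of column-sorted values; each
    value is replaced by the reference value at its within-column rank, and
    ties within a column receive the mean of the reference values their
    tied ranks span (the `normalize.quantiles` convention).
    """
    x = expr.values
    n_genes, n_samples = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = np.empty(n_genes)
        col[order[:, j]] = reference
        # average the assigned reference values over runs of tied input values
        vals = x[order[:, j], j]
        is_new = np.empty(n_genes, dtype=bool)
        is_new[0] = True
        is_new[1:] = vals[1:] != vals[:-1]
        group = np.cumsum(is_new) - 1
        sums = np.bincount(group, weights=reference)
        counts = np.bincount(group)
        col[order[:, j]] = (sums / counts)[group]
        out[:, j] = col
    return expr.with_values(out)


def build_design(meta: SampleMetadata, covariates: list[str],
                 age_exponent: float | None = None) -> pd.DataFrame:
    """Intercept + optional transformed age + dummy-coded covariates.

    Categorical covariates (non-numeric columns) are dummy-coded against the
    first level in sorted label order; numeric covariates enter as-is. The
    design is checked for full column rank and single-level categoricals.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(meta.sample_ids))}
    if age_exponent is not None:
        cols["age_t"] = meta.age ** age_exponent
    for cov in covariates:
        if cov not in meta.data.columns:
            raise ValueError(f"covariate {cov!r} not present in metadata")
        col = meta.data[cov]
        if col.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"covariate {cov!r} has a single level")
            for lv in levels[1:]:
                cols[f"{cov}[{lv}]"] = (col.astype(str) == lv).to_numpy(float)
    design = pd.DataFrame(cols, index=meta.data.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]} "
            f"columns): {list(design.columns)}")
    return design


def correct_covariates(expr: ExpressionMatrix, meta: SampleMetadata,
                       covariates: list[str],
                       keep_intercept: bool = True) -> ExpressionMatrix:
    """Remove covariate effects gene-wise by least squares (age NOT included).

    Output is the residual matrix; with ``keep_intercept`` the fitted
    per-gene intercept is added back so values stay on the log2 scale
    (variability statistics are shift-invariant, so this cannot change any
    downstream result).
    """
    if expr.sample_ids != meta.sample_ids:
        raise ValueError("correct_covariates requires aligned inputs")
    design = build_design(meta, covariates, age_exponent=None)
    x = design.to_numpy()
    y = expr.values  # genes x samples
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y - (x @ beta).T
    if keep_intercept:
        resid = resid + beta[0][:, None]
    return expr.with_values(resid)
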