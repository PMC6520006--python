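"""Differential expression on transformed age.

Each gene is fit by ordinary least squares,

    Y_i = beta_i0 + beta_i1 * age^0.25 + covariates + eps_i,

with age raised to a configurable exponent (0.25 by default: the transform
compresses the fast expression dynamics of young adulthood relative to the
slow changes of old age and balances the uneven age density). The age
coefficient beta1 measures differential expression; its two-sided t-test
p-value (residual degrees of freedom, no moderation) is BH-adjusted across
genes. Residuals are retained for the continuous differential-variability
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import build_design
from .stats import bh_fdr
from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEResult:
    """Per-gene fit: intercept, age slope, p/q, direction and residuals."""

    gene_id: str
    beta0: float
    beta1: float
    p_value: float
    q_value: float
    direction: str  # up | down | null
    residuals: np.ndarray
    degenerate: bool = False


def fit_gene_model(expr: ExpressionMatrix, meta: SampleMetadata,
                   covariates: list[str] = (),
                   exponent: float = 0.25,
                   fdr_threshold: float = 0.05) -> list[DEResult]:
    """Gene-wise OLS on intercept + age^exponent + covariates.

    The fit is vectorized across genes (shared design matrix); p-values come
    from the classical t distribution on n - p residual degrees of freedom.
    Zero-variance genes get beta1 = 0, p = 1 and a degenerate flag.
    """
    if expr.sample_ids != meta.sample_ids:
        raise ValueError("fit_gene_model requires aligned inputs")
    design = build_design(meta, list(covariates), age_exponent=exponent)
    x = design.to_numpy()
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"too few samples ({n}) for {p} design columns")
    y = expr.values
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y.T               # p x genes
    resid = y - (x @ beta).T                 # genes x samples
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / (n - p)
    se_beta1 = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))

    degenerate = expr.data.std(axis=1, ddof=0).to_numpy() == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se_beta1 > 0, beta[1] / se_beta1, 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df=n - p)
    pvals = np.where(degenerate | (se_beta1 == 0), 1.0, pvals)
    b1 = np.where(degenerate, 0.0, beta[1])
    if degenerate.any():
        log.warning("fit_gene_model: %d zero-variance genes set degenerate",
                    int(degenerate.sum()))
    qvals = bh_fdr(pvals)
    direction = np.where(qvals <= fdr_threshold,
                         np.where(b1 > 0, "up", np.where(b1 < 0, "down", "null")),
                         "null")
    return [
        DEResult(gene_id=g, beta0=float(beta[0, i]), beta1=float(b1[i]),
                 p_value=float(pvals[i]), q_value=float(qvals[i]),
                 direction=str(direction[i]), residuals=resid[i],
                 degenerate=bool(degenerate[i]))
        for i, g in enumerate(expr.gene_ids)
    ]


def de_classify(results: list[DEResult], fdr_threshold: float = 0.05) -> dict:
    """Summarize DE calls at q <= threshold (inclusive)."""
    up = [r.gene_id for r in results
          if r.q_value <= fdr_threshold and r.beta1 > 0]
    down = [r.gene_id for r in results
            if r.q_value <= fdr_threshold and r.beta1 < 0]
    called = set(up) | set(down)
    null = [r.gene_id for r in results if r.gene_id not in called]
    return {
        "n_up": len(up), "n_down": len(down), "n_null": len(null),
        "up": up, "down": down, "null": null,
    }


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """Fixed-column result table (gene_id, beta0, beta1, p, q, direction)."""
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in results],
        "beta0": [r.beta0 for r in results],
        "beta1": [r.beta1 for r in results],
        "p_value": [r.p_value for r in results],
        "q_value": [r.q_value for r in results],
        "direction": [r.direction for r in results],
    })
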