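"""Differential variability with age: the continuous and grouped statistics.

Two complementary measures of age-related change in expression variability:

* **Continuous, dvar(rho).** Fit the differential-expression model
  (age^0.25 + covariates), take the absolute residuals |eps_i| as the
  per-sample variability signal, and compute the Spearman correlation of
  |eps_i| with age. Positive values mean variability rises with age. Suited
  to monotonic trends across the whole adult range.

* **Grouped, dvar(IQR).** On a covariate-corrected matrix (age NOT removed),
  compare the old group's interquartile range with a resampled null built
  from the young group: draw B without-replacement subsamples of the young
  samples, each of the old group's size, and record their IQRs. Then

      dvar(IQR) = (IQR_old - mean(null IQRs)) / mean(null IQRs)

  with an empirical two-sided p-value (doubled one-sided tail with add-one
  correction, never exactly 0). Robust to non-normality and to non-linear
  expression dynamics, but blind to the middle-age range by construction.

When the number of distinct young subsamples is small, the null can be
enumerated exhaustively instead of resampled, which makes the empirical
p-value exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import fit_gene_model
from .stats import bh_fdr, skewness, spearman
from .types import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)

_ZERO_RESID_TOL = 1e-10


@dataclass(frozen=True)
class DVContinuousResult:
    """Spearman correlation of |model residuals| with age, per gene."""

    gene_id: str
    dvar_rho: float
    p_value: float
    q_value: float
    degenerate: bool = False

    @property
    def dvar(self) -> float:
        return self.dvar_rho


@dataclass(frozen=True)
class DVGroupedResult:
    """Old-group IQR against the resampled young-IQR null, per gene."""

    gene_id: str
    iqr_old: float
    iqr_young_mean: float
    dvar_iqr: float
    p_empirical: float
    q_value: float  # NaN for degenerate genes (excluded from FDR)
    n_resamples: int
    null_iqr_quantiles: tuple[float, float, float, float, float]  # 5/25/50/75/95%
    exhaustive: bool = False
    degenerate: bool = False

    @property
    def dvar(self) -> float:
        return self.dvar_iqr


def dvar_continuous(expr: ExpressionMatrix, meta: SampleMetadata,
                    covariates: list[str] = (),
                    exponent: float = 0.25) -> list[DVContinuousResult]:
    """Continuous differential variability for every gene.

    Genes whose model fit is exact (all residuals ~0) are degenerate:
    dvar_rho = 0, p = 1; they still enter the BH correction since p = 1
    cannot create false calls.
    """
    fits = fit_gene_model(expr, meta, covariates, exponent=exponent)
    age = meta.age
    rhos, pvals, degen = [], [], []
    for fit in fits:
        abs_resid = np.abs(fit.residuals)
        if np.max(abs_resid) < _ZERO_RESID_TOL:
            rhos.append(0.0)
            pvals.append(1.0)
            degen.append(True)
            continue
        res = spearman(abs_resid, age)
        rhos.append(res.estimate)
        pvals.append(res.p_value)
        degen.append(res.degenerate)
    qvals = bh_fdr(pvals)
    return [
        DVContinuousResult(gene_id=f.gene_id, dvar_rho=rhos[i],
                           p_value=pvals[i], q_value=float(qvals[i]),
                           degenerate=degen[i])
        for i, f in enumerate(fits)
    ]


def _subsample_indices(n_young: int, subsample_size: int, B: int,
                       rng: np.random.Generator) -> np.ndarray:
    """B without-replacement index subsets, one per row."""
    return np.argsort(rng.random((B, n_young)), axis=1)[:, :subsample_size]


def null_iqr_distribution(young_values, subsample_size: int, B: int = 10_000,
                          seed: int = 0, exhaustive_limit: int = 50_000
                          ) -> tuple[np.ndarray, bool]:
    """Null distribution of young-group IQRs at the old group's size.

    Returns (iqr_vector, exhaustive). When C(n_young, subsample_size) is at
    most ``exhaustive_limit``, all subsets are enumerated and the null is
    exact; otherwise B subsets are drawn without replacement (within each
    subset) from the given seed.
    """
    yv = np.asarray(young_values, dtype=float)
    n = yv.size
    if subsample_size < 2:
        raise ValueError("subsample_size must be >= 2")
    if subsample_size > n:
        raise ValueError(
            f"subsample_size {subsample_size} exceeds group size {n}")
    n_subsets = math.comb(n, subsample_size)
    if n_subsets <= exhaustive_limit:
        subs = np.array(list(combinations(range(n), subsample_size)))
        vals = yv[subs]
        q25, q75 = np.quantile(vals, [0.25, 0.75], axis=1, method="linear")
        return q75 - q25, True
    rng = np.random.default_rng(seed)
    idx = _subsample_indices(n, subsample_size, B, rng)
    vals = yv[idx]
    q25, q75 = np.quantile(vals, [0.25, 0.75], axis=1, method="linear")
    return q75 - q25, False


def _empirical_p(null: np.ndarray, observed: float) -> float:
    """Two-sided doubled-tail empirical p with add-one correction."""
    b = null.size
    hi = (1 + int(np.sum(null >= observed))) / (b + 1)
    lo = (1 + int(np.sum(null <= observed))) / (b + 1)
    return min(1.0, 2.0 * min(hi, lo))


def dvar_grouped(expr: ExpressionMatrix, meta: SampleMetadata,
                 young_range: tuple[float, float] = (20.0, 40.0),
                 old_range: tuple[float, float] = (60.0, 80.0),
                 B: int = 10_000, seed: int = 0,
                 exhaustive_limit: int = 50_000,
                 chunk_size: int = 256) -> list[DVGroupedResult]:
    """Grouped differential variability for every gene.

    Expression should already be covariate-corrected (without removing age).
    Group membership uses closed age intervals; samples between the groups
    are ignored. One B x n_old subsample-index matrix, derived from ``seed``,
    is shared by all genes — this keeps runtime linear in genes and makes
    per-gene location/scale invariance exact. Genes whose mean null IQR is 0
    (young expression essentially constant) are degenerate: dvar is
    undefined and they are excluded from the BH correction.
    """
    if expr.sample_ids != meta.sample_ids:
        raise ValueError("dvar_grouped requires aligned inputs")
    age = meta.age
    young = np.flatnonzero((age >= young_range[0]) & (age <= young_range[1]))
    old = np.flatnonzero((age >= old_range[0]) & (age <= old_range[1]))
    n_young, n_old = young.size, old.size
    if n_young < 4 or n_old < 4:
        raise ValueError(
            f"need >= 4 samples per group, got young={n_young}, old={n_old}")
    if n_old > n_young:
        raise ValueError("old group larger than young group; cannot subsample")

    x = expr.values
    y_young, y_old = x[:, young], x[:, old]
    q25o, q75o = np.quantile(y_old, [0.25, 0.75], axis=1, method="linear")
    iqr_old = q75o - q25o

    n_subsets = math.comb(n_young, n_old)
    exhaustive = n_subsets <= exhaustive_limit
    if exhaustive:
        idx = np.array(list(combinations(range(n_young), n_old)))
    else:
        rng = np.random.default_rng(seed)
        idx = _subsample_indices(n_young, n_old, B, rng)
    b_used = idx.shape[0]
    if exhaustive:
        log.info("dvar_grouped: exhaustive null with %d subsets", b_used)

    n_genes = x.shape[0]
    results: list[DVGroupedResult] = []
    pvals, degenerate = np.empty(n_genes), np.zeros(n_genes, dtype=bool)
    dvar = np.empty(n_genes)
    null_mean = np.empty(n_genes)
    null_q = np.empty((n_genes, 5))
    for start in range(0, n_genes, chunk_size):
        stop = min(start + chunk_size, n_genes)
        sub = y_young[start:stop][:, idx]          # chunk x B x n_old
        q25, q75 = np.quantile(sub, [0.25, 0.75], axis=2, method="linear")
        null_iqr = q75 - q25                       # chunk x B
        null_mean[start:stop] = null_iqr.mean(axis=1)
        null_q[start:stop] = np.quantile(
            null_iqr, [0.05, 0.25, 0.5, 0.75, 0.95], axis=1,
            method="linear").T
        obs = iqr_old[start:stop][:, None]
        hi = (1 + (null_iqr >= obs).sum(axis=1)) / (b_used + 1)
        lo = (1 + (null_iqr <= obs).sum(axis=1)) / (b_used + 1)
        pvals[start:stop] = np.minimum(1.0, 2.0 * np.minimum(hi, lo))

    degenerate = null_mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dvar = np.where(degenerate, np.nan,
                        (iqr_old - null_mean) / np.where(degenerate, 1.0,
                                                         null_mean))
    if degenerate.any():
        log.warning("dvar_grouped: %d genes with zero young IQR excluded "
                    "from FDR", int(degenerate.sum()))
    qvals = np.full(n_genes, np.nan)
    ok = ~degenerate
    if ok.any():
        qvals[ok] = bh_fdr(pvals[ok])
    for i, g in enumerate(expr.gene_ids):
        results.append(DVGroupedResult(
            gene_id=g, iqr_old=float(iqr_old[i]),
            iqr_young_mean=float(null_mean[i]),
            dvar_iqr=float(dvar[i]),
            p_empirical=float(pvals[i]) if not degenerate[i] else 1.0,
            q_value=float(qvals[i]), n_resamples=b_used,
            null_iqr_quantiles=tuple(float(v) for v in null_q[i]),
            exhaustive=exhaustive, degenerate=bool(degenerate[i])))
    return results


def dv_classify(results, fdr_threshold: float = 0.05) -> dict:
    """Per-gene DV labels plus transcriptome-wide distribution summary.

    Works on either result flavour (both expose ``.dvar`` and ``.q_value``).
    The summary reports the fraction of genes with dvar > 0, the median and
    skewness of the dvar distribution, and a Wilcoxon signed-rank test of
    median != 0.
    """
    scored = [r for r in results if not getattr(r, "degenerate", False)]
    increase = [r.gene_id for r in scored
                if r.q_value <= fdr_threshold and r.dvar > 0]
    decrease = [r.gene_id for r in scored
                if r.q_value <= fdr_threshold and r.dvar < 0]
    dvars = np.array([r.dvar for r in scored])
    all_zero = dvars.size > 0 and np.all(dvars == 0)
    if all_zero or dvars.size < 3:
        skew = float("nan")
        wilcoxon_p = 1.0
    else:
        skew = skewness(dvars) if np.ptp(dvars) > 0 else float("nan")
        nonzero = dvars[dvars != 0]
        wilcoxon_p = (float(sps.wilcoxon(nonzero)[1])
                      if nonzero.size >= 5 else 1.0)
    return {
        "increase": increase, "decrease": decrease,
        "n_increase": len(increase), "n_decrease": len(decrease),
        "n_scored": len(scored),
        "fraction_positive": float(np.mean(dvars > 0)) if dvars.size else 0.0,
        "median_dvar": float(np.median(dvars)) if dvars.size else float("nan"),
        "skewness_dvar": skew,
        "wilcoxon_p": wilcoxon_p,
        "all_zero": bool(all_zero),
    }


def dv_continuous_table(results: list[DVContinuousResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in results],
        "dvar_rho": [r.dvar_rho for r in results],
        "p_value": [r.p_value for r in results],
        "q_value": [r.q_value for r in results],
        "degenerate": [r.degenerate for r in results],
    })


def dv_grouped_table(results: list[DVGroupedResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in results],
        "iqr_old": [r.iqr_old for r in results],
        "iqr_young_mean": [r.iqr_young_mean for r in results],
        "dvar_iqr": [r.dvar_iqr for r in results],
        "p_empirical": [r.p_empirical for r in results],
        "q_value": [r.q_value for r in results],
        "n_resamples": [r.n_resamples for r in results],
        "degenerate": [r.degenerate for r in results],
    })
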