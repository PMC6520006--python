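"""Synthetic bulk-expression data with planted mean and variance trends.

The generator emulates the structure of an adult post-mortem brain cohort:
147 samples aged 20-80 with uneven age density (many young and middle-aged
donors, few old ones, in proportions 53:72:22 over the bins [20,40], (40,60)
and [60,80]), per-gene linear expression trends in age^0.25, technical batch
structure (19 batches by default), demographic/quality covariates (sex, race,
PMI, RIN, pH), and - the signal of interest - an age-dependent residual
scale.

Per gene i and sample j,

    Y_ij = beta0_i + beta1_i * age_j^0.25 + batch_ij + cov_ij + eps_ij,
    eps_ij ~ Normal(0, sigma_ij^2),

where the residual scale follows one of two variance-trend shapes:

    linear:  sigma_ij = sigma0_i * (1 + gamma_i * (age_j - 20) / 60)
    step:    sigma_ij = sigma0_i               for age_j < 50
             sigma_ij = sigma0_i * (1+gamma_i) for age_j >= 50

gamma_i > -1 keeps every scale positive. Variability-decreasing genes draw a
magnitude g and use gamma = -g / (1 + g), so an increase by factor (1+g) and
its matching decrease are reciprocal and the positivity constraint holds for
any g > 0.

Randomness contract: one root seed; sample-level draws and each gene's draws
come from separate `numpy.random.SeedSequence` spawns, so per-gene results do
not depend on gene evaluation order or on how many genes are simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSetCollection, SampleMetadata

log = logging.getLogger(__name__)

AGE_BINS = ((20.0, 40.0), (40.0, 60.0), (60.0, 80.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model (defaults mirror the study cohort).

    ``age_bin_weights`` are proportional counts for the young / middle / old
    bins; with ``age_quota`` the per-bin counts are exact (largest-remainder
    apportionment), otherwise multinomial. ``frac_de`` / ``frac_dv`` are the
    planted fractions of differentially expressed / variable genes;
    ``frac_dv_increase`` splits DV genes into variability increases vs
    decreases. ``trend_shape`` is "linear", "step", or "mixed" (each DV gene
    assigned one of the two at random).
    """

    n_genes: int = 1000
    n_samples: int = 147
    age_bin_weights: tuple[float, float, float] = (53.0, 72.0, 22.0)
    age_quota: bool = True
    beta0_mean: float = 8.0
    beta0_sd: float = 2.0
    frac_de: float = 0.2
    beta1_sd: float = 1.0
    sigma0_log2_mean: float = -1.0  # median residual SD 0.5 on log2 scale
    sigma0_log2_sd: float = 0.25
    frac_dv: float = 0.2
    frac_dv_increase: float = 0.5
    gamma_low: float = 0.5
    gamma_high: float = 2.0
    trend_shape: str = "linear"
    n_batches: int = 19
    batch_scale: float = 0.3
    covariate_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_dv", "frac_dv_increase"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if sum(self.age_bin_weights) <= 0 or min(self.age_bin_weights) < 0:
            raise ValueError("age_bin_weights must be non-negative, sum > 0")
        if self.trend_shape not in ("linear", "step", "mixed"):
            raise ValueError(f"unknown trend_shape {self.trend_shape!r}")
        if self.gamma_low <= 0 or self.gamma_high < self.gamma_low:
            raise ValueError("need 0 < gamma_low <= gamma_high")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene parameters and the labels they imply."""

    table: pd.DataFrame  # index gene_id; beta1_true, gamma_true, trend_shape,
    #                      de_label in {up,down,null}, dv_label in {increase,decrease,null}

    def __post_init__(self) -> None:
        t = self.table
        b, g = t["beta1_true"].to_numpy(), t["gamma_true"].to_numpy()
        de = np.where(b > 0, "up", np.where(b < 0, "down", "null"))
        dv = np.where(g > 0, "increase", np.where(g < 0, "decrease", "null"))
        if not ((t["de_label"] == de).all() and (t["dv_label"] == dv).all()):
            raise ValueError("truth labels inconsistent with parameter signs")

    @property
    def beta1_true(self) -> np.ndarray:
        return self.table["beta1_true"].to_numpy(dtype=float)

    @property
    def gamma_true(self) -> np.ndarray:
        return self.table["gamma_true"].to_numpy(dtype=float)

    @property
    def dv_label(self) -> np.ndarray:
        return self.table["dv_label"].to_numpy()

    @property
    def de_label(self) -> np.ndarray:
        return self.table["de_label"].to_numpy()


def _quota_counts(n: int, weights) -> np.ndarray:
    """Largest-remainder apportionment of n samples over the age bins."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts)):
        if counts.sum() == n:
            break
        counts[i] += 1
    return counts


def _sample_ages(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.age_quota:
        counts = _quota_counts(cfg.n_samples, cfg.age_bin_weights)
    else:
        w = np.asarray(cfg.age_bin_weights, dtype=float)
        counts = rng.multinomial(cfg.n_samples, w / w.sum())
    ages = np.concatenate([
        rng.uniform(lo, hi, size=c) for (lo, hi), c in zip(AGE_BINS, counts)
    ])
    return ages[rng.permutation(cfg.n_samples)]


def residual_scale(sigma0: float, gamma: float, shape: str,
                   ages: np.ndarray) -> np.ndarray:
    """Per-sample residual SD under the linear or step variance trend."""
    if shape == "linear":
        scale = sigma0 * (1.0 + gamma * (ages - 20.0) / 60.0)
    elif shape == "step":
        scale = np.where(ages < 50.0, sigma0, sigma0 * (1.0 + gamma))
    else:
        raise ValueError(f"unknown trend shape {shape!r}")
    if np.any(scale <= 0):
        raise ValueError("residual scale must stay positive (gamma <= -1?)")
    return scale


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Draw a full synthetic dataset: expression, metadata and ground truth."""
    root = np.random.SeedSequence(cfg.seed)
    sample_ss, genes_ss = root.spawn(2)
    rng = np.random.default_rng(sample_ss)

    ages = _sample_ages(cfg, rng)
    sample_ids = [f"s{j + 1}" for j in range(cfg.n_samples)]
    sex = rng.choice(["F", "M"], size=cfg.n_samples)
    race = rng.choice(["AA", "AS", "CAUC", "HISP"], size=cfg.n_samples)
    batch = rng.integers(0, cfg.n_batches, size=cfg.n_samples)
    pmi = rng.uniform(5.0, 40.0, size=cfg.n_samples)
    rin = rng.uniform(6.0, 9.5, size=cfg.n_samples)
    ph = rng.normal(6.5, 0.25, size=cfg.n_samples)

    meta = SampleMetadata(pd.DataFrame({
        "age": ages, "sex": sex, "race": race,
        "batch": [f"b{b + 1}" for b in batch],
        "pmi": pmi, "rin": rin, "ph": ph,
    }, index=pd.Index(sample_ids, name="sample_id")))

    # continuous covariates enter standardized so covariate_scale is in
    # log2 units regardless of their natural ranges
    def _z(v):
        return (v - v.mean()) / v.std()

    cont_cov = np.column_stack([_z(pmi), _z(rin), _z(ph)])
    sex_ind = (sex == "M").astype(float)
    race_levels = ["AS", "CAUC", "HISP"]  # AA is the reference level
    race_ind = np.column_stack([(race == lv).astype(float) for lv in race_levels])

    n_de = int(round(cfg.frac_de * cfg.n_genes))
    n_dv = int(round(cfg.frac_dv * cfg.n_genes))
    n_dv_up = int(round(cfg.frac_dv_increase * n_dv))
    de_flags = np.zeros(cfg.n_genes, dtype=bool)
    de_flags[:n_de] = True
    dv_sign = np.zeros(cfg.n_genes)
    dv_sign[:n_dv_up] = 1.0
    dv_sign[n_dv_up:n_dv] = -1.0
    rng.shuffle(de_flags)
    rng.shuffle(dv_sign)

    beta0 = rng.normal(cfg.beta0_mean, cfg.beta0_sd, size=cfg.n_genes)
    beta1 = np.where(de_flags, rng.normal(0.0, cfg.beta1_sd, size=cfg.n_genes), 0.0)
    sigma0 = 2.0 ** rng.normal(cfg.sigma0_log2_mean, cfg.sigma0_log2_sd,
                               size=cfg.n_genes)
    g_mag = rng.uniform(cfg.gamma_low, cfg.gamma_high, size=cfg.n_genes)
    gamma = np.where(dv_sign > 0, g_mag,
                     np.where(dv_sign < 0, -g_mag / (1.0 + g_mag), 0.0))
    if cfg.trend_shape == "mixed":
        shapes = np.where(rng.random(cfg.n_genes) < 0.5, "linear", "step")
    else:
        shapes = np.full(cfg.n_genes, cfg.trend_shape)

    batch_effects = rng.normal(0.0, cfg.batch_scale,
                               size=(cfg.n_genes, cfg.n_batches))
    cov_coef = rng.normal(0.0, cfg.covariate_scale, size=(cfg.n_genes, 7))

    age_t = ages ** 0.25
    design_cov = np.column_stack([sex_ind, race_ind, cont_cov])  # 7 columns
    mean_part = (beta0[:, None] + beta1[:, None] * age_t[None, :]
                 + batch_effects[:, batch] + cov_coef @ design_cov.T)

    gene_ss = genes_ss.spawn(cfg.n_genes)
    noise = np.empty((cfg.n_genes, cfg.n_samples))
    for i in range(cfg.n_genes):
        scale = residual_scale(sigma0[i], gamma[i], shapes[i], ages)
        noise[i] = np.random.default_rng(gene_ss[i]).normal(0.0, scale)

    gene_ids = [f"g{i + 1}" for i in range(cfg.n_genes)]
    expr = ExpressionMatrix(pd.DataFrame(
        mean_part + noise, index=pd.Index(gene_ids, name="gene_id"),
        columns=sample_ids))

    truth = SyntheticTruth(pd.DataFrame({
        "beta1_true": beta1,
        "gamma_true": gamma,
        "trend_shape": shapes,
        "de_label": np.where(beta1 > 0, "up", np.where(beta1 < 0, "down", "null")),
        "dv_label": np.where(gamma > 0, "increase",
                             np.where(gamma < 0, "decrease", "null")),
    }, index=pd.Index(gene_ids, name="gene_id")))
    log.info("simulated %d genes x %d samples (%d DE, %d DV planted)",
             cfg.n_genes, cfg.n_samples, n_de, n_dv)
    return expr, meta, truth


def simulate_gene_sets(n_sets: int, size_range: tuple[int, int],
                       universe: list[str], overlap_fraction: float = 0.0,
                       seed: int = 0) -> GeneSetCollection:
    """Random gene sets drawn from a universe, without replacement per set.

    ``overlap_fraction`` of each set's members come from a shared "hub" pool
    (10% of the universe) to induce between-set overlap; 0 gives independent
    uniform sets.
    """
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError(
            f"max set size {hi} exceeds universe size {len(universe)}")
    if not 0 < lo <= hi:
        raise ValueError(f"invalid size range {size_range}")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    hub = universe[:max(1, len(universe) // 10)]
    sets: dict[str, list[str]] = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        n_hub = min(int(round(overlap_fraction * size)), len(hub))
        members = list(rng.choice(hub, size=n_hub, replace=False))
        rest_pool = [g for g in universe if g not in set(members)]
        members += list(rng.choice(rest_pool, size=size - n_hub, replace=False))
        sets[f"set{k + 1}"] = members
    return GeneSetCollection(sets, {s: "synthetic" for s in sets})
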