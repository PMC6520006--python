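"""Core data containers for the variability-with-age pipeline.

An :class:`ExpressionMatrix` is a genes x samples table of log2 expression
values; :class:`SampleMetadata` carries per-sample age (years) and technical /
biological covariates (sex, race, batch, post-mortem interval, RNA integrity
number, pH); :class:`GeneSetCollection` is an ordered mapping of pathway id to
member gene list; :class:`AnalysisConfig` collects the tunable analysis
parameters with their defaults.

Both matrix-like containers wrap a :class:`pandas.DataFrame` and enforce
their invariants (unique identifiers, finite values, age present) at
construction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("sex", "race", "batch", "pmi", "rin", "ph")
CATEGORICAL_COVARIATES = ("sex", "race", "batch")


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples real matrix of (log2) expression values."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            bad = np.argwhere(~np.isfinite(self.data.to_numpy(dtype=float)))
            g, s = bad[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[g]!r}, sample {self.data.columns[s]!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(pd.DataFrame(
            values, index=self.data.index, columns=self.data.columns))


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations; ``age`` (years) is mandatory.

    Unknown columns are retained so downstream correction can use any
    covariate present in the input table.
    """

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        if "age" not in self.data.columns:
            raise ValueError("age required: metadata has no 'age' column")
        age = pd.to_numeric(self.data["age"], errors="raise")
        if not np.isfinite(age.to_numpy(dtype=float)).all():
            raise ValueError("non-finite age values in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def age(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])

    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != "age"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Ordered mapping set_id -> unique member gene list."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {sid!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {sid!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters with study defaults.

    age_transform_exponent: exponent applied to age in the expression model
        (0.25 compresses the fast young-adult dynamics).
    young_range / old_range: closed age intervals in years defining the
        grouped comparison; disjoint by construction.
    n_resamples: size B of the resampled young-IQR null distribution.
    fdr_threshold: BH q-value cutoff for calling genes (inclusive).
    """

    age_transform_exponent: float = 0.25
    young_range: tuple[float, float] = (20.0, 40.0)
    old_range: tuple[float, float] = (60.0, 80.0)
    n_resamples: int = 10_000
    fdr_threshold: float = 0.05
    set_size_min: int = 5
    set_size_max: int = 500
    gsea_size_min: int = 10
    gsea_size_max: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.young_range
        o0, o1 = self.old_range
        if not (y0 < y1 and o0 < o1):
            raise ValueError("age ranges must be increasing intervals")
        if max(y0, o0) < min(y1, o1) and not (y1 < o0 or o1 < y0):
            raise ValueError("young and old ranges must not overlap")
        if not (20.0 <= y0 and y1 <= 80.0 and 20.0 <= o0 and o1 <= 80.0):
            raise ValueError("age ranges must lie within [20, 80]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)
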