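"""Shared data containers for the pipeline stages.

Single-cell count data is carried as :class:`anndata.AnnData` (cells x genes,
sparse, with ``obs`` columns ``donor``/``condition``/``timepoint``/``cluster``);
the containers here cover everything else: bulk-style expression matrices with
sample metadata, gene sets, DE summaries, the frozen disease axis, and results
of set-overlap and empirical permutation tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "OverlapResult",
    "EmpiricalTestResult",
    "DiseaseAxis",
    "ProjectionResult",
    "BatchModel",
]


@dataclass
class ExpressionMatrix:
    """Dense gene x sample expression values plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with genes as the index and samples as columns.
    sample_meta
        DataFrame indexed by sample identifier; typical columns are
        ``batch`` (dataset of origin) and ``group`` (e.g. disease/reference).
    mode
        ``"counts"`` for raw counts (eligible for the count filter and the
        log2 variance stabilization) or ``"normalized"`` for values already
        on a variance-stabilized scale.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    mode: str = "normalized"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "normalized"):
            raise ValueError(f"mode must be 'counts' or 'normalized', got {self.mode!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match value columns (same order)")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.sample_meta, self.mode)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    members: frozenset = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def intersect(self, other) -> "GeneSet":
        other_members = other.members if isinstance(other, GeneSet) else frozenset(other)
        return GeneSet(self.name, self.members & other_members, self.description)


@dataclass
class OverlapResult:
    """Hypergeometric overlap statistics for two gene sets.

    ``ln_p`` is the natural-log upper-tail probability P(X >= overlap); the
    linear-scale ``p`` is derived and may underflow to 0.0 for display only.
    """

    size_a: int
    size_b: int
    overlap: int
    background: int
    ln_p: float
    jaccard: float = float("nan")
    p_adj: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.size_a, self.size_b):
            raise ValueError("overlap must satisfy 0 <= k <= min(K, n)")
        if max(self.size_a, self.size_b) > self.background:
            raise ValueError("set sizes cannot exceed the background size")
        if self.ln_p > 1e-12:
            raise ValueError("ln_p must be <= 0")
        if math.isnan(self.jaccard):
            union = self.size_a + self.size_b - self.overlap
            self.jaccard = self.overlap / union if union else 0.0

    @property
    def p(self) -> float:
        return math.exp(self.ln_p)


@dataclass
class EmpiricalTestResult:
    """Result of a randomization test with empirical p = (r + 1)/(n_rand + 1).

    ``r`` counts randomizations at least as extreme as the observed statistic;
    when ``r == 0`` the conventional upper bound ``p < 1/n_rand`` is also
    reported (``p_upper_bound``), matching how such tests are quoted.
    """

    observed: float
    null_values: np.ndarray
    n_rand: int

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values)
        if self.null_values.shape != (self.n_rand,):
            raise ValueError("null_values must have length n_rand")

    @property
    def r(self) -> int:
        return int(np.sum(self.null_values >= self.observed))

    @property
    def p_est(self) -> float:
        return (self.r + 1) / (self.n_rand + 1)

    @property
    def p_upper_bound(self) -> float | None:
        return 1.0 / self.n_rand if self.r == 0 else None

    @property
    def bound_str(self) -> str:
        """The value as it would be quoted: a bound when no null draw reaches it."""
        if self.r == 0:
            b = 1.0 / self.n_rand
            return f"<{b:.10g}" if b < 1e-4 else f"<{b:.4f}".rstrip("0")
        return f"{self.p_est:.6g}"


@dataclass
class DiseaseAxis:
    """Frozen first principal component of the batch-corrected meta-analysis.

    ``loadings`` is the unit-norm PC1 gene-loading vector oriented so that
    disease-model samples score positive; ``training_means`` are the per-gene
    means of the corrected training matrix (the PCA centering vector).
    """

    genes: pd.Index
    loadings: np.ndarray
    training_means: np.ndarray
    variance_explained: np.ndarray
    orientation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.training_means = np.asarray(self.training_means, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        if self.loadings.shape != (len(self.genes),):
            raise ValueError("one loading per gene required")
        norm = np.linalg.norm(self.loadings)
        if not math.isclose(norm, 1.0, rel_tol=1e-8):
            raise ValueError(f"loadings must be unit norm, got ||w|| = {norm}")
        if np.any(np.diff(self.variance_explained) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def ranked_genes(self, end: str = "lowest") -> pd.Index:
        """Genes ordered by loading; ``end='lowest'`` puts the most negative first."""
        order = np.argsort(self.loadings, kind="stable")
        if end == "highest":
            order = order[::-1]
        elif end != "lowest":
            raise ValueError("end must be 'lowest' or 'highest'")
        return self.genes[order]


@dataclass
class ProjectionResult:
    """Scores of external samples projected onto a frozen disease axis."""

    samples: pd.Index
    scores: np.ndarray
    n_shared_genes: int

    def __post_init__(self) -> None:
        self.samples = pd.Index(self.samples)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.samples),):
            raise ValueError("one score per sample required")

    @property
    def ranks(self) -> np.ndarray:
        """Ascending ranks of the scores (1 = lowest); average ranks on ties."""
        from scipy.stats import rankdata

        return rankdata(self.scores, method="average")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "rank": self.ranks}, index=self.samples
        )


@dataclass
class BatchModel:
    """Fitted parameters of the empirical-Bayes location-scale batch correction.

    Attributes follow the standard parametric formulation: after gene-wise
    standardization (``grand_mean``, ``pooled_sd``), each batch gets per-gene
    location (``gamma_hat``) and scale (``delta_sq_hat``) estimates that are
    shrunk toward batch-level priors — normal on location (``gamma_bar``,
    ``tau_sq``), inverse-gamma on scale (``a_prior``, ``b_prior``) — yielding
    ``gamma_star`` and ``delta_sq_star``.
    """

    genes: pd.Index
    batches: list
    grand_mean: np.ndarray
    pooled_sd: np.ndarray
    gamma_hat: np.ndarray      # (n_batches, n_genes)
    delta_sq_hat: np.ndarray
    gamma_bar: np.ndarray      # (n_batches,)
    tau_sq: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    gamma_star: np.ndarray
    delta_sq_star: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.pooled_sd <= 0):
            raise ValueError("pooled sd must be strictly positive for retained genes")
        if np.any(self.delta_sq_star <= 0):
            raise ValueError("shrunken scale estimates must be strictly positive")
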