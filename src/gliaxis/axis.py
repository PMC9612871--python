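"""Cross-dataset disease axis: batch-corrected PCA, projection, axis tests.

The disease axis is the first principal component of a batch-corrected,
column-merged collection of expression datasets contrasting disease-model
and reference samples, oriented so disease samples score positive.  It acts
as a 1-D coordinate: external profiles (pseudo-bulk averages, new datasets)
are batch-corrected *together with* the training datasets, centered, and
multiplied by the frozen PC1 gene loadings.  Two axis-level tests are
provided: hypergeometric enrichment of an annotated gene set in sliding
windows of extreme loadings, and a rank-randomization test asking whether a
labelled subset of projected samples sits higher along the axis than chance.

:class:`DiseaseAxisModel` packages the fit (correction + PCA) and the
projection behind a scikit-learn-style estimator; :func:`build_axis` and
:func:`project` are the functional faces of the same machinery.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.exceptions import NotFittedError

from .batch import combat_adjust, merge_datasets
from .containers import (
    DiseaseAxis,
    EmpiricalTestResult,
    ExpressionMatrix,
    GeneSet,
    ProjectionResult,
)
from .overlap import bh_adjust, log_hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "prepare_dataset",
    "map_orthologues",
    "build_axis",
    "project",
    "window_enrichment",
    "rank_randomization_test",
    "DiseaseAxisModel",
]

DEFAULT_WINDOW_SIZES = tuple(range(50, 1001, 50))


def prepare_dataset(m: ExpressionMatrix, min_total_count: int = 20) -> ExpressionMatrix:
    """Count filter and variance stabilization for one dataset.

    Count-mode matrices drop genes whose total across samples is below
    ``min_total_count`` (strictly-less-than boundary: a total equal to the
    threshold is kept) and are transformed by log2(x + 1); matrices already
    normalized pass through unchanged.
    """
    if m.mode != "counts":
        return m
    totals = m.values.sum(axis=1)
    kept = m.values.loc[totals >= min_total_count]
    dropped = m.n_genes - kept.shape[0]
    if dropped:
        logger.info("count filter removed %d/%d genes", dropped, m.n_genes)
    return ExpressionMatrix(np.log2(kept + 1.0), m.sample_meta, mode="normalized")


def map_orthologues(m: ExpressionMatrix, orth_map: pd.DataFrame) -> ExpressionMatrix:
    """Translate gene identifiers through a 1:1 orthologue map.

    ``orth_map`` is a two-column table (source id, target id).  Only rows
    forming a bijection — source appears once AND target appears once — are
    usable; genes of ``m`` without a clean 1:1 partner are dropped (logged).
    """
    if orth_map.shape[1] < 2:
        raise ValueError("orthologue map needs two columns")
    src = orth_map.iloc[:, 0].astype(str)
    dst = orth_map.iloc[:, 1].astype(str)
    one_to_one = (~src.duplicated(keep=False)) & (~dst.duplicated(keep=False))
    mapping = dict(zip(src[one_to_one], dst[one_to_one]))
    keep = [g for g in m.genes if g in mapping]
    if len(keep) < m.n_genes:
        logger.info(
            "orthologue mapping dropped %d/%d genes without a 1:1 partner",
            m.n_genes - len(keep),
            m.n_genes,
        )
    values = m.values.loc[keep].copy()
    values.index = pd.Index([mapping[g] for g in keep])
    return ExpressionMatrix(values, m.sample_meta, m.mode)


def build_axis(
    adjusted: ExpressionMatrix,
    group_key: str = "group",
    disease_label: str = "disease",
    reference_label: str = "reference",
) -> tuple[DiseaseAxis, np.ndarray]:
    """PCA on the corrected merged matrix; PC1 becomes the disease axis.

    The data are per-gene centered (no variance scaling) and the sign of the
    loadings is fixed so the mean PC1 score of disease-group samples exceeds
    the reference group's.  Returns the axis together with the training
    samples' PC1 scores.
    """
    meta = adjusted.sample_meta
    if group_key not in meta.columns:
        raise ValueError(f"sample metadata lacks column {group_key!r}")
    groups = meta[group_key]
    for label in (disease_label, reference_label):
        if not (groups == label).any():
            raise ValueError(f"no samples labelled {label!r}")
    if adjusted.n_samples < 3:
        raise ValueError("need at least 3 samples for a meaningful axis")

    X = adjusted.values.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("matrix is constant across samples; no axis exists")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)[:, 0]
    loadings = pca.components_[0]

    disease_mean = scores[(groups == disease_label).to_numpy()].mean()
    reference_mean = scores[(groups == reference_label).to_numpy()].mean()
    sign = 1.0 if disease_mean >= reference_mean else -1.0
    axis = DiseaseAxis(
        genes=adjusted.genes,
        loadings=sign * loadings,
        training_means=pca.mean_,
        variance_explained=pca.explained_variance_ratio_,
        orientation={
            "positive_group": disease_label,
            "group_key": group_key,
            "flipped": sign < 0,
        },
    )
    return axis, sign * scores


def _project_block(
    axis: DiseaseAxis,
    block: pd.DataFrame,
    center_on: str,
    min_shared_frac: float,
) -> ProjectionResult:
    shared = axis.genes.intersection(block.index)
    if len(shared) < min_shared_frac * axis.n_genes:
        raise ValueError(
            f"only {len(shared)}/{axis.n_genes} axis genes shared; "
            f"below the required fraction {min_shared_frac}"
        )
    sub = block.loc[shared].to_numpy(dtype=float)
    if center_on == "self":
        centered = sub - sub.mean(axis=1, keepdims=True)
    elif center_on == "train":
        pos = axis.genes.get_indexer(shared)
        centered = sub - axis.training_means[pos][:, None]
    else:
        raise ValueError("center_on must be 'self' or 'train'")
    w = axis.loadings[axis.genes.get_indexer(shared)]
    scores = centered.T @ w  # no rescaling of the loading sub-vector
    return ProjectionResult(
        samples=block.columns, scores=scores, n_shared_genes=len(shared)
    )


def project(
    axis: DiseaseAxis,
    new: ExpressionMatrix,
    training: Sequence[ExpressionMatrix],
    *,
    batch_key: str = "batch",
    center_on: str = "self",
    min_shared_frac: float = 0.5,
) -> ProjectionResult:
    """Project an external dataset onto a frozen disease axis.

    The new dataset is batch-corrected along with the training datasets (it
    enters the correction as one extra batch), its corrected block is
    per-gene centered (on its own sample means by default, or on the axis'
    training means with ``center_on='train'``), and the centered values are
    multiplied by the PC1 loadings restricted to the shared genes.
    """
    new = prepare_dataset(new)
    training = [prepare_dataset(t) for t in training]
    varying = new.values.var(axis=1) > 0
    if not varying.any():
        # a constant dataset centers to zero under any per-gene affine
        # correction; no correction run is needed (or possible)
        shared = axis.genes.intersection(new.genes)
        if len(shared) < min_shared_frac * axis.n_genes:
            raise ValueError(
                f"only {len(shared)}/{axis.n_genes} axis genes shared; "
                f"below the required fraction {min_shared_frac}"
            )
        logger.warning("projected dataset is constant across samples; scores are 0")
        return ProjectionResult(
            samples=new.samples,
            scores=np.zeros(new.n_samples),
            n_shared_genes=len(shared),
        )
    meta = new.sample_meta.copy()
    meta[batch_key] = "__projected__"
    tagged = ExpressionMatrix(new.values.loc[varying], meta, new.mode)
    adjusted, _ = combat_adjust(list(training) + [tagged], batch_key=batch_key)
    block = adjusted.values[list(new.samples)]
    return _project_block(axis, block, center_on, min_shared_frac)


def window_enrichment(
    axis: DiseaseAxis,
    annotated,
    background,
    sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    end: str = "lowest",
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene set in extreme-loading windows.

    Genes carrying loadings are intersected with the background, ranked by
    loading (``end='lowest'``: most negative first), and for each window size
    the overlap between the window and the annotated set is tested with the
    log-space hypergeometric upper tail; BH adjustment runs across the
    windows of this call.  Windows larger than the background are skipped
    with a warning.
    """
    bg = set(background.members if isinstance(background, GeneSet) else background)
    bg &= set(axis.genes)
    if not bg:
        raise ValueError("background shares no genes with the axis")
    ann = set(annotated.members if isinstance(annotated, GeneSet) else annotated) & bg
    ranked = [g for g in axis.ranked_genes(end) if g in bg]
    rows = []
    for size in sizes:
        if size > len(ranked):
            logger.warning("window size %d exceeds background (%d); skipped", size, len(ranked))
            continue
        window = set(ranked[:size])
        k = len(window & ann)
        ln_p = log_hypergeom_tail(k, len(ann), size, len(bg))
        rows.append(
            {
                "size": size,
                "overlap": k,
                "n_annotated": len(ann),
                "background": len(bg),
                "ln_p": ln_p,
                "p": float(np.exp(ln_p)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


def rank_randomization_test(
    proj: ProjectionResult,
    query_samples: Sequence[str],
    n_rand: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> EmpiricalTestResult:
    """Do the labelled samples rank higher along the axis than chance?

    The statistic is the mean ascending rank of the query samples along the
    projected axis; the null is the mean rank of ``n_rand`` uniformly drawn
    same-size subsets of all samples.  p_est = (r + 1)/(n_rand + 1) with r
    the number of null draws whose mean rank is at least the observed.
    """
    rng = np.random.default_rng(rng)
    query_samples = list(query_samples)
    if not query_samples:
        raise ValueError("query must be non-empty")
    pos = proj.samples.get_indexer(query_samples)
    if (pos < 0).any():
        missing = [s for s, p in zip(query_samples, pos) if p < 0]
        raise ValueError(f"query samples not in projection: {missing}")
    ranks = proj.ranks
    n = len(ranks)
    q = len(query_samples)
    observed = float(ranks[pos].mean())
    if q == n:
        logger.warning("query covers all samples; test is degenerate (p = 1)")
    # uniform subsets of size q via per-draw random keys
    keys = rng.random((n_rand, n))
    idx = np.argpartition(keys, q - 1, axis=1)[:, :q]
    null = ranks[idx].mean(axis=1)
    return EmpiricalTestResult(observed=observed, null_values=null, n_rand=n_rand)


class DiseaseAxisModel(BaseEstimator):
    """Disease-axis estimator: batch-corrected PCA with frozen projection.

    ``fit`` takes a list of expression datasets (each becomes one batch),
    applies the count filter and log2 stabilization where needed, removes
    batch effects with the parametric empirical-Bayes correction, runs PCA
    on the merged corrected matrix, and freezes the oriented unit-norm PC1
    loadings.  ``transform`` projects a new dataset through the documented
    correct-along-with-training path; a dataset recognized as one of the
    training batches (all its samples already present) reuses the fit-time
    corrected values, so training projections are self-consistent.

    Parameters
    ----------
    min_total_count
        Count-filter threshold applied to count-mode datasets before
        stabilization.
    group_key, disease_label, reference_label
        Sample-metadata column and labels used to orient the axis.
    batch_key
        Sample-metadata column naming the batch.
    center_on
        ``'self'`` (default) centers a projected block on its own per-gene
        means; ``'train'`` uses the training means.
    min_shared_frac
        Minimum fraction of axis genes a projected dataset must share.

    Attributes
    ----------
    axis_ : DiseaseAxis
        Frozen unit-norm PC1 loadings with training means and orientation.
    batch_model_ : BatchModel
        Fitted batch-correction parameters.
    adjusted_ : ExpressionMatrix
        The corrected merged training matrix.
    training_scores_ : pandas.Series
        PC1 scores of the training samples.
    """

    def __init__(
        self,
        min_total_count: int = 20,
        group_key: str = "group",
        disease_label: str = "disease",
        reference_label: str = "reference",
        batch_key: str = "batch",
        center_on: str = "self",
        min_shared_frac: float = 0.5,
    ):
        self.min_total_count = min_total_count
        self.group_key = group_key
        self.disease_label = disease_label
        self.reference_label = reference_label
        self.batch_key = batch_key
        self.center_on = center_on
        self.min_shared_frac = min_shared_frac

    def fit(self, X: Sequence[ExpressionMatrix], y=None) -> "DiseaseAxisModel":
        if isinstance(X, ExpressionMatrix):
            X = [X]
        if len(X) < 1:
            raise ValueError("need at least one dataset")
        self.training_ = [prepare_dataset(m, self.min_total_count) for m in X]
        adjusted, model = combat_adjust(self.training_, batch_key=self.batch_key)
        self.adjusted_ = adjusted
        self.batch_model_ = model
        self.axis_, scores = build_axis(
            adjusted,
            group_key=self.group_key,
            disease_label=self.disease_label,
            reference_label=self.reference_label,
        )
        self.training_scores_ = pd.Series(scores, index=adjusted.samples, name="pc1")
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "axis_"):
            raise NotFittedError("DiseaseAxisModel is not fitted; call fit first")

    def transform(self, X: ExpressionMatrix) -> ProjectionResult:
        """Project a dataset onto the fitted axis (see :func:`project`)."""
        self._check_fitted()
        if set(X.samples) <= set(self.adjusted_.samples):
            # a training dataset: its correction "along with the rest" is the
            # fit-time run, so reuse the corrected block
            block = self.adjusted_.values[list(X.samples)]
            return _project_block(
                self.axis_, block, self.center_on, self.min_shared_frac
            )
        return project(
            self.axis_,
            X,
            self.training_,
            batch_key=self.batch_key,
            center_on=self.center_on,
            min_shared_frac=self.min_shared_frac,
        )

    def fit_transform(self, X: Sequence[ExpressionMatrix], y=None) -> ProjectionResult:
        self.fit(X, y)
        merged = merge_datasets(self.training_, self.batch_key)
        return self.transform(merged)
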