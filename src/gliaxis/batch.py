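"""Parametric empirical-Bayes location-scale batch correction (ComBat).

Multi-study expression matrices carry per-batch shifts in both location and
scale that swamp the biological signal a joint PCA is meant to find.  The
correction implemented here is the standard parametric empirical-Bayes
algorithm: genes are standardized against a batch-design fit, per-batch
per-gene location/scale effects are estimated, shrunk toward batch-level
priors (normal on location, inverse-gamma on scale) by the usual iterative
solution, and the data are adjusted by inverting the location-scale model.

The fitted :class:`~gliaxis.containers.BatchModel` exposes every stage —
standardization, raw estimates, hyperpriors, shrunken estimates — so the
correction can be inspected and reused.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BatchModel, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["combat_adjust", "merge_datasets"]


def merge_datasets(matrices: list[ExpressionMatrix], batch_key: str = "batch") -> ExpressionMatrix:
    """Column-concatenate datasets on their shared genes, tagging batches.

    Each input keeps (or is assigned) a ``batch`` label in its sample
    metadata; genes are intersected across inputs in the order of the first.
    """
    if not matrices:
        raise ValueError("need at least one dataset")
    shared = matrices[0].genes
    for m in matrices[1:]:
        shared = shared.intersection(m.genes)
    shared = matrices[0].genes[matrices[0].genes.isin(shared)]
    if len(shared) == 0:
        raise ValueError("datasets share no genes")
    values = []
    metas = []
    for i, m in enumerate(matrices):
        values.append(m.values.loc[shared])
        meta = m.sample_meta.copy()
        if batch_key not in meta.columns:
            meta[batch_key] = f"batch{i}"
        metas.append(meta)
    merged_values = pd.concat(values, axis=1)
    merged_meta = pd.concat(metas, axis=0)
    if not merged_values.columns.is_unique:
        raise ValueError("sample identifiers collide across datasets")
    return ExpressionMatrix(merged_values, merged_meta, mode="normalized")


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def _it_sol(Z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-6, max_iter=500):
    """Standard iterative solution for the shrunken location/scale estimates."""
    n = Z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        ssq = ((Z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(ssq, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() else 0.0,
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    matrices: list[ExpressionMatrix] | ExpressionMatrix,
    batch_key: str = "batch",
) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove per-batch per-gene location and scale effects.

    Parameters
    ----------
    matrices
        Either a list of datasets (merged on shared genes, each treated as
        one batch) or a single merged :class:`ExpressionMatrix` whose sample
        metadata carries the batch label.
    batch_key
        Sample-metadata column holding the batch label.

    Returns
    -------
    (adjusted, model)
        The adjusted merged matrix and the fitted :class:`BatchModel`.

    Notes
    -----
    Runs without group covariates: protecting the biological grouping would
    leak the labels this pipeline later reads off the corrected data.  A
    single batch is returned unchanged with a warning; genes with zero
    variance within any batch are dropped (logged) because their scale
    effect is unidentifiable.
    """
    if isinstance(matrices, ExpressionMatrix):
        merged = matrices
        if batch_key not in merged.sample_meta.columns:
            raise ValueError(f"sample metadata lacks column {batch_key!r}")
    else:
        merged = merge_datasets(matrices, batch_key)

    batches = list(pd.unique(merged.sample_meta[batch_key]))
    X = merged.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    batch_idx = [
        np.flatnonzero((merged.sample_meta[batch_key] == b).to_numpy()) for b in batches
    ]
    n_per = np.array([len(ix) for ix in batch_idx])
    if len(batches) == 1:
        logger.warning("single batch: correction is the identity")
        model = _identity_model(merged, batches)
        return merged, model
    if np.any(n_per < 2):
        raise ValueError("every batch needs at least 2 samples")

    # drop genes with zero variance inside any batch (scale unidentifiable)
    ok = np.ones(n_genes, dtype=bool)
    for ix in batch_idx:
        ok &= X[:, ix].var(axis=1) > 0
    if not ok.all():
        logger.warning("dropping %d genes with zero within-batch variance", int((~ok).sum()))
        merged = ExpressionMatrix(
            merged.values.loc[ok], merged.sample_meta, merged.mode
        )
        X = X[ok]
        n_genes = X.shape[0]
    genes = merged.genes

    # 1) standardization from a batch-design fit
    batch_means = np.column_stack([X[:, ix].mean(axis=1) for ix in batch_idx])
    grand_mean = batch_means @ (n_per / n_samples)
    fitted = np.empty_like(X)
    for j, ix in enumerate(batch_idx):
        fitted[:, ix] = batch_means[:, [j]]
    pooled_var = ((X - fitted) ** 2).mean(axis=1)
    pooled_sd = np.sqrt(pooled_var)
    Z = (X - grand_mean[:, None]) / pooled_sd[:, None]

    # 2) per-batch location/scale estimates on the standardized data
    gamma_hat = np.stack([Z[:, ix].mean(axis=1) for ix in batch_idx])
    delta_sq_hat = np.stack([Z[:, ix].var(axis=1, ddof=1) for ix in batch_idx])

    # 3) method-of-moments hyperpriors per batch
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    m = delta_sq_hat.mean(axis=1)
    s2 = delta_sq_hat.var(axis=1, ddof=1)
    # degenerate batches (equal scale estimates across genes) would give an
    # infinite prior; the limit is delta* = m, reached with a tiny floor
    s2 = np.maximum(s2, 1e-8 * np.maximum(m, 1.0) ** 2)
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    # 4) shrunken estimates via the iterative solution
    gamma_star = np.empty_like(gamma_hat)
    delta_sq_star = np.empty_like(delta_sq_hat)
    for j, ix in enumerate(batch_idx):
        gamma_star[j], delta_sq_star[j] = _it_sol(
            Z[:, ix], gamma_hat[j], delta_sq_hat[j],
            gamma_bar[j], tau_sq[j], a_prior[j], b_prior[j],
        )

    # 5) adjust and restore location/scale
    adjusted = np.empty_like(Z)
    for j, ix in enumerate(batch_idx):
        adjusted[:, ix] = (Z[:, ix] - gamma_star[j][:, None]) / np.sqrt(
            delta_sq_star[j]
        )[:, None]
    adjusted = adjusted * pooled_sd[:, None] + grand_mean[:, None]

    out = ExpressionMatrix(
        pd.DataFrame(adjusted, index=genes, columns=merged.samples),
        merged.sample_meta,
        mode="normalized",
    )
    model = BatchModel(
        genes=genes,
        batches=batches,
        grand_mean=grand_mean,
        pooled_sd=pooled_sd,
        gamma_hat=gamma_hat,
        delta_sq_hat=delta_sq_hat,
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        a_prior=a_prior,
        b_prior=b_prior,
        gamma_star=gamma_star,
        delta_sq_star=delta_sq_star,
    )
    return out, model


def _identity_model(merged: ExpressionMatrix, batches: list) -> BatchModel:
    n_genes = merged.n_genes
    zeros = np.zeros((1, n_genes))
    ones = np.ones((1, n_genes))
    return BatchModel(
        genes=merged.genes,
        batches=batches,
        grand_mean=merged.values.to_numpy().mean(axis=1),
        pooled_sd=np.maximum(merged.values.to_numpy().std(axis=1), 1e-12),
        gamma_hat=zeros,
        delta_sq_hat=ones,
        gamma_bar=np.zeros(1),
        tau_sq=np.zeros(1),
        a_prior=np.zeros(1),
        b_prior=np.zeros(1),
        gamma_star=zeros,
        delta_sq_star=ones,
    )
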