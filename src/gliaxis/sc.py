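"""Single-cell stage: normalization, filtering, per-donor DE, pseudo-bulk.

Differential expression follows the conserved-marker design: each treatment
condition is compared to the untreated control separately within every donor
with a two-sided Wilcoxon rank-sum test, and the per-donor p-values are
combined with Tippett's minimum-p method, 1 - (1 - min p)^k.  A gene is called
differentially expressed when the combined p falls below the threshold.

Count matrices are :class:`anndata.AnnData` objects (cells x genes, sparse)
whose ``obs`` carries ``donor``, ``condition``, ``timepoint`` and ``cluster``.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .containers import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "lognormalize",
    "filter_genes",
    "wilcoxon_de",
    "tippett_combine",
    "conserved_de",
    "call_degs",
    "pseudobulk",
]

#: Per-donor gene inclusion defaults applied before testing: a gene must be
#: detected in at least MIN_PCT of cells in one of the two groups and show an
#: absolute natural-log fold change of at least MIN_LOGFC in that donor.
MIN_PCT = 0.10
MIN_LOGFC = 0.25

_LOGFC_PSEUDOCOUNT = 1.0


def lognormalize(m: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalize and log-transform: x -> ln(1 + x/total * scale).

    Each cell's counts are divided by that cell's total count, scaled (the
    conventional factor is 1e4), and shifted-log transformed.  The sparsity
    pattern is preserved (zero counts stay exactly zero).

    Raises
    ------
    ValueError
        If any cell has a total count of zero (named in the message).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    X = sp.csr_matrix(m.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = m.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total count; remove it first")
    X = X.multiply(scale_factor / totals[:, None]).tocsr()
    X.data = np.log1p(X.data)
    out = ad.AnnData(X=X, obs=m.obs.copy(), var=m.var.copy())
    out.uns["lognormalized"] = {"scale_factor": float(scale_factor)}
    return out


def filter_genes(m: ad.AnnData, min_cells: int) -> ad.AnnData:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells.

    The boundary is inclusive and gene order is preserved.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    X = sp.csr_matrix(m.X)
    n_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = n_detected >= min_cells
    return m[:, keep].copy()


def _rank_sum_exact_p(values: np.ndarray, n_a: int) -> float:
    """Exact two-sided rank-sum p by enumerating all group-A rank assignments.

    Two-sided via the symmetric deviation |R - E[R]|; with mid-ranks for ties
    this reduces to the classical doubled tail for tie-free data.
    """
    n = len(values)
    ranks = rankdata(values)
    mu = n_a * (n + 1) / 2.0
    obs_dev = abs(ranks[:n_a].sum() - mu)
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n_a)),
        dtype=np.intp,
    ).reshape(-1, n_a)
    sums = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(sums - mu) >= obs_dev - 1e-9))


def _rank_sum_normal_p(X: np.ndarray, n_a: int) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum p per column.

    ``X`` stacks group A rows on top of group B rows.  Uses mid-ranks, the
    tie-corrected variance and a 0.5 continuity correction.
    """
    n, n_genes = X.shape
    n_b = n - n_a
    ranks = rankdata(X, axis=0)
    r_a = ranks[:n_a].sum(axis=0)
    mu = n_a * (n + 1) / 2.0
    # tie correction: sum over tie groups of (t^3 - t), per gene
    tie_term = np.empty(n_genes)
    for j in range(n_genes):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(n_genes)
    ok = var > 0
    dev = np.abs(r_a[ok] - mu)
    z = np.maximum(dev - 0.5, 0.0) / np.sqrt(var[ok])
    p[ok] = np.minimum(2.0 * norm.sf(z), 1.0)
    return p


def wilcoxon_de(
    m: ad.AnnData,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    *,
    exact_max: int = 8,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    Expects log-normalized expression (see :func:`lognormalize`).  The p-value
    uses the tie-corrected normal approximation, switching to exact
    enumeration of all rank assignments when both groups have at most
    ``exact_max`` cells.  The log fold change is computed on the de-logged
    mean scale with a pseudo-count of 1:
    ``logfc = ln[(mean expm1(a) + 1) / (mean expm1(b) + 1)]``.

    Returns
    -------
    DataFrame indexed by gene with columns ``p``, ``logfc``, ``frac_a``,
    ``frac_b`` (fractions of cells with nonzero expression).
    """
    cells_a = list(cells_a)
    cells_b = list(cells_b)
    if not cells_a or not cells_b:
        raise ValueError("both cell groups must be non-empty")
    shared = set(cells_a) & set(cells_b)
    if shared:
        raise ValueError(f"cell groups overlap: {sorted(shared)[:5]}")
    A = np.asarray(m[cells_a].X.todense(), dtype=float)
    B = np.asarray(m[cells_b].X.todense(), dtype=float)
    n_a = len(cells_a)
    X = np.vstack([A, B])

    if n_a <= exact_max and len(cells_b) <= exact_max:
        p = np.array([_rank_sum_exact_p(X[:, j], n_a) for j in range(X.shape[1])])
    else:
        p = _rank_sum_normal_p(X, n_a)

    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    logfc = np.log(mean_a + _LOGFC_PSEUDOCOUNT) - np.log(mean_b + _LOGFC_PSEUDOCOUNT)
    return pd.DataFrame(
        {
            "p": p,
            "logfc": logfc,
            "frac_a": (A > 0).mean(axis=0),
            "frac_b": (B > 0).mean(axis=0),
        },
        index=m.var_names,
    )


def tippett_combine(pvals: Sequence[float]) -> float:
    """Tippett (minimum-p) combination: 1 - (1 - min p)^k over k tests."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    p_min = p.min()
    if p_min >= 1.0:
        return 1.0
    return float(-np.expm1(p.size * np.log1p(-p_min)))


def conserved_de(
    m: ad.AnnData,
    condition: str,
    control: str,
    *,
    donor_key: str = "donor",
    condition_key: str = "condition",
    min_pct: float = MIN_PCT,
    min_logfc: float = MIN_LOGFC,
    exact_max: int = 8,
) -> pd.DataFrame:
    """Per-donor condition-vs-control DE with Tippett combination.

    For every donor contributing cells to both sides, genes passing that
    donor's inclusion filter (detected in >= ``min_pct`` of cells in at least
    one group and |logfc| >= ``min_logfc``) are tested with
    :func:`wilcoxon_de`; a gene's per-donor p-values are then combined with
    :func:`tippett_combine` over the donors in which it was tested.  Donors
    missing either side are dropped with a warning.

    Returns
    -------
    DataFrame indexed by gene with per-donor columns ``p_<donor>`` and
    ``logfc_<donor>`` (NaN where the gene was filtered in that donor),
    ``combined_p``, ``mean_logfc`` and ``n_donors_tested``.  Genes filtered
    out in every donor are absent.
    """
    obs = m.obs
    for key in (donor_key, condition_key):
        if key not in obs.columns:
            raise ValueError(f"cell metadata lacks column {key!r}")
    donors = []
    for donor in pd.unique(obs[donor_key]):
        mask = obs[donor_key] == donor
        has_cond = bool((obs.loc[mask, condition_key] == condition).any())
        has_ctrl = bool((obs.loc[mask, condition_key] == control).any())
        if has_cond and has_ctrl:
            donors.append(donor)
        else:
            logger.warning(
                "donor %r lacks cells in %s; dropped from combination",
                donor,
                "condition" if not has_cond else "control",
            )
    if not donors:
        raise ValueError(
            f"no donor contributes cells to both {condition!r} and {control!r}"
        )

    per_donor: dict = {}
    for donor in donors:
        mask = obs[donor_key] == donor
        cells_a = list(m.obs_names[mask & (obs[condition_key] == condition)])
        cells_b = list(m.obs_names[mask & (obs[condition_key] == control)])
        res = wilcoxon_de(m, cells_a, cells_b, exact_max=exact_max)
        tested = ((res["frac_a"] >= min_pct) | (res["frac_b"] >= min_pct)) & (
            res["logfc"].abs() >= min_logfc
        )
        res.loc[~tested, ["p", "logfc"]] = np.nan
        per_donor[donor] = res

    genes = m.var_names
    out = pd.DataFrame(index=genes)
    for donor in donors:
        out[f"p_{donor}"] = per_donor[donor]["p"]
        out[f"logfc_{donor}"] = per_donor[donor]["logfc"]
    p_cols = [f"p_{d}" for d in donors]
    fc_cols = [f"logfc_{d}" for d in donors]
    n_tested = out[p_cols].notna().sum(axis=1)
    out = out[n_tested > 0].copy()
    out["n_donors_tested"] = n_tested[n_tested > 0]
    out["combined_p"] = [
        tippett_combine(row.dropna().to_numpy()) for _, row in out[p_cols].iterrows()
    ]
    out["mean_logfc"] = out[fc_cols].mean(axis=1)
    return out


def call_degs(results: pd.DataFrame, alpha: float = 0.05, name: str = "DEGs") -> GeneSet:
    """Genes with ``combined_p`` strictly below ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if len(results) == 0:
        return GeneSet(name, frozenset())
    hits = results.index[results["combined_p"] < alpha]
    return GeneSet(name, frozenset(hits), f"combined p < {alpha}")


def pseudobulk(m: ad.AnnData, group_keys: Sequence[str]) -> ExpressionMatrix:
    """Average expression across cells per combination of metadata keys.

    One output column per observed key combination (column name joins the key
    values with ``|``); values are arithmetic means of the (normalized)
    expression over member cells, with member counts recorded in the sample
    metadata.  Empty combinations simply do not appear.
    """
    group_keys = list(group_keys)
    for key in group_keys:
        if key not in m.obs.columns:
            raise ValueError(f"cell metadata lacks column {key!r}")
    X = sp.csr_matrix(m.X, dtype=float)
    groups = m.obs.groupby(group_keys, observed=True).indices  # positional indices
    items = sorted(
        groups.items(),
        key=lambda kv: tuple(str(v) for v in (kv[0] if isinstance(kv[0], tuple) else (kv[0],))),
    )
    cols, names, meta_rows = [], [], []
    for key, idx in items:
        key_tuple = key if isinstance(key, tuple) else (key,)
        names.append("|".join(str(v) for v in key_tuple))
        cols.append(np.asarray(X[idx].mean(axis=0)).ravel())
        meta_rows.append(dict(zip(group_keys, key_tuple), n_cells=len(idx)))
    values = pd.DataFrame(
        np.column_stack(cols), index=m.var_names.copy(), columns=names
    )
    sample_meta = pd.DataFrame(meta_rows, index=names)
    return ExpressionMatrix(values, sample_meta, mode="normalized")
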