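"""Readers and writers for the pipeline's plain-text formats.

Sparse counts travel as Matrix Market (genes x cells) with ``genes.tsv`` /
``cells.tsv`` sidecars; dense expression matrices as TSV (genes as rows) with
a ``samples.tsv`` sidecar; gene sets as GMT; networks as two-column TSV edge
lists.  Everything is tab-separated and round-trips losslessly; parsers
reject malformed input rather than coercing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .containers import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix_market",
    "write_matrix_market",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "read_expression_tsv",
    "write_expression_tsv",
    "save_axis",
    "load_axis",
    "RunConfig",
]


def read_matrix_market(mtx_path, genes_path, cells_path) -> ad.AnnData:
    """Load a genes x cells Matrix Market file with TSV sidecars.

    ``genes.tsv`` holds one gene identifier per row (first column);
    ``cells.tsv`` holds the cell identifier in its first column plus any
    metadata columns (donor, condition, timepoint, cluster).  Dimensions are
    validated and duplicate gene identifiers rejected.
    """
    try:
        matrix = scipy.io.mmread(str(mtx_path))
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    genes = pd.read_csv(genes_path, sep="\t", header=None)
    cells = pd.read_csv(cells_path, sep="\t")
    gene_ids = genes.iloc[:, 0].astype(str)
    if gene_ids.duplicated().any():
        dups = gene_ids[gene_ids.duplicated()].tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    if matrix.shape != (len(gene_ids), len(cells)):
        raise ValueError(
            f"dimension mismatch: matrix is {matrix.shape}, sidecars describe "
            f"({len(gene_ids)}, {len(cells)})"
        )
    obs = cells.set_index(cells.columns[0])
    obs.index = obs.index.astype(str)
    X = sp.csr_matrix(matrix.T)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(gene_ids)))


def write_matrix_market(m: ad.AnnData, out_dir) -> None:
    """Write an AnnData count matrix as matrix.mtx + genes.tsv + cells.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(m.X).T  # genes x cells on disk
    if np.allclose(X.data, np.round(X.data)):
        X = X.astype(np.int64)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), X)
    pd.Series(m.var_names).to_csv(
        out_dir / "genes.tsv", sep="\t", header=False, index=False
    )
    cells = m.obs.copy()
    cells.insert(0, "cell", m.obs_names)
    cells.to_csv(out_dir / "cells.tsv", sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members within a set collapse with a warning; an empty set is
    retained with a warning.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected name<TAB>description")
            name, description, *members = parts
            unique = frozenset(m for m in members if m)
            if len(unique) < len([m for m in members if m]):
                logger.warning("%s:%d: duplicate members in set %r collapsed", path, lineno, name)
            if not unique:
                logger.warning("%s:%d: empty gene set %r", path, lineno, name)
            sets.append(GeneSet(name, unique, description))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_edge_list(path) -> pd.DataFrame:
    """Two-column (plus optional source column) TSV of interacting genes."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least two columns")
    if table.iloc[:, :2].isna().any().any():
        raise ValueError(f"{path}: missing identifiers in edge list")
    return table


def read_expression_tsv(values_path, samples_path, mode: str = "normalized") -> ExpressionMatrix:
    """Dense gene x sample TSV plus a samples.tsv metadata sidecar."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, meta.loc[values.columns], mode=mode)


def write_expression_tsv(m: ExpressionMatrix, values_path, samples_path) -> None:
    m.values.to_csv(values_path, sep="\t")
    m.sample_meta.to_csv(samples_path, sep="\t")


def save_axis(axis, table_path, header_path) -> None:
    """Serialize a disease axis: per-gene TSV plus a small key/value header."""
    pd.DataFrame(
        {"loading": axis.loadings, "training_mean": axis.training_means},
        index=pd.Index(axis.genes, name="gene"),
    ).to_csv(table_path, sep="\t")
    header = {
        "n_genes": int(axis.n_genes),
        "variance_explained": [float(v) for v in axis.variance_explained],
        "orientation": {k: (bool(v) if isinstance(v, (bool, np.bool_)) else v)
                        for k, v in axis.orientation.items()},
    }
    with open(header_path, "w") as fh:
        yaml.safe_dump(header, fh)


def load_axis(table_path, header_path):
    from .containers import DiseaseAxis

    table = pd.read_csv(table_path, sep="\t", index_col=0)
    with open(header_path) as fh:
        header = yaml.safe_load(fh)
    axis = DiseaseAxis(
        genes=table.index,
        loadings=table["loading"].to_numpy(),
        training_means=table["training_mean"].to_numpy(),
        variance_explained=np.asarray(header["variance_explained"]),
        orientation=header.get("orientation", {}),
    )
    if axis.n_genes != header["n_genes"]:
        raise ValueError("axis header and table disagree on gene count")
    return axis


@dataclass
class RunConfig:
    """Validated thresholds, bins and randomization settings for a run."""

    alpha: float = 0.05
    scale_factor: float = 1e4
    min_cells: int = 100
    min_pct: float = 0.10
    min_logfc: float = 0.25
    min_total_count: int = 20
    degree_bins: int = 10
    cds_bins: int = 10
    window_min: int = 50
    window_max: int = 1000
    window_step: int = 50
    n_rand_ppi: int = 10_000
    n_rand_rank: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in (
            "scale_factor",
            "min_pct",
            "degree_bins",
            "cds_bins",
            "window_min",
            "window_max",
            "window_step",
            "n_rand_ppi",
            "n_rand_rank",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from a plain key/value YAML file; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def window_sizes(self) -> tuple:
        return tuple(range(self.window_min, self.window_max + 1, self.window_step))
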