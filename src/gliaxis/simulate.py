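"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes, at a
size a workstation handles in seconds:

* multi-batch bulk-style expression datasets sharing one latent disease
  direction (the planted axis) but differing in per-batch location/scale and
  noise — the shape of a multi-study microglia meta-analysis;
* single-cell negative-binomial counts over donors and treatment conditions,
  with donor-specific baselines and planted condition effects — the shape of
  a multi-donor stimulation experiment;
* protein-interaction networks with heavy-tailed expected degrees and
  log-normal CDS lengths, optionally with planted edges;
* orthologue maps with a controllable 1:1 fraction and GMT-style gene sets,
  including a GWAS-like set optionally correlated with the planted axis.

Every generator draws from a substream derived from one global seed by a
fixed offset, so stages reproduce independently, and returns enough ground
truth (:class:`SimTruth`) to score recovery without re-reading the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_meta_datasets",
    "simulate_sc_counts",
    "simulate_ppi",
    "simulate_gene_annotations",
]

# fixed substream offsets: stage-level reproducibility from one global seed
_STREAM_META = 1
_STREAM_SC = 2
_STREAM_PPI = 3
_STREAM_ANNOT = 4

#: Default treatment conditions: an untreated control plus stimulations at
#: two exposure times, mirroring an eight-condition stimulation design.
DEFAULT_CONDITIONS = (
    "control",
    "lps_ifng_24",
    "lps_ifng_48",
    "pge2_24",
    "pge2_48",
    "atpgs_24",
    "lps_ifng_pge2_24",
    "pge2_atpgs_24",
)


@dataclass
class SimConfig:
    """Generator settings; defaults define the standard study conditions.

    The bulk generator uses ``n_datasets`` batches of ``samples_per_dataset``
    samples (half disease-model, half reference) over ``n_genes`` genes, a
    group separation of ``group_effect`` along the planted unit axis,
    additive per-batch offsets of sd ``batch_location_sd``, multiplicative
    per-batch factors with log-sd ``batch_scale_sigma`` and Gaussian noise of
    sd ``noise_sd``.  The single-cell generator uses ``n_donors`` donors x
    ``conditions`` x ``cells_per_condition`` cells, negative-binomial counts
    with variance mu + mu^2 * ``dispersion``, library sizes uniform over
    ``library_size_range``, and ``n_de_genes`` planted genes whose absolute
    log effect is ``de_effect`` in every non-control condition.
    """

    n_genes: int = 2000
    n_datasets: int = 7
    samples_per_dataset: int = 10
    group_effect: float = 60.0  # projected separation; per-gene shift ~ 60/sqrt(n_genes)
    noise_sd: float = 1.0
    batch_location_sd: float = 2.0
    batch_scale_sigma: float = 0.1
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0

    n_donors: int = 4
    cells_per_condition: int = 200
    conditions: tuple = DEFAULT_CONDITIONS
    control_condition: str = "control"
    dispersion: float = 0.3
    library_size_range: tuple = (1000, 5000)
    donor_shift_sd: float = 0.15
    n_de_genes: int = 100
    de_effect: float = float(np.log(2.0))

    degree_exponent: float = 2.5
    mean_degree: float = 8.0
    cds_length_params: tuple = (7.7, 0.6)

    fraction_orthologous: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_datasets",
            "samples_per_dataset",
            "n_donors",
            "cells_per_condition",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.fraction_orthologous <= 1.0:
            raise ValueError("fraction_orthologous must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.degree_exponent <= 1:
            raise ValueError("degree_exponent must exceed 1")
        if self.control_condition not in self.conditions:
            raise ValueError("conditions must include the control condition")

    @property
    def genes(self) -> pd.Index:
        return pd.Index([f"g{i:05d}" for i in range(self.n_genes)])

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SimTruth:
    """Ground truth accompanying a generated dataset."""

    seed: int
    axis_vector: np.ndarray | None = None
    group_effect: float = 0.0
    batch_locations: np.ndarray | None = None
    batch_scales: np.ndarray | None = None
    de_genes: dict = field(default_factory=dict)
    planted_edges: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.axis_vector is not None:
            self.axis_vector = np.asarray(self.axis_vector, dtype=float)
            norm = np.linalg.norm(self.axis_vector)
            if not np.isclose(norm, 1.0):
                raise ValueError(f"axis_vector must have unit norm, got {norm}")
        if self.batch_scales is not None and np.any(np.asarray(self.batch_scales) <= 0):
            raise ValueError("batch_scales must be strictly positive")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def simulate_meta_datasets(
    config: SimConfig,
    truth_overrides: dict | None = None,
    *,
    require_identifiable: bool = False,
) -> tuple[list[ExpressionMatrix], SimTruth]:
    """Multi-batch expression datasets sharing a planted disease axis.

    Each dataset holds ``samples_per_dataset`` samples split evenly into
    disease and reference groups.  A sample's value for gene g in batch b is

        scale[b, g] * (baseline[g] + 1{disease} * effect * axis[g] + loc[b, g])
        + Normal(0, noise_sd)

    i.e. the location offset is applied before the multiplicative batch
    scale, mirroring the location-scale model the correction stage inverts.

    ``truth_overrides`` may pin any of ``axis_vector``, ``group_effect``,
    ``batch_locations``, ``batch_scales`` (otherwise drawn from the config's
    distributions).  With ``require_identifiable=True`` a configuration with
    zero effect and zero noise is rejected as degenerate.
    """
    if config.n_datasets < 2:
        raise ValueError("need at least 2 datasets")
    n_disease = config.samples_per_dataset // 2
    n_reference = config.samples_per_dataset - n_disease
    if min(n_disease, n_reference) < 2:
        raise ValueError("each dataset needs at least 2 samples per group")
    overrides = dict(truth_overrides or {})
    rng = config.rng(_STREAM_META)

    effect = float(overrides.get("group_effect", config.group_effect))
    if require_identifiable and effect == 0 and config.noise_sd == 0:
        raise ValueError(
            "group_effect and noise_sd both zero: the axis is unidentifiable"
        )
    axis = overrides.get("axis_vector")
    axis = _unit(rng.standard_normal(config.n_genes)) if axis is None else _unit(
        np.asarray(axis, dtype=float)
    )
    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(
        config.n_genes
    )
    locations = overrides.get("batch_locations")
    if locations is None:
        locations = config.batch_location_sd * rng.standard_normal(
            (config.n_datasets, config.n_genes)
        )
    scales = overrides.get("batch_scales")
    if scales is None:
        scales = np.exp(
            config.batch_scale_sigma * rng.standard_normal((config.n_datasets, config.n_genes))
        )
    locations = np.asarray(locations, dtype=float)
    scales = np.asarray(scales, dtype=float)

    genes = config.genes
    datasets = []
    for b in range(config.n_datasets):
        groups = np.array(["disease"] * n_disease + ["reference"] * n_reference)
        indicator = (groups == "disease").astype(float)
        signal = baseline[None, :] + indicator[:, None] * effect * axis[None, :]
        x = scales[b][None, :] * (signal + locations[b][None, :])
        x = x + config.noise_sd * rng.standard_normal(x.shape)
        sample_ids = [f"d{b}_s{i}" for i in range(config.samples_per_dataset)]
        values = pd.DataFrame(x.T, index=genes, columns=sample_ids)
        meta = pd.DataFrame(
            {"batch": f"batch{b}", "group": groups}, index=sample_ids
        )
        datasets.append(ExpressionMatrix(values, meta, mode="normalized"))

    truth = SimTruth(
        seed=config.seed,
        axis_vector=axis,
        group_effect=effect,
        batch_locations=locations,
        batch_scales=scales,
    )
    return datasets, truth


def simulate_sc_counts(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Negative-binomial single-cell counts with donor and treatment structure.

    Per-gene propensities come from softmax-normalized logits with
    donor-specific baseline shifts; genes planted as responders get a signed
    log-scale effect added to their logits in every non-control condition.
    Each cell's expected counts are its library size times the propensities;
    counts are negative-binomial with variance mu + mu^2 * dispersion.
    """
    if config.n_donors < 2:
        raise ValueError("need at least 2 donors")
    if config.cells_per_condition <= 0:
        raise ValueError("cells_per_condition must be positive")
    rng = config.rng(_STREAM_SC)
    genes = config.genes
    n_genes = config.n_genes

    base_logits = rng.standard_normal(n_genes)
    donor_shifts = config.donor_shift_sd * rng.standard_normal(
        (config.n_donors, n_genes)
    )
    n_de = min(config.n_de_genes, n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_signs = rng.choice([-1.0, 1.0], size=n_de)
    de_effects = dict(zip(genes[de_idx], de_signs * config.de_effect))
    effect_vec = np.zeros(n_genes)
    effect_vec[de_idx] = de_signs * config.de_effect

    blocks, obs_rows = [], []
    size_nb = 1.0 / config.dispersion
    lo, hi = config.library_size_range
    for d in range(config.n_donors):
        donor = f"donor{d}"
        for cond in config.conditions:
            logits = base_logits + donor_shifts[d]
            if cond != config.control_condition:
                logits = logits + effect_vec
            props = np.exp(logits - logits.max())
            props /= props.sum()
            lib = rng.uniform(lo, hi, size=config.cells_per_condition)
            mu = lib[:, None] * props[None, :]
            counts = rng.negative_binomial(size_nb, size_nb / (size_nb + mu))
            blocks.append(sp.csr_matrix(counts))
            timepoint = cond.rsplit("_", 1)[-1] if cond[-1].isdigit() else "0"
            for i in range(config.cells_per_condition):
                obs_rows.append(
                    {
                        "cell": f"{donor}_{cond}_c{i}",
                        "donor": donor,
                        "condition": cond,
                        "timepoint": timepoint,
                        "cluster": "microglia",
                    }
                )
    obs = pd.DataFrame(obs_rows).set_index("cell")
    X = sp.vstack(blocks).tocsr()
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    truth = SimTruth(seed=config.seed, de_genes=de_effects)
    return adata, truth


def simulate_ppi(
    config: SimConfig,
    planted: Iterable[tuple] | None = None,
    *,
    weights: Sequence[float] | None = None,
) -> nx.Graph:
    """Expected-degree (Chung–Lu) random graph over the gene universe.

    Per-gene expected degrees are Pareto-distributed with tail exponent
    ``degree_exponent`` and mean close to ``mean_degree`` (a supplied
    ``weights`` vector overrides this); the probability of an edge (i, j) is
    min(1, w_i * w_j / sum(w)).  No self-loops, deduplicated, every gene is
    a node (isolated genes included so backgrounds cover the universe), and
    per-gene CDS lengths are drawn log-normal.  ``planted`` gene pairs are
    added verbatim after the random draw.
    """
    rng = config.rng(_STREAM_PPI)
    genes = config.genes
    n = config.n_genes
    if weights is None:
        # Pareto(a) has mean a*m/(a-1); scale the minimum m to hit mean_degree
        a = config.degree_exponent - 1.0
        minimum = config.mean_degree * (a - 1.0) / a if a > 1 else 1.0
        w = minimum * (1.0 + rng.pareto(a, size=n))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must have one entry per gene")
    total = w.sum()
    w = np.minimum(w, np.sqrt(total))  # cap so p_ij stays a probability
    prob = np.minimum(np.outer(w, w) / total, 1.0)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    ii, jj = np.nonzero(upper)

    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(zip(genes[ii], genes[jj]))
    if planted is not None:
        for a_gene, b_gene in planted:
            if a_gene not in g or b_gene not in g:
                raise ValueError(f"planted pair ({a_gene}, {b_gene}) references unknown genes")
            if a_gene != b_gene:
                g.add_edge(a_gene, b_gene)
    mu, sigma = config.cds_length_params
    cds = np.exp(mu + sigma * rng.standard_normal(n))
    for gene, length in zip(genes, cds):
        g.nodes[gene]["cds_length"] = float(length)
    return g


def simulate_gene_annotations(
    config: SimConfig,
    *,
    axis_vector: np.ndarray | None = None,
    gwas_correlation: float = 0.0,
    gwas_size: int = 100,
    n_random_sets: int = 3,
    random_set_size: int = 50,
) -> tuple[pd.DataFrame, list[GeneSet]]:
    """Orthologue map plus GMT-style gene sets over the simulated universe.

    The map pairs exactly ``round(fraction_orthologous * n_genes)`` genes
    1:1 with partner identifiers; of the remainder, half are dropped and
    half made many-to-many (two partner rows), emulating ambiguous
    orthology.  The returned sets include a designated ``GWAS_like`` set:
    with ``gwas_correlation`` > 0 its members are biased toward the lowest
    entries of ``axis_vector`` (sampling weights exp(-corr * z(axis))), so
    the set correlates with the planted axis; at 0 it is uniform.
    """
    rng = config.rng(_STREAM_ANNOT)
    genes = config.genes
    n = config.n_genes
    n_one_to_one = int(round(config.fraction_orthologous * n))
    perm = rng.permutation(n)
    one_idx = perm[:n_one_to_one]
    rest = perm[n_one_to_one:]
    ambiguous = rest[: len(rest) // 2]  # many-to-many; the rest are dropped

    rows = [(genes[i], f"h{genes[i][1:]}") for i in sorted(one_idx)]
    for i in sorted(ambiguous):
        rows.append((genes[i], f"h{genes[i][1:]}_a"))
        rows.append((genes[i], f"h{genes[i][1:]}_b"))
    orth_map = pd.DataFrame(rows, columns=["gene", "orthologue"])

    if gwas_correlation != 0.0:
        if axis_vector is None:
            raise ValueError("gwas_correlation requires an axis_vector")
        z = (axis_vector - axis_vector.mean()) / axis_vector.std()
        weights_p = np.exp(-gwas_correlation * z)
        weights_p /= weights_p.sum()
    else:
        weights_p = None
    gwas_idx = rng.choice(n, size=min(gwas_size, n), replace=False, p=weights_p)
    sets = [GeneSet("GWAS_like", frozenset(genes[gwas_idx]), "risk-gene-like set")]
    for s in range(n_random_sets):
        idx = rng.choice(n, size=min(random_set_size, n), replace=False)
        sets.append(GeneSet(f"random_set_{s}", frozenset(genes[idx]), "uniform draw"))
    return orth_map, sets
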