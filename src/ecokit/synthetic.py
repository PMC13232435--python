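"""Seeded synthetic single-cell datasets with planted ground truth.

The generator emulates the three inputs the ecotype pipeline consumes:

* a per-sample cell-subcluster **composition** drawn multinomially from
  Dirichlet profiles specific to each planted ecotype,
* per-cell low-dimensional **embeddings** as isotropic Gaussian clusters,
  with a controllable group-specific mean shift for designated
  "remodeled" subclusters (so the divergence statistic has a known
  population value, delta^2/8 for equal covariances),
* a log-normalized **expression** matrix with exponential-tailed background
  noise and planted subcluster marker genes elevated by a fixed amount.

All stages derive their randomness from one global seed via
:func:`ecokit._seeds.child_seed`, so any stage reproduces in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .errors import InvalidConfigError

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "block_dirichlet_alpha",
    "simulate_composition",
    "simulate_cells",
    "simulate_embeddings",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]


def block_dirichlet_alpha(
    n_subclusters: int, k_ecotypes: int, low: float = 0.3, high: float = 6.0
) -> np.ndarray:
    """Block-structured Dirichlet concentrations, one row per ecotype.

    Each ecotype concentrates its mass on a contiguous block of subclusters
    (``high``) and keeps a small background concentration (``low``)
    elsewhere, producing well-separated composition profiles.
    """
    if k_ecotypes > n_subclusters:
        raise InvalidConfigError(
            f"k_ecotypes={k_ecotypes} exceeds n_subclusters={n_subclusters}"
        )
    alpha = np.full((k_ecotypes, n_subclusters), float(low))
    bounds = np.linspace(0, n_subclusters, k_ecotypes + 1).astype(int)
    for e in range(k_ecotypes):
        alpha[e, bounds[e] : bounds[e + 1]] = float(high)
    return alpha


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset.

    ``dirichlet_alpha`` is a (k_ecotypes, n_subclusters) array of positive
    concentrations; by default a block-structured profile is built with
    :func:`block_dirichlet_alpha`. ``cells_per_sample`` is either a fixed
    integer or a ``(mean, dispersion)`` pair of a negative-binomial count
    distribution. ``noise_sd`` sets both the isotropic embedding noise and
    the exponential scale of background expression, so ``marker_log_fold``
    is naturally expressed in noise-sd units.
    """

    n_groups: int = 2
    n_samples_per_group: int = 20
    n_subclusters: int = 12
    k_ecotypes: int = 3
    dirichlet_alpha: np.ndarray | None = None
    cells_per_sample: int | tuple[float, float] = (600, 5.0)
    embed_dim: int = 30
    cluster_spacing: float = 8.0
    shift_magnitude: float = 0.0
    remodeled_subclusters: tuple[int, ...] = ()
    n_genes: int = 500
    n_markers_per_subcluster: int = 10
    marker_log_fold: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_groups",
            "n_samples_per_group",
            "n_subclusters",
            "k_ecotypes",
            "embed_dim",
            "n_genes",
            "n_markers_per_subcluster",
        ):
            if int(getattr(self, name)) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        n_samples = self.n_groups * self.n_samples_per_group
        if self.k_ecotypes > n_samples:
            raise InvalidConfigError(
                f"k_ecotypes={self.k_ecotypes} exceeds the total sample count {n_samples}"
            )
        if self.dirichlet_alpha is None:
            object.__setattr__(
                self,
                "dirichlet_alpha",
                block_dirichlet_alpha(self.n_subclusters, self.k_ecotypes),
            )
        alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if alpha.shape != (self.k_ecotypes, self.n_subclusters):
            raise InvalidConfigError(
                f"dirichlet_alpha must have shape ({self.k_ecotypes}, "
                f"{self.n_subclusters}), got {alpha.shape}"
            )
        if not np.all(alpha > 0):
            raise InvalidConfigError("dirichlet_alpha entries must be > 0")
        object.__setattr__(self, "dirichlet_alpha", alpha)
        bad = [
            j
            for j in self.remodeled_subclusters
            if not (1 <= int(j) <= self.n_subclusters)
        ]
        if bad:
            raise InvalidConfigError(
                f"remodeled_subclusters {bad} outside 1..{self.n_subclusters}"
            )
        if self.shift_magnitude < 0:
            raise InvalidConfigError("shift_magnitude must be non-negative")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        if self.marker_log_fold < 0:
            raise InvalidConfigError("marker_log_fold must be non-negative")
        if self.n_markers_per_subcluster * self.n_subclusters > self.n_genes:
            raise InvalidConfigError(
                "n_markers_per_subcluster * n_subclusters exceeds n_genes"
            )
        if isinstance(self.cells_per_sample, tuple):
            mean, disp = self.cells_per_sample
            if mean < 1 or disp <= 0:
                raise InvalidConfigError("cells_per_sample (mean, dispersion) invalid")
        elif int(self.cells_per_sample) < 1:
            raise InvalidConfigError("cells_per_sample must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.n_samples_per_group

    def subcluster_names(self) -> list[str]:
        return [f"SC{j:02d}" for j in range(1, self.n_subclusters + 1)]

    def sample_names(self) -> list[str]:
        return [f"S{j:03d}" for j in range(1, self.n_samples + 1)]

    def group_names(self) -> list[str]:
        return [f"G{j}" for j in range(1, self.n_groups + 1)]

    def gene_names(self) -> list[str]:
        return [f"g{j:04d}" for j in range(1, self.n_genes + 1)]


@dataclass
class SyntheticDataset:
    """A full synthetic dataset plus its planted ground truth."""

    cells: pd.DataFrame
    embeddings: pd.DataFrame
    expression: pd.DataFrame
    counts: pd.DataFrame
    truth_ecotype: pd.Series
    truth_markers: dict[str, list[str]]
    truth_shift: dict[str, dict[str, float]]
    config: SimulationConfig = field(repr=False)


def _sample_totals(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.cells_per_sample, tuple):
        mean, disp = config.cells_per_sample
        # NB parameterized by mean m and dispersion r: p = r/(r+m)
        p = disp / (disp + mean)
        totals = rng.negative_binomial(disp, p, size=config.n_samples)
        return np.maximum(totals, 10)
    return np.full(config.n_samples, int(config.cells_per_sample))


def simulate_composition(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Draw per-sample subcluster counts from planted ecotype profiles.

    Returns ``(counts, truth_ecotype, sample_group)``: an integer
    samples x subclusters count table, the planted ecotype label of each
    sample, and each sample's clinical group. Each sample's subcluster
    proportions are a Dirichlet draw from its ecotype's concentration row;
    counts are multinomial given the sample's cell total.
    """
    rng = np.random.default_rng(child_seed(config.seed, "composition"))
    samples = config.sample_names()
    groups = np.repeat(config.group_names(), config.n_samples_per_group)
    # cycle ecotypes across samples for balance
    ecotype_idx = np.arange(config.n_samples) % config.k_ecotypes
    totals = _sample_totals(config, rng)
    counts = np.zeros((config.n_samples, config.n_subclusters), dtype=int)
    for i in range(config.n_samples):
        p = rng.dirichlet(config.dirichlet_alpha[ecotype_idx[i]])
        counts[i] = rng.multinomial(totals[i], p)
    counts_df = pd.DataFrame(counts, index=samples, columns=config.subcluster_names())
    truth = pd.Series(
        [f"E{e + 1}" for e in ecotype_idx], index=samples, name="ecotype"
    )
    group_s = pd.Series(groups, index=samples, name="group")
    return counts_df, truth, group_s


def simulate_cells(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Expand the composition counts to one row per cell.

    Returns ``(cells, truth_ecotype)``; the cell table carries cell_id,
    sample_id, group, lineage (subclusters folded into 4 coarse lineages),
    subcluster and is_denominator.
    """
    counts, truth, group_s = simulate_composition(config)
    sub_names = counts.columns.to_numpy()
    lineage_of = {
        name: f"L{(j % 4) + 1}" for j, name in enumerate(sub_names)
    }
    rows_sample: list[np.ndarray] = []
    rows_sub: list[np.ndarray] = []
    for sample in counts.index:
        c = counts.loc[sample].to_numpy()
        rows_sample.append(np.repeat(sample, c.sum()))
        rows_sub.append(np.repeat(sub_names, c))
    sample_col = np.concatenate(rows_sample)
    sub_col = np.concatenate(rows_sub)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{j:07d}" for j in range(len(sample_col))],
            "sample_id": sample_col,
            "group": group_s.loc[sample_col].to_numpy(),
            "lineage": [lineage_of[s] for s in sub_col],
            "subcluster": sub_col,
            "is_denominator": True,
        }
    )
    return cells, truth


def _base_means(config: SimulationConfig) -> np.ndarray:
    """Deterministic well-separated subcluster centroids.

    Subcluster j sits at ``cluster_spacing`` along coordinate axis
    ``j mod embed_dim`` (scaled up on each wrap), keeping centroids at
    least ``cluster_spacing`` apart for n_subclusters <= embed_dim.
    """
    means = np.zeros((config.n_subclusters, config.embed_dim))
    for j in range(config.n_subclusters):
        axis = j % config.embed_dim
        level = 1 + j // config.embed_dim
        means[j, axis] = config.cluster_spacing * level
    return means


def shift_direction(config: SimulationConfig) -> np.ndarray:
    """Fixed unit direction along which remodeled subclusters are displaced.

    The diagonal direction (1,...,1)/sqrt(d) is used: it is not aligned with
    any subcluster centroid axis, so the shift is a pure group effect.
    """
    u = np.ones(config.embed_dim)
    return u / np.linalg.norm(u)


def simulate_embeddings(
    config: SimulationConfig, cells: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell Gaussian embeddings with group-specific shifts.

    Each cell is drawn from an isotropic Gaussian centred on its
    subcluster's base mean; cells of a remodeled subcluster in the last
    (highest-index) clinical group are displaced by ``shift_magnitude``
    along a fixed unit direction. The population Bhattacharyya distance
    between the two group distributions of a remodeled subcluster is then
    exactly ``shift_magnitude**2 / (8 * noise_sd**2)``.
    """
    if config.embed_dim < 1:
        raise InvalidConfigError("embed_dim must be >= 1")
    rng = np.random.default_rng(child_seed(config.seed, "embeddings"))
    sub_names = config.subcluster_names()
    sub_index = pd.Index(sub_names)
    means = _base_means(config)
    u = shift_direction(config)
    shifted_group = config.group_names()[-1]
    remodeled = {sub_names[j - 1] for j in config.remodeled_subclusters}

    sub_codes = sub_index.get_indexer(cells["subcluster"])
    if (sub_codes < 0).any():
        raise InvalidConfigError("cells contain subclusters unknown to the config")
    coords = means[sub_codes] + config.noise_sd * rng.standard_normal(
        (len(cells), config.embed_dim)
    )
    shifted = (
        cells["group"].eq(shifted_group).to_numpy()
        & cells["subcluster"].isin(remodeled).to_numpy()
    )
    coords[shifted] += config.shift_magnitude * u
    return pd.DataFrame(
        coords,
        index=pd.Index(cells["cell_id"], name="cell_id"),
        columns=[f"PC{j + 1}" for j in range(config.embed_dim)],
    )


def simulate_expression(
    config: SimulationConfig, cells: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Log-normalized expression with planted subcluster markers.

    Background values follow an exponential distribution with scale
    ``noise_sd`` (non-negative, heavy right tail, mimicking log-normalized
    counts). Each subcluster owns a disjoint block of
    ``n_markers_per_subcluster`` genes whose expression is elevated by
    ``marker_log_fold`` in that subcluster's cells.

    Returns ``(expression, truth_markers)`` with expression genes x cells.
    """
    rng = np.random.default_rng(child_seed(config.seed, "expression"))
    genes = config.gene_names()
    n_cells = len(cells)
    X = rng.exponential(scale=config.noise_sd, size=(config.n_genes, n_cells))
    sub_names = config.subcluster_names()
    m = config.n_markers_per_subcluster
    truth_markers: dict[str, list[str]] = {}
    sub_arr = cells["subcluster"].to_numpy()
    for j, sub in enumerate(sub_names):
        gene_idx = np.arange(j * m, (j + 1) * m)
        truth_markers[sub] = [genes[g] for g in gene_idx]
        cols = np.flatnonzero(sub_arr == sub)
        if cols.size:
            X[np.ix_(gene_idx, cols)] += config.marker_log_fold
    expr = pd.DataFrame(
        X, index=pd.Index(genes, name="gene"), columns=cells["cell_id"].to_numpy()
    )
    return expr, truth_markers


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full dataset: cells, embeddings, expression, truth."""
    counts, truth, _ = simulate_composition(config)
    cells, _ = simulate_cells(config)
    embeddings = simulate_embeddings(config, cells)
    expression, truth_markers = simulate_expression(config, cells)
    sub_names = config.subcluster_names()
    shifted_group = config.group_names()[-1]
    truth_shift = {
        sub: {
            shifted_group: (
                config.shift_magnitude
                if (j + 1) in config.remodeled_subclusters
                else 0.0
            )
        }
        for j, sub in enumerate(sub_names)
    }
    return SyntheticDataset(
        cells=cells,
        embeddings=embeddings,
        expression=expression,
        counts=counts,
        truth_ecotype=truth,
        truth_markers=truth_markers,
        truth_shift=truth_shift,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as headed UTF-8 TSV files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out / "cells.tsv",
        "embeddings": out / "embeddings.tsv",
        "expression": out / "expression.tsv",
        "counts": out / "counts.tsv",
        "truth_ecotype": out / "truth_ecotype.tsv",
        "truth_markers": out / "truth_markers.tsv",
    }
    dataset.cells.to_csv(paths["cells"], sep="\t", index=False)
    dataset.embeddings.to_csv(paths["embeddings"], sep="\t")
    dataset.expression.to_csv(paths["expression"], sep="\t")
    dataset.counts.to_csv(paths["counts"], sep="\t", index_label="sample_id")
    dataset.truth_ecotype.rename("ecotype").to_csv(
        paths["truth_ecotype"], sep="\t", index_label="sample_id"
    )
    marker_rows = [
        {"subcluster": sub, "gene": g}
        for sub, gs in dataset.truth_markers.items()
        for g in gs
    ]
    pd.DataFrame(marker_rows).to_csv(paths["truth_markers"], sep="\t", index=False)
    return paths
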