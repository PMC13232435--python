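"""Per-sample composition matrices and Ro/e tissue-preference statistics.

``build_composition`` turns a cell annotation table into a samples x
clusters matrix of relative abundances over a declared denominator
population (all cells, or only those flagged as microenvironmental).

``compute_roe`` computes the ratio of observed to expected cell counts per
(cluster, group) cell of the contingency table, with expected counts from
the chi-square independence model: E(c,g) = rowtotal(c) * coltotal(g) /
grandtotal. Ro/e > 1 is read as enrichment of the cluster in that group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["CompositionMatrix", "RoeTable", "build_composition", "compute_roe"]

_LEVELS = ("lineage", "subcluster")


@dataclass
class CompositionMatrix:
    """Samples x clusters relative abundances.

    ``values`` rows sum to 1 over the included clusters; ``denominator``
    records the rule used ("all" or "tme_only"); ``sample_groups`` maps each
    sample to its clinical group.
    """

    values: pd.DataFrame
    denominator: str
    sample_groups: pd.Series
    level: str = "subcluster"

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def clusters(self) -> pd.Index:
        return self.values.columns


@dataclass
class RoeTable:
    """Observed/expected enrichment of clusters across clinical groups."""

    values: pd.DataFrame  # clusters x groups, NaN where a margin is zero
    observed: pd.DataFrame
    expected: pd.DataFrame

    @property
    def enriched(self) -> pd.DataFrame:
        """Boolean mask: Ro/e > 1 (missing values are not enriched)."""
        return self.values.gt(1.0).fillna(False)


def _check_cells(cells: pd.DataFrame, level: str) -> None:
    required = {"cell_id", "sample_id", "group", level}
    missing = sorted(required - set(cells.columns))
    if missing:
        raise ValidationError(f"cell table missing required column(s): {missing}")
    if level not in _LEVELS:
        raise ValidationError(f"level must be one of {_LEVELS}, got {level!r}")
    for col in ("sample_id", "group", level):
        if cells[col].isna().any():
            raise ValidationError(f"cell table has missing values in {col!r}")


def build_composition(
    cells: pd.DataFrame,
    level: str = "subcluster",
    denominator_rule: str = "all",
) -> CompositionMatrix:
    """Relative cluster abundances per sample.

    Parameters
    ----------
    cells
        Cell annotation table with columns cell_id, sample_id, group and
        the requested ``level`` column; an optional boolean
        ``is_denominator`` column marks microenvironmental cells.
    level
        "lineage" or "subcluster" — the clustering granularity.
    denominator_rule
        "all" uses every cell; "tme_only" restricts numerator and
        denominator to cells with ``is_denominator`` true (e.g. excluding
        malignant epithelium).

    Raises
    ------
    ValidationError
        If a sample retains zero denominator cells (named in the message).
    """
    _check_cells(cells, level)
    if denominator_rule not in ("all", "tme_only"):
        raise ValidationError(
            f"denominator_rule must be 'all' or 'tme_only', got {denominator_rule!r}"
        )
    kept = cells
    if denominator_rule == "tme_only":
        if "is_denominator" not in cells.columns:
            raise ValidationError(
                "denominator_rule='tme_only' requires an 'is_denominator' column"
            )
        kept = cells[cells["is_denominator"].astype(bool)]
    all_samples = pd.Index(cells["sample_id"].unique())
    empty = all_samples.difference(pd.Index(kept["sample_id"].unique()))
    if len(empty):
        raise ValidationError(
            "sample(s) with zero denominator cells: " + ", ".join(map(str, empty))
        )
    counts = pd.crosstab(kept["sample_id"], kept[level])
    values = counts.div(counts.sum(axis=1), axis=0)
    groups = (
        cells.drop_duplicates("sample_id").set_index("sample_id")["group"]
    ).reindex(values.index)
    return CompositionMatrix(
        values=values,
        denominator=denominator_rule,
        sample_groups=groups,
        level=level,
    )


def compute_roe(
    cells: pd.DataFrame,
    cluster_level: str = "subcluster",
    weighting: str = "cells",
) -> RoeTable:
    """Ratio of observed to expected cell counts per cluster and group.

    Expected counts come from the chi-square contingency expectation on the
    full clusters x groups table built jointly across all clusters. Rows or
    columns with a zero margin yield missing (NaN) Ro/e values — "absent"
    is distinguished from "depleted" — with a warning.

    ``weighting='equal_sample'`` rescales every sample's cell counts to a
    common total before pooling, so each sample contributes equally; the
    default pools raw cells as in standard practice.
    """
    _check_cells(cells, cluster_level)
    if weighting not in ("cells", "equal_sample"):
        raise ValidationError(
            f"weighting must be 'cells' or 'equal_sample', got {weighting!r}"
        )
    if cells["group"].nunique() < 2:
        raise ValidationError("Ro/e requires at least 2 groups")
    if weighting == "cells":
        observed = pd.crosstab(cells[cluster_level], cells["group"]).astype(float)
    else:
        per_sample = pd.crosstab(
            [cells["sample_id"], cells["group"]], cells[cluster_level]
        )
        scaled = per_sample.div(per_sample.sum(axis=1), axis=0)
        observed = scaled.groupby(level="group").sum().T
        observed.index.name = cluster_level
    grand = float(observed.to_numpy().sum())
    if grand <= 0:
        raise ValidationError("empty contingency table")
    row = observed.sum(axis=1).to_numpy()
    col = observed.sum(axis=0).to_numpy()
    expected = pd.DataFrame(
        np.outer(row, col) / grand, index=observed.index, columns=observed.columns
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        roe = observed / expected
    zero_rows = observed.index[row == 0]
    zero_cols = observed.columns[col == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            "zero-margin cluster(s)/group(s) give undefined Ro/e: "
            f"clusters={list(zero_rows)}, groups={list(zero_cols)}",
            stacklevel=2,
        )
        roe.loc[zero_rows, :] = np.nan
        roe.loc[:, zero_cols] = np.nan
    return RoeTable(values=roe, observed=observed, expected=expected)
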