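"""Transcriptional divergence between clinical groups on embeddings.

A cell population's divergence between two clinical states is quantified by
the Bhattacharyya distance between the group distributions of its cells in
a shared low-dimensional (batch-corrected) embedding space, under a
Gaussian approximation:

    D_B = 1/8 (mu1-mu2)^T Sigma_bar^{-1} (mu1-mu2)
          + 1/2 ln( det Sigma_bar / sqrt(det Sigma1 det Sigma2) ),

with Sigma_bar = (Sigma1+Sigma2)/2. Because subsamples are small relative
to the embedding dimension (50 cells in 30 dimensions), each covariance is
shrunk toward a scaled identity, (1-lambda) S + lambda tr(S)/d I, with
Ledoit-Wolf data-driven intensity by default.

``divergence_test`` estimates the distance from repeated equal-size
subsamples of the two groups and contrasts it with a null built from random
splits of the pooled cells (group labels ignored); the paired differences
(observed - null) are the divergence statistic. Clusters without more than
``min_cells_per_group`` cells in each group are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf

from ._seeds import child_seed
from .errors import NumericalDegeneracyError, ValidationError

__all__ = [
    "DivergenceConfig",
    "DivergenceResult",
    "bhattacharyya_from_params",
    "bhattacharyya_gaussian",
    "divergence_test",
    "divergence_screen",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class DivergenceConfig:
    """Subsampling parameters of the divergence test."""

    n_iterations: int = 100
    subsample_size: int = 50
    min_cells_per_group: int = 200
    covariance_regularization: float | str = "auto"
    null: str = "pooled"  # or "within_group"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.subsample_size < 2:
            raise ValidationError("subsample_size must be >= 2")
        if self.null not in ("pooled", "within_group"):
            raise ValidationError("null must be 'pooled' or 'within_group'")
        lam = self.covariance_regularization
        if lam != "auto" and not (0.0 <= float(lam) <= 1.0):
            raise ValidationError("covariance_regularization must be in [0,1] or 'auto'")


@dataclass
class DivergenceResult:
    """Per-iteration observed, null and paired-difference distances."""

    cluster: str
    group_a: str
    group_b: str
    observed: np.ndarray | None = None
    null: np.ndarray | None = None
    excluded: bool = False
    n_cells: dict[str, int] = field(default_factory=dict)

    @property
    def difference(self) -> np.ndarray | None:
        if self.excluded:
            return None
        return self.observed - self.null

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.difference))

    @property
    def median_difference(self) -> float:
        return float(np.median(self.difference))

    def to_frame(self) -> pd.DataFrame:
        if self.excluded:
            return pd.DataFrame(
                {"cluster": [self.cluster], "excluded": [True]}
            )
        return pd.DataFrame(
            {
                "cluster": self.cluster,
                "iteration": np.arange(1, len(self.observed) + 1),
                "observed": self.observed,
                "null": self.null,
                "difference": self.difference,
            }
        )


def _shrunk_cov(X: np.ndarray, lam: float | str) -> np.ndarray:
    d = X.shape[1]
    if lam == "auto":
        cov, _ = ledoit_wolf(X)
        return cov
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    if lam == 0:
        return S
    mu = np.trace(S) / d
    return (1.0 - lam) * S + lam * mu * np.eye(d)


def bhattacharyya_from_params(
    mu1: np.ndarray, cov1: np.ndarray, mu2: np.ndarray, cov2: np.ndarray
) -> float:
    """Population Bhattacharyya distance of two Gaussians from parameters.

    Evaluates the closed form on the given means and covariances; for equal
    covariances sigma^2 I this reduces to ||mu1-mu2||^2 / (8 sigma^2).
    """
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    S1 = np.atleast_2d(np.asarray(cov1, dtype=float))
    S2 = np.atleast_2d(np.asarray(cov2, dtype=float))
    Sbar = 0.5 * (S1 + S2)
    sign, logdet_bar = np.linalg.slogdet(Sbar)
    if sign <= 0:
        raise NumericalDegeneracyError("pooled covariance is singular")
    dmu = mu1 - mu2
    maha = 0.125 * float(dmu @ np.linalg.solve(Sbar, dmu))
    s1, l1 = np.linalg.slogdet(S1)
    s2, l2 = np.linalg.slogdet(S2)
    if s1 <= 0 or s2 <= 0:
        raise NumericalDegeneracyError("singular covariance")
    return max(0.0, maha + 0.5 * (logdet_bar - 0.5 * (l1 + l2)))


def bhattacharyya_gaussian(
    X: np.ndarray, Y: np.ndarray, shrinkage: float | str = "auto"
) -> float:
    """Gaussian closed-form Bhattacharyya distance between two point sets.

    Parameters
    ----------
    X, Y
        (n1, d) and (n2, d) arrays; n1, n2 >= 2.
    shrinkage
        Covariance shrinkage intensity lambda in [0, 1], or "auto" for the
        Ledoit-Wolf estimate per point set. The target is the scaled
        identity tr(S)/d * I.

    Returns the non-negative distance; symmetric in (X, Y) and exactly 0
    when X and Y contain the same points.

    Raises
    ------
    NumericalDegeneracyError
        If the pooled covariance is numerically singular (typically with
        shrinkage 0 and fewer points than dimensions).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValidationError("X and Y must be 2-D with matching dimensionality")
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValidationError("need at least 2 points per set")
    S1 = _shrunk_cov(X, shrinkage)
    S2 = _shrunk_cov(Y, shrinkage)
    Sbar = 0.5 * (S1 + S2)
    sign, logdet_bar = np.linalg.slogdet(Sbar)
    if sign <= 0 or np.linalg.cond(Sbar) > _COND_LIMIT:
        raise NumericalDegeneracyError(
            "pooled covariance is numerically singular; use shrinkage > 0 "
            "(e.g. covariance_regularization='auto')"
        )
    dmu = X.mean(axis=0) - Y.mean(axis=0)
    maha = 0.125 * float(dmu @ np.linalg.solve(Sbar, dmu))
    s1, l1 = np.linalg.slogdet(S1)
    s2, l2 = np.linalg.slogdet(S2)
    if s1 <= 0 or s2 <= 0:
        raise NumericalDegeneracyError(
            "singular per-group covariance; use shrinkage > 0"
        )
    logterm = 0.5 * (logdet_bar - 0.5 * (l1 + l2))
    return max(0.0, maha + logterm)


def divergence_test(
    cells: pd.DataFrame,
    emb: pd.DataFrame,
    cluster: str,
    group_a: str,
    group_b: str,
    cfg: DivergenceConfig | None = None,
    cluster_level: str = "subcluster",
) -> DivergenceResult:
    """Subsampled Bhattacharyya divergence of one cluster between two groups.

    For each iteration, ``subsample_size`` cells are drawn without
    replacement from the cluster's cells in each group and their distance
    recorded; a matched null distance is computed between two disjoint
    random subsets of the pooled cluster cells (or of one group's cells
    when ``cfg.null == 'within_group'``). The paired difference
    observed - null is the divergence statistic; under no group effect its
    distribution is centred at zero.

    Clusters lacking more than ``min_cells_per_group`` cells in either
    group are returned flagged ``excluded`` with no distances.
    """
    cfg = cfg or DivergenceConfig()
    sub = cells[cells[cluster_level] == cluster]
    if sub.empty:
        raise ValidationError(f"cluster {cluster!r} not present in cell table")
    coords = emb.loc[sub["cell_id"]].to_numpy()
    in_a = sub["group"].eq(group_a).to_numpy()
    in_b = sub["group"].eq(group_b).to_numpy()
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    result = DivergenceResult(
        cluster=cluster,
        group_a=group_a,
        group_b=group_b,
        n_cells={group_a: n_a, group_b: n_b},
    )
    if n_a <= cfg.min_cells_per_group or n_b <= cfg.min_cells_per_group:
        result.excluded = True
        return result
    m = cfg.subsample_size
    pool_idx = (
        np.flatnonzero(in_a | in_b)
        if cfg.null == "pooled"
        else np.flatnonzero(in_a)
    )
    if 2 * m > pool_idx.size:
        raise ValidationError(
            f"2*subsample_size={2 * m} exceeds the {pool_idx.size} cells "
            "available for the null draw"
        )
    idx_a = np.flatnonzero(in_a)
    idx_b = np.flatnonzero(in_b)
    rng = np.random.default_rng(child_seed(cfg.seed, f"divergence:{cluster}"))
    lam = cfg.covariance_regularization
    observed = np.empty(cfg.n_iterations)
    null = np.empty(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        sa = rng.choice(idx_a, size=m, replace=False)
        sb = rng.choice(idx_b, size=m, replace=False)
        observed[it] = bhattacharyya_gaussian(coords[sa], coords[sb], lam)
        perm = rng.permutation(pool_idx)
        null[it] = bhattacharyya_gaussian(coords[perm[:m]], coords[perm[m : 2 * m]], lam)
    result.observed = observed
    result.null = null
    return result


def divergence_screen(
    cells: pd.DataFrame,
    emb: pd.DataFrame,
    group_a: str,
    group_b: str,
    cfg: DivergenceConfig | None = None,
    cluster_level: str = "subcluster",
) -> dict[str, DivergenceResult]:
    """Run :func:`divergence_test` for every cluster; excluded ones flagged."""
    cfg = cfg or DivergenceConfig()
    return {
        cl: divergence_test(cells, emb, cl, group_a, group_b, cfg, cluster_level)
        for cl in sorted(cells[cluster_level].unique())
    }
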