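"""Marker derivation, binned-control module scoring and meta-analysis.

Markers are one-vs-rest Wilcoxon rank-sum tests per gene and cluster with
Bonferroni control over the full genes x clusters family; the fold change
is log2 of expm1-means with pseudocount 1 (expression is consumed on the
log-normalized scale). Signatures are the top-k passing genes ranked by
fold change. Module scores subtract the mean expression of
expression-matched control genes — genes ranked by overall mean expression
are cut into equal-frequency bins, and each signature gene draws its
controls from its own bin — so the score is centred at zero for a random
gene set. Cross-dataset effect estimates are pooled with the
DerSimonian-Laird random-effects model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_seed
from .errors import ValidationError

__all__ = [
    "SignatureSet",
    "RandomEffectsResults",
    "rank_markers",
    "signature_top_k",
    "derive_group_signatures",
    "module_score",
    "ecotype_score",
    "meta_random_effects",
    "log_odds_from_scores",
]


@dataclass
class SignatureSet:
    """Named, ordered gene lists with derivation metadata."""

    sets: dict[str, list[str]]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"sets": self.sets, "meta": self.meta}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureSet":
        obj = json.loads(Path(path).read_text())
        if "sets" in obj:
            return cls(sets=obj["sets"], meta=obj.get("meta", {}))
        return cls(sets=obj)


# ---------------------------------------------------------------------------
# marker derivation


def rank_markers(
    expr: pd.DataFrame, labels: pd.Series, min_cells: int = 3
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    Parameters
    ----------
    expr
        genes x cells log-normalized expression.
    labels
        cell -> cluster, aligned to ``expr`` columns.

    For each gene and cluster the two-sided Mann-Whitney/Wilcoxon rank-sum
    statistic is computed with mid-rank ties (normal approximation; exact
    enumeration when both sides have <= 10 cells), and
    ``avg_log2FC = log2((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1))``.
    P-values are Bonferroni-adjusted over the genes x clusters family.
    Clusters with fewer than ``min_cells`` cells are skipped with a warning.
    """
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValidationError("labels missing for some expression columns")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValidationError("marker ranking requires >= 2 clusters")
    X = expr.to_numpy(dtype=float)
    E = np.expm1(X)
    rows = []
    tested_clusters = []
    for cl in clusters:
        mask = labels.eq(cl).to_numpy()
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in < min_cells or n_out < min_cells:
            warnings.warn(
                f"cluster {cl!r} has < {min_cells} cells on one side; skipped",
                stacklevel=2,
            )
            continue
        tested_clusters.append(cl)
        method = "exact" if (n_in <= 10 and n_out <= 10) else "asymptotic"
        res = stats.mannwhitneyu(
            X[:, mask], X[:, ~mask], axis=1, alternative="two-sided", method=method
        )
        mean_in = E[:, mask].mean(axis=1)
        mean_out = E[:, ~mask].mean(axis=1)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        rows.append(
            pd.DataFrame(
                {
                    "gene": expr.index,
                    "cluster": cl,
                    "avg_log2FC": lfc,
                    "p_raw": res.pvalue,
                }
            )
        )
    if not rows:
        raise ValidationError("no cluster had enough cells for testing")
    table = pd.concat(rows, ignore_index=True)
    m = len(expr.index) * len(tested_clusters)
    table["p_adj"] = np.minimum(1.0, table["p_raw"] * m)
    return table


def signature_top_k(
    markers: pd.DataFrame, k: int = 50, p_filter: float = 0.05
) -> SignatureSet:
    """Top-k signature genes per cluster by fold change.

    Keeps genes with ``p_adj <= p_filter``, sorts by ``avg_log2FC``
    descending (ties toward the lexicographically smaller gene name), and
    truncates to ``k`` (shorter if fewer pass). Clusters with no passing
    gene get an empty list with a warning.
    """
    if markers.empty:
        raise ValidationError("marker table is empty")
    sets: dict[str, list[str]] = {}
    for cl, sub in markers.groupby("cluster", sort=True):
        passing = sub[sub["p_adj"] <= p_filter]
        ordered = passing.sort_values(
            ["avg_log2FC", "gene"], ascending=[False, True]
        )
        genes = ordered["gene"].tolist()[:k]
        if not genes:
            warnings.warn(f"cluster {cl!r}: no gene passes p_adj <= {p_filter}",
                          stacklevel=2)
        sets[str(cl)] = genes
    return SignatureSet(
        sets=sets, meta={"k": k, "p_filter": p_filter, "rank_by": "avg_log2FC"}
    )


def derive_group_signatures(
    markers: pd.DataFrame,
    group_means: pd.DataFrame,
    k: int = 20,
    p_filter: float = 1e-4,
) -> tuple[SignatureSet, list[str]]:
    """Group-specific signatures from subcluster markers by expression preference.

    The per-subcluster marker lists are filtered (``p_adj <= p_filter``),
    reduced to their top-``k`` genes by fold change, pooled, and each
    pooled gene is assigned to the single group where its mean expression
    (``group_means``, genes x groups) is maximal. Genes with all-equal
    group means go to the first group in column order and are returned in
    the flagged list.
    """
    if group_means.shape[1] < 2:
        raise ValidationError("need >= 2 groups")
    top = signature_top_k(markers, k=k, p_filter=p_filter)
    pooled = sorted({g for genes in top.sets.values() for g in genes})
    missing = [g for g in pooled if g not in group_means.index]
    if missing:
        raise ValidationError(f"group_means missing genes: {missing[:5]}...")
    sets: dict[str, list[str]] = {g: [] for g in group_means.columns}
    flagged: list[str] = []
    gm = group_means.loc[pooled]
    pref = gm.idxmax(axis=1)  # first column wins ties
    ties = gm.nunique(axis=1) == 1
    for gene in pooled:
        sets[pref[gene]].append(gene)
        if ties[gene]:
            flagged.append(gene)
    return (
        SignatureSet(
            sets=sets,
            meta={"k": k, "p_filter": p_filter, "assignment": "expression preference"},
        ),
        flagged,
    )


# ---------------------------------------------------------------------------
# binned-control module scoring


def module_score(
    expr: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per column (cell or sample).

    All genes are ranked by their mean expression across columns and cut
    into ``n_bins`` equal-frequency bins. For each signature gene,
    ``n_controls`` control genes are sampled without replacement from its
    bin (the whole bin if smaller). The score of a column is the mean
    expression of the signature genes minus the mean expression of the
    pooled (unique) control genes, so expression-matched random sets score
    about zero. Missing signature genes are dropped with a warning; an
    empty intersection is an error.
    """
    present = [g for g in gene_set if g in expr.index]
    dropped = len(gene_set) - len(present)
    if dropped:
        warnings.warn(f"{dropped} signature gene(s) absent from the matrix; dropped",
                      stacklevel=2)
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")
    means = expr.mean(axis=1)
    order = means.rank(method="first").astype(int) - 1  # 0..n_genes-1, stable
    n_genes = len(means)
    bins = (order * n_bins) // n_genes  # equal-frequency bins
    rng = np.random.default_rng(child_seed(seed, "module-score"))
    control: set[str] = set()
    genes_by_bin = {b: expr.index[(bins == b).to_numpy()] for b in np.unique(bins)}
    for g in present:
        pool = genes_by_bin[int(bins[g])]
        take = min(n_controls, len(pool))
        control.update(rng.choice(pool, size=take, replace=False))
    ctrl = sorted(control)
    score = expr.loc[present].mean(axis=0) - expr.loc[ctrl].mean(axis=0)
    score.name = "module_score"
    return score


def ecotype_score(
    expr: pd.DataFrame,
    signatures: SignatureSet,
    n_bins: int = 24,
    n_controls: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned-control score of each signature on bulk samples or spots.

    Same construction as :func:`module_score`, applied per signature with
    a smaller default control pool (50 per bin), returning a
    columns x signatures score table.
    """
    out = {}
    for name, genes in signatures.items():
        out[name] = module_score(
            expr, genes, n_bins=n_bins, n_controls=n_controls,
            seed=child_seed(seed, f"sig:{name}"),
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# random-effects meta-analysis


@dataclass
class RandomEffectsResults:
    """DerSimonian-Laird pooled effect with heterogeneity diagnostics."""

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    df: int
    i2: float
    weights: pd.Series
    table: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        lines = [
            "Random-effects meta-analysis (DerSimonian-Laird)",
            "=" * 52,
            self.table.to_string(float_format=lambda v: f"{v:.4f}"),
            "-" * 52,
            f"pooled effect: {self.pooled:.4f} "
            f"(95% CI {self.ci_low:.4f} to {self.ci_high:.4f})",
            f"tau^2 = {self.tau2:.4f}   Q = {self.q:.4f} (df={self.df})   "
            f"I^2 = {100 * self.i2:.1f}%",
        ]
        return "\n".join(lines)


def meta_random_effects(
    effects, ses, labels=None
) -> RandomEffectsResults:
    """Pool per-study effect estimates with DerSimonian-Laird weights.

    Fixed-effect weights w_i = 1/SE_i^2 give the Cochran heterogeneity
    statistic Q = sum w_i (theta_i - theta_FE)^2; the between-study
    variance is tau^2 = max(0, (Q - (n-1)) / (sum w - sum w^2 / sum w));
    random-effects weights w*_i = 1/(SE_i^2 + tau^2) yield the pooled
    estimate and its 95% CI pooled +/- 1.96/sqrt(sum w*).
    """
    theta = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.size < 1:
        raise ValidationError("need >= 1 study")
    if theta.shape != se.shape:
        raise ValidationError("effects and ses must have equal length")
    if (se <= 0).any():
        raise ValidationError("all standard errors must be > 0")
    if labels is None:
        labels = [f"study{i + 1}" for i in range(theta.size)]
    n = theta.size
    w = 1.0 / se**2
    theta_fe = float((w * theta).sum() / w.sum())
    q = float((w * (theta - theta_fe) ** 2).sum())
    if n > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (n - 1)) / denom)
    else:
        tau2 = 0.0
    wr = 1.0 / (se**2 + tau2)
    pooled = float((wr * theta).sum() / wr.sum())
    pooled_se = float(1.0 / np.sqrt(wr.sum()))
    i2 = max(0.0, (q - (n - 1)) / q) if (n > 1 and q > 0) else 0.0
    weights = pd.Series(wr / wr.sum(), index=pd.Index(labels, name="study"),
                        name="weight")
    table = pd.DataFrame(
        {"effect": theta, "se": se, "weight": weights.to_numpy()},
        index=weights.index,
    )
    return RandomEffectsResults(
        pooled=pooled,
        se=pooled_se,
        ci_low=pooled - 1.96 * pooled_se,
        ci_high=pooled + 1.96 * pooled_se,
        tau2=tau2,
        q=q,
        df=max(0, n - 1),
        i2=i2,
        weights=weights,
        table=table,
    )


def log_odds_from_scores(
    scores: pd.Series, groups: pd.Series, positive_group: str
) -> tuple[float, float]:
    """Log odds ratio of high-score membership in ``positive_group``.

    One convention for turning per-sample signature scores into a
    meta-analyzable effect: scores are dichotomized at the median
    ("high" = strictly above), a 2x2 table of high/low vs
    positive/other group is formed with the Haldane-Anscombe 0.5
    correction, and the log odds ratio and its standard error
    sqrt(sum of reciprocal cell counts) are returned. Other
    dichotomizations are equally defensible; callers may supply their own
    (effect, SE) pairs to :func:`meta_random_effects` instead.
    """
    groups = groups.reindex(scores.index)
    if groups.isna().any():
        raise ValidationError("groups missing for some scored samples")
    high = scores > scores.median()
    pos = groups.eq(positive_group)
    a = float((high & pos).sum()) + 0.5
    b = float((high & ~pos).sum()) + 0.5
    c = float((~high & pos).sum()) + 0.5
    d = float((~high & ~pos).sum()) + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(log_or), float(se)
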