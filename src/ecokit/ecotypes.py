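"""Sample-level ecotype discovery from cell-subtype composition.

The central object is a consensus non-negative matrix factorization of the
min-max-normalized subtypes x samples abundance matrix:

* ``nmf_brunet`` — multiplicative-update NMF minimizing the generalized
  Kullback-Leibler divergence D(V || WH) (the Brunet variant, with
  row/column-normalized update factors), random uniform initialization.
* ``select_rank`` — for each candidate rank, many seeded runs are reduced
  to sample co-assignment (argmax factor) connectivity matrices; their mean
  is the consensus matrix, and the cophenetic correlation between
  (1 - consensus) dissimilarities and an average-linkage tree on them
  scores the stability of that rank. The recommended rank maximizes the
  cophenetic coefficient (ties to the smaller rank).
* ``extract_features`` — per-subtype factor-specificity score
  1 + (1/log2 k) * sum_f p_f log2 p_f on the normalized basis rows;
  subtypes scoring above median + 3*MAD are representative of their argmax
  factor.
* ``assign_samples`` — each sample goes to the factor with the maximal
  coefficient (ties to the lowest factor index).

Companion analyses: pairwise Spearman co-occurrence of subtype abundances
with Benjamini-Hochberg control, and 'ward.D' hierarchical clustering of
samples on Euclidean composition distances (the classic Lance-Williams
Ward update applied to the distances as given, matching R's hclust
ward.D rather than ward.D2).

:class:`EcotypeModel` bundles the workflow statsmodels-style: build from a
composition matrix, call ``fit()``, inspect the returned
:class:`EcotypeResults` (estimates, stability survey, assignments,
``summary()``).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from ._seeds import child_seed, iter_seed
from .composition import CompositionMatrix
from .errors import ValidationError

__all__ = [
    "AbundanceMatrix",
    "CooccurrenceNetwork",
    "DendrogramResult",
    "EcotypeModel",
    "EcotypeResults",
    "minmax_normalize",
    "correlate_abundances",
    "cluster_samples_ward",
    "nmf_brunet",
    "select_rank",
    "extract_features",
    "assign_samples",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# abundance normalization


@dataclass
class AbundanceMatrix:
    """Subtypes x samples matrix after per-subtype min-max normalization."""

    values: pd.DataFrame
    dropped_subtypes: list[str]


def _comp_values(comp: CompositionMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(comp, CompositionMatrix):
        return comp.values
    return comp


def minmax_normalize(comp: CompositionMatrix | pd.DataFrame) -> AbundanceMatrix:
    """Scale each subtype to [0, 1] across samples; drop zero-variance ones.

    Input is samples x subtypes (a composition matrix); output is the
    transposed subtypes x samples abundance matrix ready for NMF.
    """
    values = _comp_values(comp)
    if values.shape[0] < 2:
        raise ValidationError("min-max normalization requires >= 2 samples")
    V = values.T  # subtypes x samples
    rng_ = V.max(axis=1) - V.min(axis=1)
    dropped = V.index[rng_ <= 0].tolist()
    kept = V.loc[rng_ > 0]
    if kept.empty:
        raise ValidationError("all subtypes have zero variance across samples")
    normed = kept.sub(kept.min(axis=1), axis=0).div(
        kept.max(axis=1) - kept.min(axis=1), axis=0
    )
    return AbundanceMatrix(values=normed, dropped_subtypes=dropped)


# ---------------------------------------------------------------------------
# co-occurrence network


@dataclass
class CooccurrenceNetwork:
    """Pairwise Spearman co-occurrence of subtype abundances."""

    rho: pd.DataFrame
    p_adj: pd.DataFrame
    alpha: float = 0.05

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Unordered subtype pairs with adjusted p <= alpha."""
        cols = self.p_adj.columns
        out = []
        for i, j in itertools.combinations(range(len(cols)), 2):
            p = self.p_adj.iat[i, j]
            if np.isfinite(p) and p <= self.alpha:
                out.append((cols[i], cols[j]))
        return out


@lru_cache(maxsize=4)
def _rank_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    n = rx.size
    perms = _rank_permutations(n)
    rxc = rx - rx.mean()
    ryp = ry[perms]
    rypc = ryp - ryp.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(rypc, axis=1) * np.linalg.norm(rxc)
    with np.errstate(invalid="ignore"):
        rhos = rypc @ rxc / denom
    obs = abs(float(rhos[0]))  # identity permutation is first
    return float(np.mean(np.abs(rhos) >= obs - 1e-12))


def correlate_abundances(
    comp: CompositionMatrix | pd.DataFrame, alpha: float = 0.05
) -> CooccurrenceNetwork:
    """Spearman correlation of every subtype pair across samples, with BH.

    Two-sided p-values use the large-sample t approximation, except for
    n <= 9 samples where the exact permutation distribution is enumerated.
    Constant subtypes yield missing correlations for all their pairs.
    """
    values = _comp_values(comp)
    n, m = values.shape
    if n < 3:
        raise ValidationError("co-occurrence requires >= 3 samples")
    X = values.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    constant = X.std(axis=0) == 0
    rho = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    praw = np.full((m, m), np.nan)
    exact = n <= 9
    for i, j in itertools.combinations(range(m), 2):
        r = rho[i, j]
        if not np.isfinite(r):
            continue
        if exact:
            p = _spearman_exact_p(ranks[:, i], ranks[:, j])
        elif abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
        praw[i, j] = praw[j, i] = p
    iu = np.triu_indices(m, k=1)
    flat = praw[iu]
    ok = np.isfinite(flat)
    padj = np.full_like(flat, np.nan)
    if ok.any():
        padj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    P = np.full((m, m), np.nan)
    P[iu] = padj
    P.T[iu] = padj
    cols = values.columns
    return CooccurrenceNetwork(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p_adj=pd.DataFrame(P, index=cols, columns=cols),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ward.D hierarchical clustering


@dataclass
class DendrogramResult:
    """Ward linkage over samples with a convenience cut."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: pd.Index

    def cut(self, n_clusters: int) -> pd.Series:
        if n_clusters > len(self.labels):
            raise ValidationError(
                f"n_clusters={n_clusters} exceeds the {len(self.labels)} samples"
            )
        lab = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(lab, index=self.labels, name="cluster")


def _ward_d_linkage(D: np.ndarray) -> np.ndarray:
    """Classic 'ward.D' agglomeration on a dissimilarity matrix.

    Applies the Lance-Williams Ward update directly to the supplied
    dissimilarities (R hclust 'ward.D' semantics; scipy's 'ward' is
    'ward.D2'). Ties break toward the lexicographically smallest pair of
    cluster ids, so the result is deterministic given input order. The
    update coefficients sum to 1, so merge heights are non-decreasing.
    """
    n = D.shape[0]
    d = D.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    size = np.ones(n)
    cid = np.arange(n)  # linkage id of the cluster currently in row i
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = np.where(active)[0]
        dsub = d[np.ix_(sub, sub)]
        flat = np.argmin(dsub)
        i_, j_ = np.unravel_index(flat, dsub.shape)
        u, v = sub[min(i_, j_)], sub[max(i_, j_)]
        if cid[u] > cid[v]:
            u, v = v, u
        h = d[u, v]
        nu, nv = size[u], size[v]
        for k in sub:
            if k == u or k == v:
                continue
            nk = size[k]
            d_new = (
                (nu + nk) * d[u, k] + (nv + nk) * d[v, k] - nk * h
            ) / (nu + nv + nk)
            d[u, k] = d[k, u] = d_new
        Z[step] = (min(cid[u], cid[v]), max(cid[u], cid[v]), h, nu + nv)
        size[u] = nu + nv
        cid[u] = n + step
        active[v] = False
        d[v, :] = np.inf
        d[:, v] = np.inf
    return Z


def cluster_samples_ward(
    comp: CompositionMatrix | pd.DataFrame, n_clusters: int | None = None
) -> DendrogramResult | tuple[DendrogramResult, pd.Series]:
    """Hierarchical 'ward.D' clustering of samples on Euclidean distances.

    Returns the dendrogram; when ``n_clusters`` is given, also the labels
    of the cut at that many clusters.
    """
    values = _comp_values(comp)
    if values.shape[0] < 2:
        raise ValidationError("clustering requires >= 2 samples")
    if n_clusters is not None and n_clusters > values.shape[0]:
        raise ValidationError(
            f"n_clusters={n_clusters} exceeds the {values.shape[0]} samples"
        )
    D = squareform(pdist(values.to_numpy(dtype=float), metric="euclidean"))
    Z = _ward_d_linkage(D)
    result = DendrogramResult(linkage=Z, labels=values.index)
    if n_clusters is None:
        return result
    return result, result.cut(n_clusters)


# ---------------------------------------------------------------------------
# Brunet NMF


def _gkl(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) with 0*log0 := 0."""
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / WH[mask])
    return float(term.sum() - V.sum() + WH.sum())


def nmf_brunet(
    V: AbundanceMatrix | pd.DataFrame | np.ndarray,
    k: int,
    n_iter: int = 500,
    seed: int = 0,
    tol: float = 1e-9,
    patience: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """KL-divergence NMF with Brunet multiplicative updates.

    Factorizes the non-negative matrix V (features x samples) as W @ H,
    minimizing the generalized Kullback-Leibler divergence. The update
    factors are normalized by the column sums of W (for H) and the row
    sums of H (for W), which keeps the objective non-increasing. W and H
    are initialized i.i.d. uniform(0, max(V)) from ``seed``. Iteration
    stops early when the relative objective change stays below ``tol``
    for ``patience`` consecutive iterations, capped at ``n_iter``.

    Returns ``(W, H, objective_trace)``; the trace includes the initial
    objective, so it has at most ``n_iter + 1`` entries.
    """
    if isinstance(V, AbundanceMatrix):
        V = V.values
    A = np.asarray(V, dtype=float)
    if A.ndim != 2:
        raise ValidationError("V must be 2-D")
    if (A < 0).any():
        raise ValidationError("V has negative entries")
    if not (1 <= k <= min(A.shape)):
        raise ValidationError(f"rank k={k} must be in 1..{min(A.shape)}")
    n, m = A.shape
    rng = np.random.default_rng(seed)
    vmax = A.max() or 1.0
    W = np.maximum(rng.uniform(0, vmax, size=(n, k)), _EPS)
    H = np.maximum(rng.uniform(0, vmax, size=(k, m)), _EPS)
    trace = [(_gkl(A, W @ H))]
    still = 0
    for _ in range(n_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (A / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        H = np.maximum(H, _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((A / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        W = np.maximum(W, _EPS)
        obj = _gkl(A, W @ H)
        prev = trace[-1]
        trace.append(obj)
        rel = abs(prev - obj) / max(abs(prev), _EPS)
        still = still + 1 if rel < tol else 0
        if still >= patience:
            break
    return W, H, np.asarray(trace)


# ---------------------------------------------------------------------------
# consensus rank selection


def _connectivity(H: np.ndarray) -> np.ndarray:
    a = np.argmax(H, axis=0)
    return (a[:, None] == a[None, :]).astype(float)


def _cophenetic(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the (1 - consensus) dissimilarities."""
    D = 1.0 - consensus
    cond = squareform(D, checks=False)
    if np.ptp(cond) == 0:
        # perfectly flat consensus: trivially stable
        return 1.0
    Z = sch.linkage(cond, method="average")
    c, _ = sch.cophenet(Z, cond)
    return float(c)


def select_rank(
    V: AbundanceMatrix | pd.DataFrame | np.ndarray,
    ranks: range | list[int] = range(2, 11),
    runs_per_rank: int = 100,
    seed: int = 0,
    n_iter: int = 200,
) -> tuple[int, pd.Series, dict[int, np.ndarray]]:
    """Survey factorization ranks by consensus-clustering stability.

    For each rank, ``runs_per_rank`` NMF runs from distinct seeded
    initializations are summarized by the mean sample co-assignment
    (connectivity) matrix; the cophenetic correlation of the resulting
    consensus dissimilarities scores the rank. Returns
    ``(recommended_rank, survey, consensus_by_rank)`` where the
    recommendation is the argmax cophenetic coefficient with ties broken
    toward the smaller rank.
    """
    if isinstance(V, AbundanceMatrix):
        V = V.values
    A = np.asarray(V, dtype=float)
    ranks = list(ranks)
    if runs_per_rank < 2:
        raise ValidationError("runs_per_rank must be >= 2 for a stability estimate")
    if any(r < 2 for r in ranks):
        raise ValidationError("ranks below 2 have no defined stability; use ranks >= 2")
    if max(ranks) > min(A.shape):
        raise ValidationError(
            f"max rank {max(ranks)} exceeds min dimension {min(A.shape)}"
        )
    survey = {}
    consensus_by_rank: dict[int, np.ndarray] = {}
    for r in ranks:
        acc = np.zeros((A.shape[1], A.shape[1]))
        for run in range(runs_per_rank):
            s = iter_seed(seed, f"nmf-rank{r}", run)
            _, H, _ = nmf_brunet(A, r, n_iter=n_iter, seed=s)
            acc += _connectivity(H)
        consensus = acc / runs_per_rank
        consensus_by_rank[r] = consensus
        survey[r] = _cophenetic(consensus)
    survey_s = pd.Series(survey, name="cophenetic").sort_index()
    best = max(survey_s.index, key=lambda r: (survey_s[r], -r))
    return int(best), survey_s, consensus_by_rank


# ---------------------------------------------------------------------------
# feature extraction & sample assignment


def extract_features(
    W: pd.DataFrame | np.ndarray, subtype_names=None
) -> tuple[dict[int, list[str]], pd.Series]:
    """Representative subtypes per factor via the basis-specificity score.

    Each subtype row of W is normalized to p_f = W[s,f]/sum_f W[s,f] and
    scored 1 + (1/log2 k) sum_f p_f log2 p_f, which is 1 for a
    factor-specific row and 0 for a uniform one. Subtypes with score above
    median + 3*MAD (raw MAD) are representative of their argmax factor.
    When the scores are exactly tied (MAD 0, e.g. a block-diagonal W) the
    threshold degenerates to the median, with positive specificity still
    required, so uniform rows are never selected. All-zero rows are
    excluded. Factors may end up with empty lists (warned).

    Returns ``(features, scores)`` with 1-based factor keys.
    """
    if isinstance(W, pd.DataFrame):
        subtype_names = W.index
        Wv = W.to_numpy(dtype=float)
    else:
        Wv = np.asarray(W, dtype=float)
        if subtype_names is None:
            subtype_names = pd.Index([f"row{i}" for i in range(Wv.shape[0])])
    n, k = Wv.shape
    if k < 2:
        raise ValidationError("feature extraction requires >= 2 factors")
    rowsum = Wv.sum(axis=1)
    nonzero = rowsum > 0
    P = np.zeros_like(Wv)
    P[nonzero] = Wv[nonzero] / rowsum[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    score = 1.0 + plogp.sum(axis=1) / np.log2(k)
    scores = pd.Series(score, index=pd.Index(subtype_names), name="score")
    valid = scores[nonzero]
    med = float(valid.median())
    mad = float((valid - med).abs().median())
    if mad > 0:
        selected = valid.index[(valid > med + 3 * mad).to_numpy()]
    else:
        selected = valid.index[((valid >= med) & (valid > 0)).to_numpy()]
    argmax = pd.Series(np.argmax(Wv, axis=1) + 1, index=scores.index)
    features: dict[int, list[str]] = {f: [] for f in range(1, k + 1)}
    for s in selected:
        features[int(argmax[s])].append(s)
    empty = [f for f, lst in features.items() if not lst]
    if empty:
        warnings.warn(f"factor(s) {empty} have no representative subtypes", stacklevel=2)
    return features, scores


def assign_samples(H: pd.DataFrame | np.ndarray, sample_names=None) -> pd.Series:
    """Assign each sample to its argmax factor (1-based).

    Ties break toward the lowest factor index; an all-zero column is
    unassigned (label 0) with a warning.
    """
    if isinstance(H, pd.DataFrame):
        sample_names = H.columns
        Hv = H.to_numpy(dtype=float)
    else:
        Hv = np.asarray(H, dtype=float)
        if sample_names is None:
            sample_names = pd.Index([f"s{i}" for i in range(Hv.shape[1])])
    if (Hv < 0).any():
        raise ValidationError("H has negative entries")
    lab = np.argmax(Hv, axis=0) + 1  # np.argmax already takes the first maximum
    zero = Hv.sum(axis=0) == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) have all-zero coefficients; unassigned",
            stacklevel=2,
        )
        lab = np.where(zero, 0, lab)
    return pd.Series(lab, index=pd.Index(sample_names), name="factor")


# ---------------------------------------------------------------------------
# model / results


class EcotypeModel:
    """Consensus-NMF ecotype discovery on a composition matrix.

    Parameters
    ----------
    comp
        A :class:`~ecokit.composition.CompositionMatrix` or a samples x
        subclusters DataFrame of relative abundances.
    ranks, runs_per_rank
        The stability survey grid (default ranks 2-10, 100 runs per rank).

    ``fit()`` min-max-normalizes the abundances, surveys the ranks, fits
    the final factorization at the selected (or forced) rank, extracts
    representative subtypes per factor and assigns samples; it also runs
    the companion 'ward.D' hierarchical clustering cut at the same rank,
    reporting both partitions and their cross-tabulation without merging
    them.
    """

    def __init__(
        self,
        comp: CompositionMatrix | pd.DataFrame,
        ranks: range | list[int] = range(2, 11),
        runs_per_rank: int = 100,
    ):
        self.comp = comp
        self.ranks = list(ranks)
        self.runs_per_rank = runs_per_rank
        self.abundance = minmax_normalize(comp)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EcotypeModel":
        return cls(df, **kwargs)

    def fit(
        self,
        rank: int | None = None,
        n_iter: int = 500,
        survey_iter: int = 200,
        n_init: int = 10,
        seed: int = 0,
    ) -> "EcotypeResults":
        A = self.abundance.values
        best, survey, consensus = select_rank(
            A,
            ranks=self.ranks,
            runs_per_rank=self.runs_per_rank,
            seed=child_seed(seed, "rank-survey"),
            n_iter=survey_iter,
        )
        k = int(rank) if rank is not None else best
        # multiplicative updates are init-sensitive: keep the best of
        # n_init seeded runs by final KL objective (ties -> first seed)
        W = H = trace = None
        for run in range(max(1, n_init)):
            Wr, Hr, tr = nmf_brunet(
                A, k, n_iter=n_iter, seed=iter_seed(seed, "final-nmf", run)
            )
            if trace is None or tr[-1] < trace[-1]:
                W, H, trace = Wr, Hr, tr
        Wdf = pd.DataFrame(
            W, index=A.index, columns=[f"F{f}" for f in range(1, k + 1)]
        )
        Hdf = pd.DataFrame(
            H, index=[f"F{f}" for f in range(1, k + 1)], columns=A.columns
        )
        features, scores = extract_features(Wdf.to_numpy(), subtype_names=A.index)
        assignment = assign_samples(Hdf.to_numpy(), sample_names=A.columns)
        dendro = cluster_samples_ward(_comp_values(self.comp))
        ward_labels = dendro.cut(k)
        return EcotypeResults(
            model=self,
            k=k,
            recommended_rank=best,
            rank_survey=survey,
            consensus=consensus,
            W=Wdf,
            H=Hdf,
            objective_trace=trace,
            features=features,
            feature_scores=scores,
            assignment=assignment,
            dendrogram=dendro,
            ward_labels=ward_labels,
        )


@dataclass
class EcotypeResults:
    """Fitted ecotype model: factors, stability survey and assignments."""

    model: EcotypeModel = field(repr=False)
    k: int
    recommended_rank: int
    rank_survey: pd.Series
    consensus: dict[int, np.ndarray] = field(repr=False)
    W: pd.DataFrame = field(repr=False)
    H: pd.DataFrame = field(repr=False)
    objective_trace: np.ndarray = field(repr=False)
    features: dict[int, list[str]]
    feature_scores: pd.Series = field(repr=False)
    assignment: pd.Series
    dendrogram: DendrogramResult = field(repr=False)
    ward_labels: pd.Series

    def crosstab(self) -> pd.DataFrame:
        """NMF factor assignment vs Ward cluster cross-tabulation."""
        return pd.crosstab(self.assignment, self.ward_labels)

    def summary(self) -> str:
        lines = [
            "Ecotype discovery (consensus NMF, KL/brunet)",
            "=" * 52,
            f"samples: {self.H.shape[1]}   subtypes: {self.W.shape[0]}"
            f"   dropped (zero variance): {len(self.model.abundance.dropped_subtypes)}",
            f"rank survey (cophenetic): "
            + ", ".join(f"k={r}: {c:.3f}" for r, c in self.rank_survey.items()),
            f"recommended rank: {self.recommended_rank}   fitted rank: {self.k}",
            f"final KL objective: {self.objective_trace[-1]:.6g} "
            f"({len(self.objective_trace) - 1} iterations)",
            "",
            "factor sizes and representative subtypes:",
        ]
        sizes = self.assignment.value_counts().sort_index()
        for f in range(1, self.k + 1):
            reps = ", ".join(self.features.get(f, [])) or "(none)"
            lines.append(f"  F{f}: {int(sizes.get(f, 0))} samples | {reps}")
        lines += ["", "NMF vs ward.D cross-tabulation:", str(self.crosstab())]
        return "\n".join(lines)
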