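"""Marker derivation, binned-control scoring and random-effects pooling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.stats.meta_analysis as smm
from scipy import stats

from ecokit import (
    SignatureSet,
    SimulationConfig,
    ValidationError,
    derive_group_signatures,
    ecotype_score,
    log_odds_from_scores,
    meta_random_effects,
    module_score,
    rank_markers,
    signature_top_k,
    simulate_dataset,
)


def _labels(cells):
    return pd.Series(cells["subcluster"].to_numpy(), index=cells["cell_id"].to_numpy())


# ---------------------------------------------------------------------------
# markers


def test_planted_markers_recovered(small_dataset):
    expr = small_dataset.expression
    markers = rank_markers(expr, _labels(small_dataset.cells))
    sigs = signature_top_k(markers, k=50, p_filter=1e-4)
    recalls = []
    for sub, truth in small_dataset.truth_markers.items():
        got = set(sigs[sub][: len(truth)])
        recalls.append(len(got & set(truth)) / len(truth))
    assert np.mean(recalls) >= 0.9


def test_null_pvalues_approximately_uniform():
    rng = np.random.default_rng(0)
    n_genes, n_cells = 500, 60
    expr = pd.DataFrame(
        rng.exponential(size=(n_genes, n_cells)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"c{i}" for i in range(n_cells)],
    )
    labels = pd.Series(
        rng.permutation(["A"] * 30 + ["B"] * 30), index=expr.columns
    )
    markers = rank_markers(expr, labels)
    pa = markers.loc[markers["cluster"] == "A", "p_raw"].to_numpy()
    ks = stats.kstest(pa, "uniform").statistic
    assert ks < 0.05


def test_bonferroni_is_p_times_family_size():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(
        rng.exponential(size=(20, 30)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"c{i}" for i in range(30)],
    )
    labels = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=expr.columns)
    markers = rank_markers(expr, labels)
    m = 20 * 3
    assert np.allclose(
        markers["p_adj"], np.minimum(1.0, markers["p_raw"] * m)
    )
    assert (markers["p_adj"] >= markers["p_raw"]).all()


def test_tiny_cluster_skipped_with_warning():
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(
        rng.exponential(size=(10, 23)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"c{i}" for i in range(23)],
    )
    labels = pd.Series(["A"] * 10 + ["B"] * 11 + ["tiny"] * 2, index=expr.columns)
    with pytest.warns(UserWarning, match="tiny"):
        markers = rank_markers(expr, labels)
    assert set(markers["cluster"]) == {"A", "B"}


# ---------------------------------------------------------------------------
# top-k signatures


def _marker_table(rows):
    return pd.DataFrame(rows, columns=["gene", "cluster", "avg_log2FC", "p_raw",
                                       "p_adj"])


def test_top_k_truncation_and_order():
    rows = [(f"g{i:02d}", "A", float(60 - i), 1e-6, 1e-5) for i in range(60)]
    sigs = signature_top_k(_marker_table(rows), k=50, p_filter=0.05)
    assert len(sigs["A"]) == 50
    assert sigs["A"][0] == "g00"  # highest fold change first
    short = signature_top_k(_marker_table(rows[:12]), k=20, p_filter=0.05)
    assert len(short["A"]) == 12


def test_top_k_tie_breaks_lexicographically():
    rows = [
        ("zzz", "A", 2.0, 1e-6, 1e-5),
        ("aaa", "A", 2.0, 1e-6, 1e-5),
        ("mmm", "A", 3.0, 1e-6, 1e-5),
    ]
    sigs = signature_top_k(_marker_table(rows), k=2, p_filter=0.05)
    assert sigs["A"] == ["mmm", "aaa"]


def test_top_k_monotone_in_p_filter():
    rng = np.random.default_rng(3)
    rows = [
        (f"g{i}", "A", float(rng.normal()), p, p * 10)
        for i, p in enumerate(rng.uniform(1e-8, 0.2, size=50))
    ]
    table = _marker_table(rows)
    loose = signature_top_k(table, k=50, p_filter=0.5)
    tight = signature_top_k(table, k=50, p_filter=1e-3)
    assert set(tight["A"]) <= set(loose["A"])


def test_empty_cluster_warns():
    rows = [("g1", "A", 1.0, 0.5, 1.0)]
    with pytest.warns(UserWarning, match="no gene"):
        sigs = signature_top_k(_marker_table(rows), k=5, p_filter=1e-4)
    assert sigs["A"] == []


# ---------------------------------------------------------------------------
# group signatures


def test_group_assignment_by_expression_preference():
    rows = [
        ("gH", "SC1", 3.0, 1e-9, 1e-7),
        ("gC", "SC2", 2.5, 1e-9, 1e-7),
        ("gTie", "SC1", 2.0, 1e-9, 1e-7),
    ]
    gm = pd.DataFrame(
        {"HS": [1.0, 0.2, 0.7], "CR": [0.3, 2.0, 0.7]},
        index=["gH", "gC", "gTie"],
    )
    sigs, flagged = derive_group_signatures(_marker_table(rows), gm, k=20,
                                            p_filter=1e-4)
    assert "gH" in sigs["HS"] and "gH" not in sigs["CR"]
    assert "gC" in sigs["CR"]
    assert "gTie" in sigs["HS"]  # tie goes to the first declared group
    assert flagged == ["gTie"]


def test_group_signatures_recover_planted_markers():
    cfg = SimulationConfig(
        n_groups=2, n_samples_per_group=4, n_subclusters=4, k_ecotypes=2,
        cells_per_sample=150, embed_dim=5, n_genes=120,
        n_markers_per_subcluster=6, marker_log_fold=4.0, seed=12,
    )
    ds = simulate_dataset(cfg)
    markers = rank_markers(ds.expression, _labels(ds.cells))
    group_of_cell = pd.Series(
        ds.cells["group"].to_numpy(), index=ds.cells["cell_id"].to_numpy()
    )
    gm = ds.expression.T.groupby(group_of_cell).mean().T
    sigs, _ = derive_group_signatures(markers, gm, k=6, p_filter=1e-4)
    pooled = {g for lst in sigs.sets.values() for g in lst}
    planted = {g for lst in ds.truth_markers.values() for g in lst}
    assert len(pooled & planted) / len(planted) >= 0.9


# ---------------------------------------------------------------------------
# module score


def test_constant_matrix_scores_exactly_zero():
    expr = pd.DataFrame(
        3.14, index=[f"g{i}" for i in range(200)], columns=["c1", "c2", "c3"]
    )
    s = module_score(expr, ["g3", "g77"], seed=0)
    assert (s == 0.0).all()


def test_random_set_mean_score_near_zero():
    rng = np.random.default_rng(5)
    n_genes = 400
    # heterogeneous expression levels across genes
    base = rng.exponential(scale=np.linspace(0.2, 3.0, n_genes)[:, None],
                           size=(n_genes, 80))
    expr = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"c{i}" for i in range(80)])
    means = []
    for seed in range(50):
        genes = list(rng.choice(expr.index, size=25, replace=False))
        means.append(module_score(expr, genes, seed=seed).mean())
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means)) < 2 * se + 0.01


def test_planted_set_scores_higher_in_its_subcluster(small_dataset):
    expr = small_dataset.expression
    cells = small_dataset.cells
    sub = "SC01"
    genes = small_dataset.truth_markers[sub]
    s = module_score(expr, genes, seed=1)
    in_mask = cells.set_index("cell_id")["subcluster"].eq(sub)
    assert s[in_mask].mean() > s[~in_mask].mean()


def test_module_score_determinism_and_errors(small_dataset):
    expr = small_dataset.expression
    genes = small_dataset.truth_markers["SC02"]
    a = module_score(expr, genes, seed=7)
    b = module_score(expr, genes, seed=7)
    pd.testing.assert_series_equal(a, b)
    with pytest.raises(ValidationError):
        module_score(expr, ["not_a_gene"], seed=0)
    with pytest.warns(UserWarning, match="absent"):
        module_score(expr, genes + ["not_a_gene"], seed=0)


def test_ecotype_score_ranks_enriched_spots():
    rng = np.random.default_rng(9)
    n_genes = 300
    genes = [f"g{i}" for i in range(n_genes)]
    expr = pd.DataFrame(
        rng.exponential(size=(n_genes, 30)), index=genes,
        columns=[f"spot{i}" for i in range(30)],
    )
    sig_genes = genes[:15]
    hot = [f"spot{i}" for i in range(5)]
    expr.loc[sig_genes, hot] += 2.0
    sigs = SignatureSet(sets={"eco4": sig_genes})
    scores = ecotype_score(expr, sigs, seed=2)
    top5 = set(scores["eco4"].nlargest(5).index)
    assert top5 == set(hot)
    again = ecotype_score(expr, sigs, seed=2)
    pd.testing.assert_frame_equal(scores, again)


def test_signature_set_json_roundtrip(tmp_path):
    sigs = SignatureSet(sets={"A": ["g1", "g2"], "B": ["g3"]}, meta={"k": 2})
    p = tmp_path / "sigs.json"
    sigs.to_json(p)
    back = SignatureSet.from_json(p)
    assert back.sets == sigs.sets and back.meta == sigs.meta


# ---------------------------------------------------------------------------
# meta-analysis


def _dl_oracle(theta, se):
    """Independent step-by-step evaluation of the DL formulas."""
    theta, se = np.asarray(theta, float), np.asarray(se, float)
    w = 1 / se**2
    fixed = (w * theta).sum() / w.sum()
    q = (w * (theta - fixed) ** 2).sum()
    n = len(theta)
    tau2 = max(0.0, (q - (n - 1)) / (w.sum() - (w**2).sum() / w.sum()))
    wr = 1 / (se**2 + tau2)
    pooled = (wr * theta).sum() / wr.sum()
    half = 1.96 / np.sqrt(wr.sum())
    return pooled, tau2, pooled - half, pooled + half


def test_three_study_toy_matches_formula_oracle():
    theta = [0.8, 0.2, 0.5]
    se = [0.2, 0.1, 0.3]
    res = meta_random_effects(theta, se)
    pooled, tau2, lo, hi = _dl_oracle(theta, se)
    assert res.pooled == pytest.approx(pooled, abs=1e-10)
    assert res.tau2 == pytest.approx(tau2, abs=1e-10)
    assert res.ci_low == pytest.approx(lo, abs=1e-10)
    assert res.ci_high == pytest.approx(hi, abs=1e-10)
    assert res.tau2 >= 0


def test_dl_matches_statsmodels():
    theta = np.array([0.5, 0.7, 0.3, 0.9])
    se = np.array([0.1, 0.2, 0.15, 0.25])
    res = meta_random_effects(theta, se)
    sm = smm.combine_effects(theta, se**2, method_re="dl")
    assert res.pooled == pytest.approx(float(sm.mean_effect_re), abs=1e-10)
    assert res.tau2 == pytest.approx(float(sm.tau2), abs=1e-10)


def test_single_study_degenerate():
    res = meta_random_effects([0.42], [0.1])
    assert res.pooled == 0.42
    assert res.tau2 == 0.0
    assert res.df == 0


def test_identical_estimates_zero_heterogeneity():
    res = meta_random_effects([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
    assert res.q == pytest.approx(0.0, abs=1e-12)
    assert res.tau2 == 0.0
    assert res.pooled == pytest.approx(0.3)
    # with tau2 = 0 the pooled estimate is a convex combination of the inputs
    assert 0.3 - 1e-12 <= res.pooled <= 0.3 + 1e-12


def test_meta_rejects_bad_se():
    with pytest.raises(ValidationError):
        meta_random_effects([0.1, 0.2], [0.1, 0.0])
    with pytest.raises(ValidationError):
        meta_random_effects([], [])


def test_log_odds_helper_is_finite_and_signed():
    rng = np.random.default_rng(3)
    scores = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
    groups = pd.Series(["CR"] * 20 + ["HS"] * 20, index=scores.index)
    scores[groups == "CR"] += 2.0  # CR samples score higher
    est, se = log_odds_from_scores(scores, groups, positive_group="CR")
    assert np.isfinite(est) and np.isfinite(se) and se > 0
    assert est > 0

    def summary_smoke():
        return meta_random_effects([est], [se]).summary()

    assert "pooled effect" in summary_smoke()
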