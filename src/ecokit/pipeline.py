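"""End-to-end pipeline runner with a reproducibility manifest.

A single YAML/dict configuration drives: synthetic data generation (or
loading of user files) -> composition -> Ro/e -> divergence screen ->
co-occurrence network -> consensus-NMF ecotype discovery -> marker /
signature derivation -> per-cell signature scoring -> random-effects
meta-analysis of per-pseudo-dataset score contrasts. Every stage derives
its seed from the global seed, all outputs are TSV/JSON, and a manifest
records parameters, seeds, timings and output checksums so that two runs
with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import child_seed
from .composition import build_composition, compute_roe
from .divergence import DivergenceConfig, divergence_screen
from .ecotypes import EcotypeModel, correlate_abundances
from .errors import ValidationError
from .io import read_cell_table, read_matrix
from .signatures import (
    derive_group_signatures,
    log_odds_from_scores,
    meta_random_effects,
    module_score,
    rank_markers,
    signature_top_k,
)
from .synthetic import SimulationConfig, simulate_dataset, write_dataset

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """A small self-contained demo configuration (synthetic inputs)."""
    return {
        "seed": 7,
        "simulate": {
            "n_groups": 2,
            "n_samples_per_group": 15,
            "n_subclusters": 9,
            "k_ecotypes": 3,
            "cells_per_sample": 300,
            "embed_dim": 10,
            "shift_magnitude": 2.0,
            "remodeled_subclusters": [1],
            "n_genes": 300,
            "n_markers_per_subcluster": 8,
            "marker_log_fold": 3.0,
        },
        "composition": {"level": "subcluster", "denominator": "all"},
        "divergence": {
            "n_iterations": 30,
            "subsample_size": 40,
            "min_cells_per_group": 200,
        },
        "ecotype": {"ranks": [2, 6], "runs_per_rank": 30, "final_iters": 500},
        "signatures": {
            "top_k": 50,
            "p_filter": 0.05,
            "group_k": 20,
            "group_p": 1e-4,
            "bins": 24,
            "controls": 100,
        },
        "meta": {"n_pseudo_datasets": 3},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Raises before any stage runs if a referenced input path is missing.
    Stage failures abort with a message naming the stage.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    # pre-flight: every referenced input must exist
    for key, p in (cfg.get("inputs") or {}).items():
        if not Path(p).exists():
            raise ValidationError(f"input file for {key!r} does not exist: {p}")

    manifest: dict = {"config": cfg, "seed": seed, "stages": {}, "outputs": {}}
    t_all = time.perf_counter()

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t, 3)
                }
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Ctx()

    # --- inputs -----------------------------------------------------------
    with _stage("simulate"):
        if "simulate" in cfg:
            sim_cfg = SimulationConfig(
                seed=child_seed(seed, "simulate"),
                **{
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in cfg["simulate"].items()
                },
            )
            dataset = simulate_dataset(sim_cfg)
            paths = write_dataset(dataset, out / "data")
            manifest["outputs"].update({k: str(v) for k, v in paths.items()})
            cells, emb, expr = dataset.cells, dataset.embeddings, dataset.expression
        else:
            inputs = cfg["inputs"]
            cells = read_cell_table(inputs["cells"])
            emb = read_matrix(inputs["embeddings"])
            expr = read_matrix(inputs["expression"], kind=inputs.get(
                "expression_kind", "dense_tsv"))

    groups = sorted(cells["group"].unique())

    # --- composition & Ro/e ----------------------------------------------
    with _stage("composition"):
        comp_cfg = cfg.get("composition", {})
        comp = build_composition(
            cells,
            level=comp_cfg.get("level", "subcluster"),
            denominator_rule=comp_cfg.get("denominator", "all"),
        )
        comp.values.to_csv(out / "composition.tsv", sep="\t")

    with _stage("roe"):
        roe = compute_roe(cells, cluster_level=comp_cfg.get("level", "subcluster"))
        roe.values.to_csv(out / "roe.tsv", sep="\t")

    # --- divergence -------------------------------------------------------
    with _stage("diverge"):
        div_cfg = cfg.get("divergence", {})
        dcfg = DivergenceConfig(
            n_iterations=div_cfg.get("n_iterations", 100),
            subsample_size=div_cfg.get("subsample_size", 50),
            min_cells_per_group=div_cfg.get("min_cells_per_group", 200),
            seed=child_seed(seed, "diverge"),
        )
        ga, gb = div_cfg.get("groups", (groups[0], groups[-1]))
        results = divergence_screen(cells, emb, ga, gb, dcfg)
        frames = [r.to_frame() for r in results.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            out / "divergence.tsv", sep="\t", index=False
        )
        summary = pd.DataFrame(
            {
                "cluster": list(results),
                "excluded": [r.excluded for r in results.values()],
                "mean_difference": [
                    np.nan if r.excluded else r.mean_difference
                    for r in results.values()
                ],
            }
        )
        summary.to_csv(out / "divergence_summary.tsv", sep="\t", index=False)

    # --- co-occurrence ----------------------------------------------------
    with _stage("cooccur"):
        net = correlate_abundances(comp)
        net.rho.to_csv(out / "cooccurrence_rho.tsv", sep="\t")
        net.p_adj.to_csv(out / "cooccurrence_padj.tsv", sep="\t")

    # --- ecotypes ---------------------------------------------------------
    with _stage("ecotype"):
        eco_cfg = cfg.get("ecotype", {})
        lo, hi = eco_cfg.get("ranks", [2, 10])
        model = EcotypeModel(
            comp,
            ranks=range(lo, hi + 1),
            runs_per_rank=eco_cfg.get("runs_per_rank", 100),
        )
        eco = model.fit(
            rank=eco_cfg.get("rank"),
            n_iter=eco_cfg.get("final_iters", 500),
            seed=child_seed(seed, "ecotype"),
        )
        eco.rank_survey.to_csv(out / "rank_survey.tsv", sep="\t")
        eco.W.to_csv(out / "W.tsv", sep="\t")
        eco.H.to_csv(out / "H.tsv", sep="\t")
        eco.assignment.to_csv(out / "assignment.tsv", sep="\t")
        eco.ward_labels.to_csv(out / "ward_labels.tsv", sep="\t")
        pd.DataFrame(
            [(f, s) for f, lst in eco.features.items() for s in lst],
            columns=["factor", "subtype"],
        ).to_csv(out / "features.tsv", sep="\t", index=False)
        (out / "ecotype_summary.txt").write_text(eco.summary() + "\n")

    # --- signatures & scoring --------------------------------------------
    with _stage("signatures"):
        sig_cfg = cfg.get("signatures", {})
        labels = pd.Series(
            cells["subcluster"].to_numpy(), index=cells["cell_id"].to_numpy()
        )
        markers = rank_markers(expr, labels)
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        sigs = signature_top_k(
            markers, k=sig_cfg.get("top_k", 50), p_filter=sig_cfg.get("p_filter", 0.05)
        )
        sigs.to_json(out / "signatures.json")
        group_of_cell = pd.Series(
            cells["group"].to_numpy(), index=cells["cell_id"].to_numpy()
        )
        group_means = expr.T.groupby(group_of_cell).mean().T
        gsigs, _ = derive_group_signatures(
            markers,
            group_means,
            k=sig_cfg.get("group_k", 20),
            p_filter=sig_cfg.get("group_p", 1e-4),
        )
        gsigs.to_json(out / "group_signatures.json")

    with _stage("score"):
        target_group = groups[-1]
        genes = gsigs[target_group] or next(
            lst for lst in gsigs.sets.values() if lst
        )
        cell_scores = module_score(
            expr,
            genes,
            n_bins=sig_cfg.get("bins", 24),
            n_controls=sig_cfg.get("controls", 100),
            seed=child_seed(seed, "score"),
        )
        cell_scores.rename("score").to_csv(
            out / "cell_scores.tsv", sep="\t", index_label="cell_id"
        )
        sample_scores = cell_scores.groupby(
            pd.Series(cells["sample_id"].to_numpy(), index=cells["cell_id"].to_numpy())
        ).mean()
        sample_scores.rename("score").to_csv(
            out / "sample_scores.tsv", sep="\t", index_label="sample_id"
        )

    # --- meta-analysis ----------------------------------------------------
    with _stage("meta"):
        meta_cfg = cfg.get("meta", {})
        n_ds = int(meta_cfg.get("n_pseudo_datasets", 3))
        sample_group = (
            cells.drop_duplicates("sample_id").set_index("sample_id")["group"]
        ).loc[sample_scores.index]
        order = sample_scores.index.to_numpy()
        splits = np.array_split(np.arange(len(order)), n_ds)
        effects, ses, names = [], [], []
        for i, idx in enumerate(splits):
            sub = order[idx]
            est, se = log_odds_from_scores(
                sample_scores.loc[sub],
                sample_group.loc[sub],
                positive_group=meta_cfg.get("positive_group", target_group),
            )
            effects.append(est)
            ses.append(se)
            names.append(f"dataset{i + 1}")
        meta = meta_random_effects(effects, ses, names)
        meta.table.assign(pooled=meta.pooled, tau2=meta.tau2).to_csv(
            out / "meta.tsv", sep="\t"
        )
        (out / "meta_summary.txt").write_text(meta.summary() + "\n")

    # --- manifest ---------------------------------------------------------
    manifest["total_seconds"] = round(time.perf_counter() - t_all, 3)
    checksums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(out))] = _sha256(p)
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
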