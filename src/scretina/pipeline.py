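"""End-to-end orchestration: configuration, stage sequencing, reporting.

``run_pipeline`` executes filter -> normalize -> gene selection -> PCA ->
multiplet flagging -> clustering -> merging -> cluster profiles on a count
matrix (read from disk or freshly simulated), followed by the optional
analyses (density/divergence, developmental age, regional identity,
specificity), and writes per-stage tables plus a deterministic JSON
summary.  One global seed fans out to per-stage child seeds at fixed
offsets so toggling a stage never shifts another stage's randomness.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import density as dn
from . import dev_age as da
from . import multiplet as mp
from . import preprocess as pp
from . import simulate as sim
from . import specificity as spc
from .matrix import ExpressionMatrix, read_counts, write_counts_mtx

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "load_config"]

log = logging.getLogger("scretina")

# fixed per-stage seed offsets (stage toggles must not shift other stages)
_SEED_OFFSETS = {
    "simulate": 1, "filter": 2, "multiplet": 3, "cluster": 4,
    "bootstrap": 5, "density": 6, "dev_age": 7, "regional": 8,
    "specificity": 9,
}


@dataclass
class PipelineConfig:
    """All pipeline parameters with their standard defaults.

    Unknown keys in a config mapping are rejected.
    """

    # input: path to MTX triplet dir / dense TSV, or None to simulate
    counts: str | None = None
    seed: int = 0
    out_dir: str = "scretina_out"

    # simulation (used when counts is None)
    sim_cells_per_cluster: int = 150
    sim_n_genes: int = 300
    sim_doublet_rate: float = 0.05
    sim_damaged_fraction: float = 0.05

    # preprocessing
    low_pct: float = 0.05
    high_pct: float = 0.95
    pool_threshold: int = 400
    cov_alpha: float = 0.8
    cov_n_top: int = 1000
    mnr_threshold: float = 4.0
    dnr_threshold: float = 0.5
    n_components: int = 100

    # multiplet
    cluster_fraction: float = 0.15

    # clustering
    knn_k: int = 50
    theta_start: float = 0.99
    theta_floor: float = 0.90
    theta_step: float = 0.01
    bootstrap_iters: int = 50
    bootstrap_frac: float = 0.85

    # density
    density_eps: float = 0.01
    grid_range: float = 17.0

    # specificity
    perm_iters: int = 1000
    n_exceed_init: int = 250

    # stage toggles
    run_multiplet: bool = True
    run_clustering: bool = True
    run_bootstrap: bool = False
    run_density: bool = False
    run_specificity: bool = False
    specificity_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.run_specificity and not self.run_clustering:
            raise ValueError("specificity requires clustering to be enabled")

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 10_007 + _SEED_OFFSETS[stage]) % (2**31 - 1)


def load_config(path) -> PipelineConfig:
    """Read a YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage(name: str, t0: float) -> None:
    log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the JSON-ready summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": []}

    # ---- input ------------------------------------------------------
    t0 = time.perf_counter()
    if config.counts is None:
        cfg = sim.retina_like_config(
            n_genes=config.sim_n_genes,
            cells_per_cluster=config.sim_cells_per_cluster,
            doublet_rate=config.sim_doublet_rate,
            damaged_fraction=config.sim_damaged_fraction,
            seed=config.stage_seed("simulate"),
        )
        m, truth = sim.simulate_counts(cfg)
        sim.write_truth_csv(truth, out / "truth.csv")
        write_counts_mtx(m, out / "counts")
        summary["simulated"] = True
    else:
        m = read_counts(config.counts)
        truth = None
        summary["simulated"] = False
    summary["n_cells_input"] = m.n_cells
    summary["n_genes"] = m.n_genes
    summary["stages"].append("input")
    _stage("input", t0)

    # ---- filtering --------------------------------------------------
    t0 = time.perf_counter()
    high, low, diag = pp.filter_cells(
        m, config.low_pct, config.high_pct, config.pool_threshold)
    kept = high.append(low)
    pd.Series(high).to_csv(out / "cells_high_pool.txt", index=False, header=False)
    pd.Series(kept).to_csv(out / "cells_kept.txt", index=False, header=False)
    summary.update(
        n_cells_kept=len(kept), n_high_pool=len(high), n_low_pool=len(low),
        n_removed_genes_criterion=diag.n_removed_genes,
        n_removed_mito_criterion=diag.n_removed_mito,
    )
    summary["stages"].append("filter")
    _stage("filter", t0)

    # ---- normalization + gene selection + PCA ----------------------
    t0 = time.perf_counter()
    m_high = m.subset_cells(high)
    nm = pp.library_normalize(m_high, log=True)
    excluded = m_high.gene_ids[m_high.mito_mask | m_high.ribo_mask]
    cov = pp.select_genes(m_high, "cov", alpha=config.cov_alpha,
                          n_top=config.cov_n_top, exclude=excluded)
    mnr = pp.select_genes(m_high, "mnr", alpha=config.cov_alpha,
                          mnr_threshold=config.mnr_threshold, exclude=excluded)
    pd.DataFrame({
        "cov_score": cov.scores, "cov_selected": cov.scores.index.isin(cov.selected),
        "mnr_score": mnr.scores, "mnr_selected": mnr.scores.index.isin(mnr.selected),
    }).to_csv(out / "gene_scores.tsv", sep="\t")
    pca = pp.compute_pca(nm, genes=cov.selected,
                         n_components=config.n_components)
    pca.scores.round(6).to_csv(out / "pca_scores.tsv", sep="\t")
    summary["n_genes_cov_selected"] = len(cov.selected)
    summary["n_genes_mnr_selected"] = len(mnr.selected)
    summary["n_components"] = pca.scores.shape[1]
    summary["stages"].append("preprocess")
    _stage("preprocess", t0)

    # ---- clustering -------------------------------------------------
    clustering = None
    if config.run_clustering:
        t0 = time.perf_counter()
        graph = cl.build_knn_graph(pca.scores, k=min(config.knn_k, len(high) - 1),
                                   seed=config.stage_seed("cluster"))
        clustering = cl.infomap_partition(graph, seed=config.stage_seed("cluster"))
        summary["n_clusters_initial"] = clustering.n_clust
        merge_genes = mnr.selected if len(mnr.selected) else cov.selected
        clustering = cl.merge_similar_clusters(
            nm, clustering, merge_genes, config.theta_start,
            config.theta_floor, config.theta_step)
        clustering.labels.rename("cluster").to_csv(out / "clusters.csv")
        summary["n_clusters_merged"] = clustering.n_clust
        summary["cluster_sizes"] = {
            str(k): int(v) for k, v in clustering.sizes().items()}
        summary["stages"].append("cluster")
        _stage("cluster", t0)

    # ---- multiplets -------------------------------------------------
    if config.run_multiplet:
        t0 = time.perf_counter()
        flagger = mp.MarkerMultipletFlagger(
            cluster_fraction=config.cluster_fraction)
        flagger.fit(m_high)
        flags = flagger.predict(
            m_high, clustering.labels if clustering is not None else None)
        flags.to_csv(out / "multiplet_flags.csv")
        summary["n_flagged_multiplets"] = int(flags["flagged"].sum())
        summary["stages"].append("multiplet")
        _stage("multiplet", t0)

    # ---- cluster profiles -------------------------------------------
    profiles = None
    if clustering is not None:
        t0 = time.perf_counter()
        profiles = cl.cluster_profiles(m_high, pp.library_normalize(m_high), clustering)
        profiles.mu.round(6).to_csv(out / "cluster_mu.tsv", sep="\t")
        summary["clusters_present"] = {
            str(k): bool(v) for k, v in profiles.present.items()}
        summary["stages"].append("profiles")
        _stage("profiles", t0)

    # ---- optional: bootstrap quality --------------------------------
    if config.run_bootstrap and clustering is not None:
        t0 = time.perf_counter()
        quality = cl.bootstrap_quality(
            pca.scores, clustering, n_iter=config.bootstrap_iters,
            frac=config.bootstrap_frac, k=min(config.knn_k, len(high) - 1),
            seed=config.stage_seed("bootstrap"))
        pd.DataFrame({"purity": quality.purity,
                      "stability": quality.stability}).to_csv(
            out / "cluster_quality.csv")
        summary["mean_purity"] = round(float(quality.purity.mean()), 6)
        summary["mean_stability"] = round(float(quality.stability.mean()), 6)
        summary["stages"].append("bootstrap")
        _stage("bootstrap", t0)

    # ---- optional: density maps -------------------------------------
    if config.run_density and truth is not None and clustering is not None:
        t0 = time.perf_counter()
        cfg_emb = cfg  # simulation config from above
        truth_high = pd.Series(truth.cluster, index=truth.cell_ids).reindex(high)
        emb = sim.simulate_embedding(truth, cfg_emb)
        emb_high = emb.loc[high]
        est = dn.EmbeddingDensity(grid_range=config.grid_range,
                                  eps=config.density_eps).fit(emb_high)
        first = truth_high == truth_high.iloc[0]
        d_same = dn.js_divergence(est.subset_density(first.to_numpy()),
                                  est.subset_density(first.to_numpy()))
        d_diff = dn.js_divergence(est.subset_density(first.to_numpy()),
                                  est.subset_density((~first).to_numpy()))
        emb_high.round(6).to_csv(out / "embedding.tsv", sep="\t")
        summary["js_same_subset"] = round(d_same, 6)
        summary["js_disjoint_subsets"] = round(d_diff, 6)
        summary["stages"].append("density")
        _stage("density", t0)

    # ---- optional: specificity --------------------------------------
    if config.run_specificity and profiles is not None:
        t0 = time.perf_counter()
        keep = profiles.raw.columns[profiles.raw.sum(axis=0) > 0]
        counts = profiles.raw[keep]
        genes = config.specificity_genes or list(
            profiles.mu_hat.max(axis=0).nlargest(5).index)
        genes = [g for g in genes if g in counts.columns]
        rows = []
        for i, g in enumerate(genes):
            res = spc.permutation_pvalue(
                counts, gene=g, n_iter=config.perm_iters,
                n_exceed_init=config.n_exceed_init,
                seed=config.stage_seed("specificity") + i)
            rows.append({"gene": g, "spg": round(res.observed, 6),
                         "p": float(res.p_value), "method": res.method,
                         "cluster_of_max": str(profiles.mu_hat[g].idxmax())})
        pd.DataFrame(rows).to_csv(out / "specificity.tsv", sep="\t", index=False)
        summary["specificity"] = {
            r["gene"]: {"spg": r["spg"], "p": r["p"], "method": r["method"]}
            for r in rows}
        summary["stages"].append("specificity")
        _stage("specificity", t0)

    # ---- summary ----------------------------------------------------
    summary["parameters"] = {
        k: v for k, v in asdict(config).items()
        if not k.startswith("sim_") and k != "out_dir"}
    write_report(summary, out / "summary.json")
    return summary


def write_report(summary: dict, path) -> None:
    """Write the summary as deterministic (sorted, no-timestamp) JSON."""
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
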