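"""Pipeline orchestration: run the analysis stages in dependency order on a
synthetic dataset and leave TSV artifacts plus a reproducibility manifest."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import engram as eng
from . import io as eio
from . import modulecorr as mc
from . import qc, simulate, spatial, taxonomy
from .config import AnalysisConfig

log = logging.getLogger("engramap")

STAGE_ORDER = (
    "simulate",
    "qc",
    "cluster",
    "spatial",
    "engram",
    "corr",
    "photometry",
    "report",
)


def default_demo_design(seed: int = 0) -> simulate.SynthDesign:
    """Small end-to-end demo design with planted engrams and one module."""
    return simulate.SynthDesign(
        n_types_per_class={"GABA": 2, "VGLUT1": 2, "VGLUT2": 2, "non-neuronal": 0},
        cells_per_type_per_timepoint=40,
        n_genes=600,
        engram_spec=(
            simulate.EngramSpec("GABA-1", {"2h": 0.3, "24h": 0.3}, panel_fold=5.0),
        ),
        module_spec=(
            simulate.ModuleSpec(
                genes=tuple(f"Gene{k:05d}" for k in range(10)),
                loading=0.6,
                active_groups=tuple(
                    ("VGLUT1-1", tp) for tp in simulate.CFC_TIMEPOINTS
                ),
            ),
        ),
        seed=seed,
    )


def run_pipeline(
    cfg: AnalysisConfig,
    stages: tuple[str, ...] = STAGE_ORDER,
    design: simulate.SynthDesign | None = None,
) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Intermediates are cached in ``cfg.outdir``; a stage subset reuses cached
    upstream artifacts and fails with an actionable error if they are missing.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(s for s in STAGE_ORDER if s in stages)
    outputs: dict[str, Path] = {}
    state: dict = {}

    def _need(key: str, stage: str):
        if key not in state:
            raise RuntimeError(
                f"stage {stage!r} needs upstream artifact {key!r}; "
                f"run its producing stage first or include it in --stages"
            )
        return state[key]

    if "simulate" in stages:
        design = design or default_demo_design(cfg.seed)
        adata, truth = simulate.generate_counts(design)
        state["raw"], state["truth"], state["design"] = adata, truth, design
        eio.write_counts(adata, outdir / "counts")
        truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t")
        outputs["counts"] = outdir / "counts"
        log.info("simulate: %d cells x %d genes", *adata.shape)
    elif cfg.counts_path:
        state["raw"] = eio.read_counts(cfg.counts_path)

    if "qc" in stages:
        adata = _need("raw", "qc")
        keep = qc.filter_cells(adata, cfg.qc.min_umi_neurons, cfg.qc.min_genes_neurons)
        filtered = adata[keep].copy()
        filtered.uns["normalized"] = False
        state["norm"] = qc.normalize_cells(
            filtered, cfg.qc.normalization_scale, cfg.qc.norm
        )
        log.info("qc: retained %d / %d cells", len(keep), adata.n_obs)

    if "cluster" in stages:
        norm = _need("norm", "cluster")
        ranking = taxonomy.rank_features(
            norm,
            cfg.clustering.min_feature_cells,
            cfg.clustering.max_feature_cell_frac,
            excluded=cfg.excluded_genes(),
        )
        feats = taxonomy.selected_genes(ranking)
        X = np.asarray(norm[:, feats].X)
        proj, _ = taxonomy.pca_project(X, n_pcs=cfg.clustering.n_pcs, seed=cfg.seed)
        proj = taxonomy.correct_batches(proj, norm.obs["batch"].to_numpy())
        coords = taxonomy.embed_2d(
            proj,
            taxonomy.EmbeddingConfig(
                exaggeration=cfg.clustering.exaggeration,
                theta=cfg.clustering.theta,
                seed=cfg.seed,
            ),
        )
        cs = taxonomy.cluster_embedding(
            coords,
            eps=cfg.clustering.dbscan_eps,
            min_pts=cfg.clustering.dbscan_min_pts,
            index=norm.obs_names,
        )
        labels = taxonomy.merge_similar_clusters(
            norm, cs.labels, cfg.clustering.merge_similarity_threshold,
            tuple(cfg.clustering.merge_pairs), features=feats,
        )
        assignment = qc.assign_classes(norm, labels)
        qc.call_doublet_clusters(assignment, cfg.qc.doublet_ratio_threshold)
        state.update(
            {"labels": labels, "coords": coords, "features": feats, "classes": assignment}
        )
        pd.DataFrame(
            {"cluster": labels, "tsne1": coords[:, 0], "tsne2": coords[:, 1]}
        ).to_csv(outdir / "clusters.tsv", sep="\t")
        if len(set(labels) - {-1}) >= 2:
            dendro = taxonomy.build_dendrogram(norm, labels, seed=cfg.seed)
            (outdir / "dendrogram.nwk").write_text(dendro.to_newick())
            markers = taxonomy.branch_markers(norm, dendro, labels)
            markers.to_csv(outdir / "branch_markers.tsv", sep="\t", index=False)
            state["dendrogram"] = dendro
        outputs["clusters"] = outdir / "clusters.tsv"
        log.info("cluster: %d clusters", len(set(labels) - {-1}))

    if "spatial" in stages:
        norm, labels = _need("norm", "spatial"), _need("labels", "spatial")
        design = state.get("design") or default_demo_design(cfg.seed)
        target, _truth = simulate.generate_spatial(design)
        means = _cluster_means(norm, labels)
        feats = spatial.shared_features(norm, target, excluded=cfg.excluded_genes())
        sc = spatial.correlate_profiles(means, target, feats)
        summary = spatial.regionwise_summary(sc, target.regions)
        sc.rho.to_csv(outdir / "spatial_rho.tsv", sep="\t")
        summary.to_csv(outdir / "spatial_regions.tsv", sep="\t")
        outputs["spatial"] = outdir / "spatial_rho.tsv"

    if "engram" in stages:
        norm, labels = _need("norm", "engram"), _need("labels", "engram")
        th = eng.activation_thresholds(
            norm, tuple(cfg.engram.panel), cfg.engram.score_percentile
        )
        flags = eng.flag_active(norm, th)
        tables = eng.activation_tables(
            flags,
            labels,
            norm.obs["timepoint"],
            min_cells=cfg.engram.min_cluster_cells,
            min_per_group=cfg.engram.min_group_cells,
        )
        state["activation"] = tables
        out = tables.S.copy()
        out["ieg_score"] = tables.score
        out["low_confidence"] = tables.low_confidence
        out.to_csv(outdir / "ieg_scores.tsv", sep="\t")
        outputs["ieg_scores"] = outdir / "ieg_scores.tsv"

    if "corr" in stages:
        norm, labels = _need("norm", "corr"), _need("labels", "corr")
        genes, ok = mc.eligibility(
            norm,
            norm.obs_names,
            labels,
            norm.obs["timepoint"],
            cfg.modulecorr.min_gene_cells,
            cfg.modulecorr.min_cluster_per_tp,
        )
        all_tables = []
        for name, mod_genes in cfg.modulecorr.modules.items():
            usable = [g for g in mod_genes if g in genes]
            if len(usable) < 3:
                continue
            tbl = mc.score_table(
                norm, usable, labels, norm.obs["timepoint"], norm.obs["batch"], ok
            )
            if len(tbl):
                tbl.insert(0, "module", name)
                all_tables.append(tbl)
        if all_tables:
            scores = pd.concat(all_tables)
            scores.to_csv(outdir / "module_scores.tsv", sep="\t")
            outputs["module_scores"] = outdir / "module_scores.tsv"
            state["module_scores"] = scores

    if "photometry" in stages:
        from . import photometry as ph

        trace, events = simulate.generate_photometry(seed=cfg.seed)
        dff = ph.detrend(trace)
        resp = ph.event_zscore(dff, trace.time, events)
        ph.response_table(resp).to_csv(outdir / "photometry_z.tsv", sep="\t")
        outputs["photometry"] = outdir / "photometry_z.tsv"

    if "report" in stages:
        lines = [f"stages run: {', '.join(stages)}"]
        if "labels" in state:
            lines.append(f"clusters: {len(set(state['labels']) - {-1})}")
        if "activation" in state:
            top = state["activation"].score.dropna().sort_values(ascending=False)
            lines.append("top IEG scores: " + ", ".join(f"{c}={v:.3f}" for c, v in top.head(5).items()))
        (outdir / "report.txt").write_text("\n".join(lines) + "\n")
        outputs["report"] = outdir / "report.txt"

    manifest = eio.write_manifest(
        outdir / "manifest.json", cfg.model_dump(), cfg.seed, outputs
    )
    return manifest


def _cluster_means(adata, labels: pd.Series) -> pd.DataFrame:
    rows = {}
    for c in sorted(set(labels) - {-1}):
        sub = adata[labels.index[labels == c]]
        X = sub.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        rows[c] = X.mean(axis=0)
    return pd.DataFrame(rows, index=adata.var_names).T
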