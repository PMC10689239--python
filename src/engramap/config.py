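"""Run configuration: every threshold, list and seed the pipeline uses, in
one validated block so the analysis constants are configuration rather than
code literals."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import genesets


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_umi_neurons: int = 3000
    min_genes_neurons: int = 2500
    min_umi_nonneuronal: int = 2000
    min_genes_nonneuronal: int = 1000
    normalization_scale: float = 20000.0
    norm: str = "l1"
    doublet_ratio_threshold: float = 2.0


class ClusteringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_feature_cells: int = 5
    max_feature_cell_frac: float = 0.5
    theta: float = 0.5
    exaggeration: float = 20.0
    final_viz_perplexity: float = 100.0
    final_viz_exaggeration: float = 5.0
    dbscan_min_pts: int = 10
    dbscan_eps: float | None = None
    knn_reassign_k: int = 5
    merge_similarity_threshold: float = 0.995
    merge_pairs: list[tuple[str, str]] = Field(default_factory=list)
    n_pcs: int | None = None


class EngramConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    panel: list[str] = Field(default_factory=lambda: list(genesets.IEG_PANEL))
    score_percentile: float = 90.0
    trap_percentile: float = 95.0
    obs_exp_percentile: float = 99.0
    min_cluster_cells: int = 60
    min_group_cells: int = 20
    fc_pseudocount: float = 0.1
    de_top_n: int = 100
    de_min_mean_umi: float = 1.0
    de_frequency_threshold: float = 0.5
    hc_baseline: str = "pooled"  # or "batch"

    @field_validator("hc_baseline")
    @classmethod
    def _check_mode(cls, v):
        if v not in ("pooled", "batch"):
            raise ValueError("hc_baseline must be 'pooled' or 'batch'")
        return v


class ModuleCorrConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    modules: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in genesets.DEFAULT_MODULES.items()}
    )
    min_gene_cells: int = 200
    min_cluster_per_tp: int = 20
    screen_min_cells: int = 5
    screen_alpha: float = 0.01
    screen_top_n: int = 200


class AnalysisConfig(BaseModel):
    """Top-level, schema-validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    outdir: str = "engramap_out"
    seed: int = 0
    qc: QCConfig = Field(default_factory=QCConfig)
    clustering: ClusteringConfig = Field(default_factory=ClusteringConfig)
    engram: EngramConfig = Field(default_factory=EngramConfig)
    modulecorr: ModuleCorrConfig = Field(default_factory=ModuleCorrConfig)
    ieg_exclusion: list[str] = Field(default_factory=lambda: list(genesets.IEG_EXCLUSION))
    sex_genes: list[str] = Field(default_factory=lambda: list(genesets.SEX_GENES))
    nonneuronal_markers: list[str] = Field(
        default_factory=lambda: list(genesets.NONNEURONAL_MARKERS)
    )
    counts_path: str | None = None

    def excluded_genes(self) -> tuple[str, ...]:
        return tuple(self.ieg_exclusion) + tuple(self.sex_genes) + tuple(
            self.nonneuronal_markers
        )


def load_config(path: str | Path) -> AnalysisConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisConfig.model_validate(data)


def dump_config(cfg: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
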