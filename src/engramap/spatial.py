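"""Spatial correlation mapping of cluster profiles onto spot matrices and
voxel atlases.

Cluster mean expression profiles are correlated (Pearson) with every spatial
unit (Visium-style capture spot, or 200 um in-situ "energy" voxel) over a
shared feature list — the intersection of highly variable genes selected
independently in the single-cell and spatial datasets, with non-neuronal
markers removed; voxel atlases additionally require genes to pass coverage,
peak-energy and mean-energy quality thresholds. Per-region summaries and
dominant/weighted color maps are derived from the correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .genesets import NONNEURONAL_MARKERS
from .taxonomy import rank_features, selected_genes


@dataclass
class SpatialTarget:
    """A spot matrix or voxel atlas: per-unit gene expression with coordinates
    and region annotations."""

    mode: str  # "spots" | "voxels"
    expression: pd.DataFrame  # units x genes (counts or energy)
    coords: np.ndarray  # units x 2 (xy) or units x 3 (xyz)
    regions: pd.Series  # per-unit region label
    grid_shape: tuple | None = None

    def __post_init__(self):
        if self.mode not in ("spots", "voxels"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.expression) != len(self.coords):
            raise ValueError("coordinates do not cover every unit")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression must be nonnegative")


@dataclass
class SpatialCorrelation:
    """Pearson rho of every cluster with every spatial unit."""

    rho: pd.DataFrame  # clusters x units; NaN marks undefined units
    features: list[str]
    normalization: dict


def shared_features(
    sc_adata: AnnData,
    target: SpatialTarget,
    excluded: tuple[str, ...] = NONNEURONAL_MARKERS,
    min_intersection: int = 20,
    spot_max_cell_frac: float = 1.01,
    **rank_kw,
) -> list[str]:
    """Intersection of highly variable genes selected independently in the
    single-cell and spatial datasets, non-neuronal markers removed first.

    Capture spots pool several cells' mRNA ("micro-bulk"), so most genes are
    detected in most spots; the spot-side upper detection gate is therefore
    disabled by default (``spot_max_cell_frac``) while the cell-side gates
    keep their single-cell defaults.
    """
    sc_sel = set(selected_genes(rank_features(sc_adata, excluded=excluded, **rank_kw)))
    spot_ad = AnnData(
        X=target.expression.to_numpy(float),
        obs=pd.DataFrame(index=target.expression.index),
        var=pd.DataFrame(index=target.expression.columns),
    )
    spot_ad.uns["normalized"] = True
    rank_kw.pop("max_cell_frac", None)
    sp_sel = set(
        selected_genes(
            rank_features(
                spot_ad, excluded=excluded, max_cell_frac=spot_max_cell_frac, **rank_kw
            )
        )
    )
    inter = sorted((sc_sel & sp_sel) - set(excluded))
    if len(inter) < min_intersection:
        raise ValueError(
            f"feature intersection has {len(inter)} genes; need >= {min_intersection}"
        )
    return inter


def _unit_normalize(df: pd.DataFrame) -> pd.DataFrame:
    totals = df.sum(axis=1)
    totals = totals.replace(0, np.nan)
    return df.div(totals, axis=0)


def correlate_profiles(
    cluster_means: pd.DataFrame,
    target: SpatialTarget,
    features: list[str],
    normalize: bool = True,
) -> SpatialCorrelation:
    """Pairwise Pearson correlation of each cluster mean with each unit over
    the feature list. Zero-variance units are marked undefined (NaN), not 0."""
    if len(features) < 3:
        raise ValueError("need at least 3 features to correlate")
    missing = [g for g in features if g not in cluster_means.columns or g not in target.expression.columns]
    if missing:
        raise KeyError(f"features absent from profiles or target: {missing[:5]}")
    P = cluster_means[features].astype(float)
    U = target.expression[features].astype(float)
    if normalize:
        P, U = _unit_normalize(P), _unit_normalize(U)
    Pc = P.sub(P.mean(axis=1), axis=0)
    Uc = U.sub(U.mean(axis=1), axis=0)
    Pn = np.sqrt((Pc**2).sum(axis=1))
    Un = np.sqrt((Uc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Pc.to_numpy() @ Uc.to_numpy().T) / np.outer(Pn, Un)
    rho[:, Un.to_numpy() == 0] = np.nan
    rho[Pn.to_numpy() == 0, :] = np.nan
    out = pd.DataFrame(rho, index=cluster_means.index, columns=target.expression.index)
    return SpatialCorrelation(
        rho=out,
        features=list(features),
        normalization={"unit_sum": bool(normalize)},
    )


def regionwise_summary(sc: SpatialCorrelation, regions: pd.Series) -> pd.DataFrame:
    """Mean rho per cluster per region; undefined units are skipped and a
    region with no valid unit is missing (NaN)."""
    regions = regions.reindex(sc.rho.columns)
    return sc.rho.T.groupby(regions).mean().T


def minmax_scale_rho(sc: SpatialCorrelation) -> pd.DataFrame:
    """Per-cluster min-max scaling of rho across units (global-pattern view)."""
    r = sc.rho
    lo = r.min(axis=1)
    span = (r.max(axis=1) - lo).replace(0, np.nan)
    return r.sub(lo, axis=0).div(span, axis=0)


def render_map(
    sc: SpatialCorrelation,
    mode: str = "dominant",
    colors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-unit dominant cluster label, or a weighted color blend.

    Dominant mode: argmax cluster per unit (ties -> lower cluster id).
    Weighted mode: per unit, color = convex combination of cluster colors
    weighted by max(rho, 0) normalized to sum 1; units with no positive rho
    get the background (NaN color, label None).
    """
    rho = sc.rho
    if mode == "dominant":
        vals = rho.to_numpy()
        allnan = np.all(np.isnan(vals), axis=0)
        idx = np.nanargmax(np.where(np.isnan(vals), -np.inf, vals), axis=0)
        labels = rho.index.to_numpy()[idx].astype(object)
        labels[allnan] = None
        return pd.DataFrame({"unit": rho.columns, "label": labels}).set_index("unit")
    if mode != "weighted":
        raise ValueError(f"unknown mode {mode!r}")
    if colors is None:
        # deterministic default palette over clusters
        k = len(rho.index)
        hues = np.linspace(0, 1, k, endpoint=False)
        colors = pd.DataFrame(
            {
                "r": 0.5 + 0.5 * np.cos(2 * np.pi * hues),
                "g": 0.5 + 0.5 * np.cos(2 * np.pi * (hues + 1 / 3)),
                "b": 0.5 + 0.5 * np.cos(2 * np.pi * (hues + 2 / 3)),
            },
            index=rho.index,
        )
    W = np.clip(np.nan_to_num(rho.to_numpy()), 0.0, None)
    totals = W.sum(axis=0)
    out = np.full((rho.shape[1], colors.shape[1]), np.nan)
    ok = totals > 0
    Wn = W[:, ok] / totals[ok]
    out[ok] = Wn.T @ colors.to_numpy()
    return pd.DataFrame(out, index=rho.columns, columns=colors.columns)


def filter_atlas_genes(
    atlas: SpatialTarget,
    min_voxels: int = 30,
    min_energy: float = 5.0,
    min_mean: float = 0.2,
) -> list[str]:
    """Atlas quality filter: a gene is valid iff it covers more than
    ``min_voxels`` voxels (energy > 0), its peak energy exceeds
    ``min_energy`` and its mean over all voxels exceeds ``min_mean``
    (all strict inequalities)."""
    if atlas.mode != "voxels":
        raise ValueError("atlas filter applies to voxel targets")
    E = atlas.expression
    coverage = (E > 0).sum(axis=0)
    peak = E.max(axis=0)
    mean = E.mean(axis=0)
    ok = (coverage > min_voxels) & (peak > min_energy) & (mean > min_mean)
    return list(E.columns[ok])


def correlate_atlas(
    cluster_means: pd.DataFrame,
    atlas: SpatialTarget,
    features: list[str],
) -> tuple[SpatialCorrelation, pd.Series, pd.DataFrame]:
    """Correlate cluster profiles with every voxel over quality-filtered
    features; call each cluster's region as the one with highest mean rho.

    ``features`` should already be the intersection of the single-cell feature
    selection with the atlas quality genes; any gene failing the atlas filter
    here is dropped defensively.
    """
    valid = set(filter_atlas_genes(atlas))
    feats = [g for g in features if g in valid]
    sc = correlate_profiles(cluster_means, atlas, feats)
    per_region = regionwise_summary(sc, atlas.regions)
    calls = per_region.idxmax(axis=1)
    return sc, calls, per_region
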