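"""Cell quality filtering, normalization and neurotransmitter-class assignment.

First pass of the iterative clustering procedure: cells are kept above
class-appropriate UMI/gene thresholds (neurons: 3,000 UMI and 2,500 genes;
non-neuronal stream: 2,000 UMI and 1,000 genes), each cell vector is
normalized to unit length and rescaled to 20,000, rough clusters are assigned
to GABA / VGLUT1 / VGLUT2 / non-neuronal by a majority vote of marker genes,
and clusters mixing two marker sets at a score ratio below 2 are flagged as
doublets (the VGLUT1+VGLUT2 combination is biologically permitted and exempt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .genesets import CLASS_MARKERS, NONNEURONAL_MARKERS

DEFAULT_ALLOWED_PAIRS: frozenset[frozenset[str]] = frozenset(
    {frozenset({"VGLUT1", "VGLUT2"})}
)


def default_marker_sets() -> dict[str, tuple[str, ...]]:
    """Vote categories: the three neuron classes plus combined non-neuronal."""
    sets = {cls: genes for cls, genes in CLASS_MARKERS.items()}
    sets["non-neuronal"] = NONNEURONAL_MARKERS
    return sets


@dataclass
class ClassAssignment:
    """Per-cluster class call with the score table behind it."""

    cluster_class: pd.Series  # cluster -> class label ("unassigned" possible)
    scores: pd.DataFrame  # clusters x classes, mean marker-set expression
    doublet: pd.Series  # cluster -> bool


def _dense(adata: AnnData, genes: list[str] | None = None) -> np.ndarray:
    X = adata[:, genes].X if genes is not None else adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def filter_cells(adata: AnnData, min_umi: int = 3000, min_genes: int = 2500) -> pd.Index:
    """Cells with total UMI >= ``min_umi`` and detected genes >= ``min_genes``.

    Operates on raw counts only; order of retained cells is preserved.
    """
    if adata.uns.get("normalized", False):
        raise ValueError("filter_cells requires raw counts, got a normalized matrix")
    X = adata.X
    if hasattr(X, "tocsr"):
        totals = np.asarray(X.sum(axis=1)).ravel()
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        totals = X.sum(axis=1)
        detected = (X > 0).sum(axis=1)
    keep = (totals >= min_umi) & (detected >= min_genes)
    return adata.obs_names[keep]


def normalize_cells(adata: AnnData, scale: float = 20000.0, norm: str = "l1") -> AnnData:
    """Rescale every cell vector to unit length (L1 by default) times ``scale``.

    Returns a new AnnData with float X and ``uns['normalized'] = True``.
    """
    X = adata.X
    dense = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, float)
    dense = dense.astype(float)
    if norm == "l1":
        lengths = dense.sum(axis=1)
    elif norm == "l2":
        lengths = np.sqrt((dense**2).sum(axis=1))
    else:
        raise ValueError(f"unknown norm {norm!r}")
    zero = np.flatnonzero(lengths == 0)
    if zero.size:
        names = ", ".join(adata.obs_names[zero[:5]])
        raise ValueError(f"cells with zero total cannot be normalized: {names}")
    out = adata.copy()
    out.X = dense / lengths[:, None] * scale
    out.uns["normalized"] = True
    out.uns["normalization"] = {"norm": norm, "scale": float(scale)}
    return out


def assign_classes(
    adata: AnnData,
    clusters: pd.Series,
    marker_sets: dict[str, tuple[str, ...]] | None = None,
) -> ClassAssignment:
    """Majority vote of marker genes over normalized expression.

    Each cell votes for the class whose marker-set mean expression is highest
    (all-zero -> no vote); a cluster's class is the modal vote, and the
    per-cluster per-class mean marker expression is reported for the doublet
    ratio rule.
    """
    if not adata.uns.get("normalized", False):
        raise ValueError("assign_classes expects a normalized matrix")
    marker_sets = marker_sets or default_marker_sets()
    clusters = clusters.reindex(adata.obs_names)

    per_cell = pd.DataFrame(index=adata.obs_names, dtype=float)
    for cls, genes in marker_sets.items():
        present = [g for g in genes if g in adata.var_names]
        if not present:
            per_cell[cls] = 0.0
            continue
        per_cell[cls] = _dense(adata, present).mean(axis=1)

    vals = per_cell.to_numpy()
    best = vals.argmax(axis=1)
    voted = vals.max(axis=1) > 0
    vote = pd.Series(
        np.where(voted, per_cell.columns.to_numpy()[best], None), index=adata.obs_names
    )

    labels = sorted(clusters.dropna().unique())
    cls_call, rows = {}, {}
    for c in labels:
        members = clusters.index[clusters == c]
        votes = vote.loc[members].dropna()
        cls_call[c] = votes.mode().iloc[0] if len(votes) else "unassigned"
        rows[c] = per_cell.loc[members].mean(axis=0)
    scores = pd.DataFrame(rows).T
    scores.index.name = "cluster"
    return ClassAssignment(
        cluster_class=pd.Series(cls_call, name="class"),
        scores=scores,
        doublet=pd.Series(False, index=scores.index, name="doublet"),
    )


def call_doublet_clusters(
    assignment: ClassAssignment,
    ratio_threshold: float = 2.0,
    allowed_pairs: frozenset[frozenset[str]] = DEFAULT_ALLOWED_PAIRS,
) -> pd.Series:
    """Flag clusters whose top two marker-set scores are within ``ratio_threshold``.

    A cluster combining two marker sets at top/second < threshold is a putative
    doublet cluster, unless that pair is explicitly permitted. A second score
    of zero never flags.
    """
    flags = {}
    for c, row in assignment.scores.iterrows():
        ranked = row.sort_values(ascending=False)
        top, second = ranked.index[0], ranked.index[1]
        if ranked.iloc[1] <= 0:
            flags[c] = False
            continue
        ratio = ranked.iloc[0] / ranked.iloc[1]
        flags[c] = ratio < ratio_threshold and frozenset({top, second}) not in allowed_pairs
    out = pd.Series(flags, name="doublet")
    assignment.doublet = out
    return out


def exclude_expressing(adata: AnnData, genes: list[str]) -> pd.Index:
    """Cells with zero raw count for every listed gene (non-neuronal stream)."""
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {', '.join(missing)}")
    if not genes:
        return adata.obs_names
    expr = _dense(adata, list(genes))
    keep = (expr > 0).sum(axis=1) == 0
    return adata.obs_names[keep]
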