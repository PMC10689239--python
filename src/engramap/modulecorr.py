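"""Gene-module coexpression scoring.

For each cell type and sampling timepoint, the pairwise Pearson correlation
matrix of a gene module (IEGs, learning/memory genes, receptor and channel
families, semaphorins, or all combined) is aggregated to a single correlation
via the mean Fisher z of its off-diagonal entries, converted to a two-sided
P value through the t distribution, and summarized as score = -log10(p).
The per-cluster correlation score is the maximum score among the
post-conditioning timepoints minus the maximum among the home-cage controls
(batch A or B). A transcriptome-wide single-gene screen ranks genes by how
often they correlate significantly with a target gene across
(cluster, timepoint) groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

from .simulate import CFC_TIMEPOINTS

SCORE_CAP = 320.0  # double-precision -log10 floor


def _dense(adata: AnnData, genes=None) -> np.ndarray:
    X = adata[:, list(genes)].X if genes is not None else adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, float)


def eligibility(
    adata: AnnData,
    class_cells,
    clusters: pd.Series,
    timepoints: pd.Series,
    min_gene_cells: int = 200,
    min_cluster_per_tp: int = 20,
    tp_order: tuple[str, ...] | None = None,
) -> tuple[list[str], list]:
    """Genes expressed in more than ``min_gene_cells`` cells of the class, and
    clusters with at least ``min_cluster_per_tp`` cells at every timepoint."""
    class_cells = list(class_cells)
    X = _dense(adata[class_cells])
    n_pos = (X > 0).sum(axis=0)
    genes = list(adata.var_names[n_pos > min_gene_cells])

    cl = clusters.reindex(class_cells)
    tp = timepoints.reindex(class_cells)
    tps = list(tp_order) if tp_order is not None else sorted(tp.dropna().unique())
    ok_clusters = []
    for c in sorted(x for x in cl.dropna().unique() if x != -1):
        counts = [(((cl == c) & (tp == t)).sum()) for t in tps]
        if min(counts) >= min_cluster_per_tp:
            ok_clusters.append(c)
    return genes, ok_clusters


def pairwise_correlation(
    adata: AnnData, genes: list[str], cells
) -> tuple[pd.DataFrame, int]:
    """Pearson correlation matrix of the genes over the cells, with the cell
    count n. Zero-variance genes are dropped with a warning."""
    cells = list(cells)
    if len(cells) < 3:
        raise ValueError("need at least 3 cells for pairwise correlation")
    X = _dense(adata[cells], genes)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(f"dropping zero-variance genes: {dropped[:5]}")
    genes = [g for g, k in zip(genes, keep) if k]
    if len(genes) < 2:
        raise ValueError("fewer than 2 usable genes after dropping zero variance")
    R = np.corrcoef(X[:, keep], rowvar=False)
    return pd.DataFrame(R, index=genes, columns=genes), len(cells)


def correlation_p(r: float, n: int) -> float:
    """Two-sided P value of a Pearson correlation via the t distribution:
    t = r * sqrt((n-2) / (1-r^2)), p = 2 * SF_t(|t|; n-2).

    Computed through the log survival function so extreme correlations
    underflow gracefully (|r| = 1 caps at the smallest positive float).
    """
    return float(np.exp(correlation_log_p(r, n)))


def correlation_log_p(r: float, n: int) -> float:
    """Natural log of the two-sided correlation P value."""
    if n < 4:
        raise ValueError("need n >= 4")
    r = float(r)
    if abs(r) >= 1.0:
        return np.log(np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(np.log(2.0) + stats.t.logsf(abs(t), df=n - 2))


def module_score(r_matrix: pd.DataFrame, n: int) -> tuple[float, float, float]:
    """Aggregate a pairwise correlation matrix to (r_bar, p, score).

    r_bar is the inverse Fisher z of the mean Fisher z over the off-diagonal
    upper-triangle entries; p is its two-sided t-distribution P value at n
    cells; score = min(-log10(p), 320).
    """
    R = r_matrix.to_numpy()
    iu = np.triu_indices_from(R, k=1)
    if iu[0].size == 0:
        raise ValueError("no off-diagonal entries to aggregate")
    z = np.arctanh(np.clip(R[iu], -0.999999, 0.999999))
    r_bar = float(np.tanh(z.mean()))
    logp = correlation_log_p(r_bar, n)
    score = min(-logp / np.log(10.0), SCORE_CAP)
    return r_bar, float(np.exp(logp)), float(score)


def cluster_score(cfc_scores: dict, hc_scores: dict) -> float:
    """max over post-conditioning timepoint scores minus max over home-cage
    control scores (batch A or B); may be negative."""
    cfc = [v for v in cfc_scores.values() if v is not None and not np.isnan(v)]
    hc = [v for v in hc_scores.values() if v is not None and not np.isnan(v)]
    if not cfc or not hc:
        return float("nan")
    return float(max(cfc) - max(hc))


def score_table(
    adata: AnnData,
    module_genes: list[str],
    clusters: pd.Series,
    timepoints: pd.Series,
    batches: pd.Series,
    eligible_clusters: list,
    hc_key: str = "HC",
    cfc_keys: tuple[str, ...] = CFC_TIMEPOINTS,
) -> pd.DataFrame:
    """Per cluster x timepoint module scores plus the per-cluster score.

    Home-cage controls are scored separately per batch; the cluster score is
    max(CFC timepoints) - max(HC batch A, HC batch B).
    """
    clusters = clusters.reindex(adata.obs_names)
    timepoints = timepoints.reindex(adata.obs_names)
    batches = batches.reindex(adata.obs_names)
    rows = []
    for c in eligible_clusters:
        base = clusters == c
        tp_scores, hc_scores = {}, {}
        for t in cfc_keys:
            cells = adata.obs_names[base & (timepoints == t)]
            tp_scores[t] = _safe_score(adata, module_genes, cells)
        for b in sorted(batches.dropna().unique()):
            cells = adata.obs_names[base & (timepoints == hc_key) & (batches == b)]
            hc_scores[b] = _safe_score(adata, module_genes, cells)
        row = {"cluster": c}
        row.update({f"score_{t}": v for t, v in tp_scores.items()})
        row.update({f"score_HC_{b}": v for b, v in hc_scores.items()})
        row["cluster_score"] = cluster_score(tp_scores, hc_scores)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster") if rows else pd.DataFrame()


def _safe_score(adata, genes, cells) -> float:
    try:
        R, n = pairwise_correlation(adata, genes, cells)
        return module_score(R, n)[2]
    except ValueError:
        return float("nan")


def hierarchical_gene_order(r_matrix: pd.DataFrame) -> list[str]:
    """Display order of module genes: average linkage on 1 - r."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    D = 1.0 - r_matrix.to_numpy()
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return [r_matrix.index[i] for i in hierarchy.leaves_list(Z)]


def gene_correlation_screen(
    target: str,
    adata: AnnData,
    clusters: pd.Series,
    timepoints: pd.Series,
    eligible_clusters: list,
    cfc_keys: tuple[str, ...] = CFC_TIMEPOINTS,
    min_cells_gene: int = 5,
    alpha: float = 0.01,
    top_n: int = 200,
) -> pd.DataFrame:
    """Transcriptome-wide correlation screen for one target gene.

    For every (eligible cluster, post-conditioning timepoint) group, genes
    expressed in more than ``min_cells_gene`` cells are correlated with the
    target; genes with two-sided P < alpha count one occurrence. The output
    ranks genes by their occurrence frequency (the target itself excluded).
    """
    if target not in adata.var_names:
        raise KeyError(f"target gene {target!r} not in matrix")
    clusters = clusters.reindex(adata.obs_names)
    timepoints = timepoints.reindex(adata.obs_names)
    freq: dict[str, int] = {}
    n_groups = 0
    X_all = _dense(adata)
    var_names = np.asarray(adata.var_names)
    t_idx = int(np.flatnonzero(var_names == target)[0])
    obs_pos = {n: i for i, n in enumerate(adata.obs_names)}
    for c in eligible_clusters:
        for t in cfc_keys:
            cells = adata.obs_names[(clusters == c) & (timepoints == t)]
            if len(cells) < 4:
                continue
            rows = [obs_pos[x] for x in cells]
            Xg = X_all[rows]
            y = Xg[:, t_idx]
            if y.std() == 0:
                continue  # target flat in this group
            n_groups += 1
            expressed = (Xg > 0).sum(axis=0) > min_cells_gene
            expressed[t_idx] = False
            sd = Xg.std(axis=0)
            usable = expressed & (sd > 0)
            yc = y - y.mean()
            Xc = Xg[:, usable] - Xg[:, usable].mean(axis=0)
            r = (Xc.T @ yc) / (np.sqrt((Xc**2).sum(axis=0)) * np.sqrt((yc**2).sum()))
            n = len(cells)
            tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
            p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
            for g in var_names[usable][p < alpha]:
                freq[g] = freq.get(g, 0) + 1
    tbl = pd.Series(freq, name="frequency").sort_index(kind="stable")
    tbl = tbl.sort_values(ascending=False, kind="stable")
    out = tbl.head(top_n).to_frame()
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["n_groups"] = n_groups
    return out
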