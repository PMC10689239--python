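"""Cell-type taxonomy: feature selection, PCA, batch correction, t-SNE
embedding, density clustering, dendrogram and branch-point markers.

The pipeline follows the iterative-clustering recipe: highly variable genes
are ranked by their residual above a least-squares fit of log2(CV) on
log2(mean) and the selection size is the bend of the sorted residual curve;
the number of PCs is the bend of the explained-variance curve; the 2D map is
Barnes-Hut t-SNE with correlation distance, theta 0.5, learning rate n/12 and
exaggeration 20 (final visualization: perplexity 100, exaggeration 5),
initialized from the first two PCs; clusters are DBSCAN calls on the 2D map
with outliers removed (spots: reassigned by kNN); the cluster dendrogram is
Ward linkage with correlation distance on a PCA of log2(x+1) cluster means
with optimal leaf ordering; branch markers rank genes by the difference in
fraction-positive cells between the two branches of each junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE


# ------------------------------------------------------------------ elbow

def find_elbow(values) -> int:
    """1-based index of the bend of a monotone curve.

    The curve is min-max normalized, a chord is drawn between its first and
    last points, and the point of maximum perpendicular distance to the chord
    is the bend (Kneedle-style). Ties break to the smallest index; a constant
    series returns 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 points to locate a bend")
    span = v.max() - v.min()
    if span == 0:
        return 1
    x = np.linspace(0.0, 1.0, v.size)
    y = (v - v.min()) / span
    dy, dx = y[-1] - y[0], 1.0
    # distance from (x, y) to the chord through (0, y0) and (1, y1)
    d = np.abs(dy * x - dx * (y - y[0])) / np.hypot(dx, dy)
    d[d < 1e-12] = 0.0  # strictly linear series degrade to the first index
    # ties (within rounding) break to the smallest index
    return int(np.flatnonzero(d >= d.max() - 1e-12)[0]) + 1


# --------------------------------------------------------- feature selection

def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, float)


def rank_features(
    adata: AnnData,
    min_cells: int = 5,
    max_cell_frac: float = 0.5,
    excluded: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Rank genes by coefficient-of-variation residual and mark the selection.

    Eligible genes are expressed (count > 0) in at least ``min_cells`` cells
    but in fewer than ``max_cell_frac`` of all cells and are not on the
    exclusion list (IEGs, sex genes, irrelevant markers). log2(CV) is
    regressed on log2(mean); genes are ranked by residual above the fit and
    the number selected is the bend of the sorted residual curve.
    """
    X = _dense(adata)
    n_cells = X.shape[0]
    pos = (X > 0).sum(axis=0)
    eligible = (pos >= min_cells) & (pos < max_cell_frac * n_cells)
    eligible &= ~adata.var_names.isin(excluded).astype(bool)

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if n_cells > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    eligible &= mean > 0
    eligible &= np.nan_to_num(cv) > 0
    if eligible.sum() < 10:
        raise ValueError(f"only {int(eligible.sum())} eligible genes; need >= 10")

    lm, lcv = np.log2(mean[eligible]), np.log2(cv[eligible])
    slope, intercept = np.polyfit(lm, lcv, 1)
    resid = np.full(X.shape[1], np.nan)
    resid[eligible] = lcv - (slope * lm + intercept)

    out = pd.DataFrame(
        {"mean": mean, "cv": cv, "residual": resid, "eligible": eligible},
        index=adata.var_names,
    )
    order = out.loc[eligible, "residual"].sort_values(ascending=False)
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    out["rank"] = ranks.reindex(out.index)
    # The residual curve is heavy-tailed; its bend is located on a log axis
    # over the positive residuals (genes above the CV-mean fit).
    vals = order.to_numpy()
    pos = vals[vals > 0]
    n_sel = find_elbow(np.log(pos)) if pos.size >= 3 else find_elbow(vals)
    out["selected"] = out["rank"] <= n_sel
    out["selected"] = out["selected"].fillna(False)
    return out


def selected_genes(ranking: pd.DataFrame) -> list[str]:
    return list(ranking.index[ranking["selected"]])


# ----------------------------------------------------------------- PCA stage

def pca_project(
    X: np.ndarray, n_pcs: int | None = None, max_pcs: int = 50, seed: int = 0
) -> tuple[np.ndarray, PCA]:
    """PCA projection; if ``n_pcs`` is None it is the bend of the
    explained-variance curve."""
    k = min(max_pcs, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, random_state=seed)
    proj = pca.fit_transform(X)
    if n_pcs is None:
        # explained variance spans orders of magnitude; bend judged on log scale
        n_pcs = max(2, find_elbow(np.log(pca.explained_variance_ratio_)))
    return proj[:, :n_pcs], pca


def correct_batches(projection: np.ndarray, batches, backend=None) -> np.ndarray:
    """Align batches in PC space so a batch-mixing statistic does not decrease.

    The default backend centers each principal component per batch (global
    mean restored); a callable ``backend(projection, batches) -> projection``
    can plug in an external alignment method. Batches with fewer than 3 cells
    are passed through with a warning; a single batch is the identity.
    """
    batches = np.asarray(batches)
    labels = pd.unique(batches)
    if len(labels) < 2:
        return projection
    if backend is not None:
        return backend(projection, batches)
    out = projection.astype(float).copy()
    grand = projection.mean(axis=0)
    for b in labels:
        m = batches == b
        if m.sum() < 3:
            warnings.warn(f"batch {b!r} has <3 cells; passed through uncorrected")
            continue
        out[m] += grand - projection[m].mean(axis=0)
    return out


# ------------------------------------------------------------------- t-SNE

@dataclass
class EmbeddingConfig:
    """t-SNE parameters; defaults are the clustering-pass heuristics."""

    metric: str = "correlation"
    theta: float = 0.5
    learning_rate: float | None = None  # None -> n_cells / 12
    exaggeration: float = 20.0
    perplexity: float | None = None  # None -> choose_perplexity heuristic
    n_pcs: int | None = None
    seed: int = 0

    @classmethod
    def final_viz(cls, **kw) -> "EmbeddingConfig":
        """Final-visualization mode: perplexity 100, exaggeration 5."""
        kw.setdefault("perplexity", 100.0)
        kw.setdefault("exaggeration", 5.0)
        return cls(**kw)


def choose_perplexity(projection: np.ndarray, k_max: int = 500) -> float:
    """Perplexity heuristic: median over cells of the bend of each cell's
    sorted correlation-distance curve to its first ``k_max`` neighbors,
    clipped to [5, n/4]."""
    n = projection.shape[0]
    k = min(k_max, n - 1)
    D = cdist(projection, projection, metric="correlation")
    np.fill_diagonal(D, np.inf)
    part = np.sort(np.partition(D, k - 1, axis=1)[:, :k], axis=1)
    per_cell = np.array([find_elbow(row) for row in part])
    perp = float(np.median(per_cell))
    perp = min(perp, n / 4)
    return max(perp, 5.0)


def embed_2d(projection: np.ndarray, cfg: EmbeddingConfig | None = None) -> np.ndarray:
    """Barnes-Hut t-SNE of the (batch-corrected) PC projection, initialized
    from the first two PCs scaled to sd 1e-4."""
    cfg = cfg or EmbeddingConfig()
    n = projection.shape[0]
    perplexity = cfg.perplexity if cfg.perplexity is not None else choose_perplexity(projection)
    perplexity = min(perplexity, (n - 1) / 3)
    if n < perplexity * 3:
        raise ValueError(f"{n} cells too few for perplexity {perplexity}")
    lr = cfg.learning_rate if cfg.learning_rate is not None else max(n / 12, 10.0)
    init = projection[:, :2].astype(float).copy()
    init = init / max(init[:, 0].std(), 1e-12) * 1e-4
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        early_exaggeration=cfg.exaggeration,
        learning_rate=lr,
        metric=cfg.metric,
        init=init,
        angle=cfg.theta,
        random_state=cfg.seed,
        method="barnes_hut",
    )
    return tsne.fit_transform(projection)


# ---------------------------------------------------------------- clustering

@dataclass
class ClusterSet:
    """DBSCAN cluster labels on the 2D map (-1 marks outliers)."""

    labels: pd.Series
    eps: float
    min_pts: int
    within_order: dict = field(default_factory=dict)

    def clusters(self) -> list:
        return sorted(c for c in self.labels.unique() if c != -1)


def dbscan_eps_heuristic(coords: np.ndarray, min_pts: int) -> float:
    """eps from the bend of the descending k-distance curve (k = min_pts)."""
    D = cdist(coords, coords)
    kdist = np.sort(D, axis=1)[:, min(min_pts, coords.shape[0] - 1)]
    curve = np.sort(kdist)[::-1]
    return float(curve[find_elbow(curve) - 1])


def cluster_embedding(
    coords: np.ndarray,
    eps: float | None = None,
    min_pts: int = 10,
    index: pd.Index | None = None,
) -> ClusterSet:
    """Density clustering of the 2D embedding; outliers keep label -1 and are
    excluded from cluster membership downstream."""
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite embedding coordinates")
    if eps is None:
        eps = dbscan_eps_heuristic(coords, min_pts)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    if (labels == -1).all():
        raise ValueError(
            f"DBSCAN labeled every cell an outlier (eps={eps:.4g}, min_pts={min_pts}); "
            "increase eps or decrease min_pts"
        )
    idx = index if index is not None else pd.RangeIndex(len(labels))
    return ClusterSet(labels=pd.Series(labels, index=idx), eps=float(eps), min_pts=min_pts)


def reassign_outliers_knn(coords: np.ndarray, labels, k: int = 5):
    """Give each outlier (-1) the modal label of its k nearest non-outlier
    points; ties resolve to the single nearest neighbor's label."""
    labels = pd.Series(labels).copy()
    out_mask = labels.to_numpy() == -1
    if not out_mask.any():
        return labels
    good = ~out_mask
    if not good.any():
        raise ValueError("no non-outlier points to reassign to")
    D = cdist(coords[out_mask], coords[good])
    good_labels = labels.to_numpy()[good]
    kk = min(k, good_labels.size)
    for row, pos in enumerate(np.flatnonzero(out_mask)):
        order = np.argsort(D[row])[:kk]
        neigh = good_labels[order]
        counts = pd.Series(neigh).value_counts()
        top = counts[counts == counts.iloc[0]].index
        labels.iloc[pos] = top[0] if len(top) == 1 else neigh[0]
    return labels


def order_within_cluster(adata: AnnData, cells, seed: int = 0) -> list:
    """1D t-SNE ordering of a cluster's cells; fewer than 3 cells keep their
    input order."""
    cells = list(cells)
    if len(cells) < 3:
        return cells
    X = _dense(adata[cells])
    n = len(cells)
    # ordering (not cluster separation) wants a large neighborhood and no
    # exaggeration phase; init from PC1 of the cluster
    perp = max(2.0, min(50.0, (n - 1) / 1.2))
    init = PCA(n_components=1, random_state=seed).fit_transform(
        X - X.mean(axis=1, keepdims=True)
    )
    init = init / max(np.abs(init).max(), 1e-12) * 1e-4
    emb = TSNE(
        n_components=1,
        perplexity=perp,
        metric="correlation",
        init=init,
        early_exaggeration=1.0,
        random_state=seed,
        method="exact",
    ).fit_transform(X)
    order = np.argsort(emb.ravel(), kind="stable")
    return [cells[i] for i in order]


def merge_similar_clusters(
    adata: AnnData,
    labels: pd.Series,
    threshold: float = 0.995,
    explicit: tuple[tuple, ...] = (),
    features: list[str] | None = None,
) -> pd.Series:
    """Merge clusters whose mean profiles correlate above ``threshold``
    (plus any explicitly listed pairs); replaces manual visual merging.

    Similarity should be judged in the clustering feature space (pass the
    selected genes via ``features``): over the full transcriptome the shared
    baseline makes every pair of cluster means correlate near 1.
    """
    labels = labels.copy()
    clusters = sorted(c for c in labels.unique() if c != -1)
    if len(clusters) < 2:
        return labels
    sub = adata[:, features] if features is not None else adata
    means = np.vstack(
        [_dense(sub[labels.index[labels == c]]).mean(axis=0) for c in clusters]
    )
    R = np.corrcoef(means)
    parent = {c: c for c in clusters}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, ci in enumerate(clusters):
        for j in range(i + 1, len(clusters)):
            if R[i, j] > threshold:
                parent[find(clusters[j])] = find(ci)
    for a, b in explicit:
        if a in parent and b in parent:
            parent[find(b)] = find(a)
    mapping = {c: find(c) for c in clusters}
    return labels.map(lambda c: mapping.get(c, c))


# ---------------------------------------------------------------- dendrogram

@dataclass
class Dendrogram:
    """Ward/correlation merge tree over clusters with optimal leaf order."""

    linkage: np.ndarray
    clusters: list  # leaf id -> cluster label
    leaf_order: list  # cluster labels in display order

    def junctions(self):
        """Yield (junction id, left cluster set, right cluster set)."""
        n = len(self.clusters)
        members = {i: {self.clusters[i]} for i in range(n)}
        for j, (a, b, *_rest) in enumerate(self.linkage):
            a, b = int(a), int(b)
            members[n + j] = members[a] | members[b]
            yield n + j, frozenset(members[a]), frozenset(members[b])

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return str(self.clusters[node.id])
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def build_dendrogram(
    adata: AnnData, labels: pd.Series, n_pcs: int | None = None, seed: int = 0
) -> Dendrogram:
    """log2(x+1) cluster means -> PCA -> Ward linkage on correlation distance
    -> optimal leaf ordering.

    Ward's update formally assumes Euclidean geometry; applying it to a
    correlation-distance matrix follows the source procedure verbatim.
    """
    clusters = sorted(c for c in labels.dropna().unique() if c != -1)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for a dendrogram")
    logX = np.log2(_dense(adata) + 1.0)
    obs_pos = {n: i for i, n in enumerate(adata.obs_names)}
    means = np.vstack(
        [
            logX[[obs_pos[c] for c in labels.index[labels == cl]]].mean(axis=0)
            for cl in clusters
        ]
    )
    k = min(20, len(clusters) - 1, means.shape[1])
    # correlation distance needs >= 2 coordinates; with very few clusters the
    # PCA projection degenerates, so fall back to the mean profiles themselves
    proj = (
        PCA(n_components=k, random_state=seed).fit_transform(means)
        if k >= 2
        else means
    )
    dists = pdist(proj, metric="correlation")
    dists = np.clip(dists, 0.0, None)
    Z = hierarchy.linkage(dists, method="ward")
    Z = hierarchy.optimal_leaf_ordering(Z, dists)
    leaves = hierarchy.leaves_list(Z)
    return Dendrogram(
        linkage=Z, clusters=clusters, leaf_order=[clusters[i] for i in leaves]
    )


def branch_markers(
    adata: AnnData, dendro: Dendrogram, labels: pd.Series, top_k: int = 10
) -> pd.DataFrame:
    """Per junction, genes ranked by the difference in fraction-positive cells
    between the branches (per-cluster fractions averaged within each branch)."""
    X = _dense(adata)
    pos = X > 0
    obs_pos = {n: i for i, n in enumerate(adata.obs_names)}
    frac = {}
    for c in dendro.clusters:
        rows = [obs_pos[i] for i in labels.index[labels == c]]
        frac[c] = pos[rows].mean(axis=0)
    frac = pd.DataFrame(frac, index=adata.var_names).T  # clusters x genes

    records = []
    for jid, left, right in dendro.junctions():
        delta = frac.loc[sorted(left)].mean(axis=0) - frac.loc[sorted(right)].mean(axis=0)
        for side, series in (("left", delta), ("right", -delta)):
            top = series.sort_values(ascending=False).head(top_k)
            for g, d in top.items():
                records.append(
                    {"junction": jid, "side": side, "gene": g, "delta": float(d)}
                )
    return pd.DataFrame.from_records(records)
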