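"""Feature selection, elbow detection, embedding, clustering, dendrogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from engramap import taxonomy as tax
from tests.conftest import make_adata


# ------------------------------------------------------------------- elbow

def brute_force_elbow(values):
    """Exhaustive max-chord-distance search (independent of the implementation)."""
    v = np.asarray(values, float)
    if v.max() == v.min():
        return 1
    x = np.linspace(0, 1, v.size)
    y = (v - v.min()) / (v.max() - v.min())
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    best, best_d = 0, -1.0
    for i in range(v.size):
        # distance from point i to the line through the curve's endpoints
        d = abs((y1 - y0) * x[i] - (x1 - x0) * (y[i] - y0)) / np.hypot(x1 - x0, y1 - y0)
        if d > best_d + 1e-12:  # ties break to the smallest index
            best, best_d = i, d
    return best + 1


def test_find_elbow_bend_example():
    assert tax.find_elbow([10, 9, 1, 0.9, 0.8]) == 3


def test_find_elbow_degenerate_series():
    assert tax.find_elbow(np.linspace(10, 0, 8)) == 1  # strictly linear
    assert tax.find_elbow([5, 5, 5, 5]) == 1  # constant
    with pytest.raises(ValueError):
        tax.find_elbow([3, 1])


@given(
    st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=3, max_size=40)
)
def test_find_elbow_matches_exhaustive_search(values):
    v = np.sort(np.asarray(values))[::-1]
    assert tax.find_elbow(v) == brute_force_elbow(v)


# --------------------------------------------------------- feature selection

def test_feature_gates_and_exclusion():
    rng = np.random.default_rng(0)
    n_cells = 60
    X = rng.poisson(0.6, size=(n_cells, 40)).astype(float)
    genes = [f"g{i}" for i in range(38)] + ["rare", "Fos"]
    X[:, 38] = 0
    X[:4, 38] = 9.0  # expressed in only 4 cells -> below the >=5-cell gate
    X[:, 39] = 0
    X[: n_cells // 4, 39] = 50.0  # highly variable but on the exclusion list
    ad = make_adata(X, genes=genes, normalized=True)
    rk = tax.rank_features(ad, excluded=("Fos",))
    assert not rk.loc["rare", "eligible"]
    assert not rk.loc["Fos", "selected"]
    assert np.isnan(rk.loc["Fos", "rank"])
    sel = rk.loc[rk["eligible"], "rank"].dropna()
    assert sel.is_unique


def test_planted_markers_dominate_ranking(normalized_small):
    """With the study's exclusion lists applied (class / non-neuronal markers
    and IEGs are excluded from feature selection), the planted type markers
    fill at least 90% of the top-|markers| ranks."""
    from engramap.genesets import CLASS_MARKERS, IEG_PANEL, NONNEURONAL_MARKERS

    norm, truth = normalized_small
    excluded = tuple(IEG_PANEL) + tuple(NONNEURONAL_MARKERS)
    excluded += tuple(g for mk in CLASS_MARKERS.values() for g in mk)
    rk = tax.rank_features(norm, excluded=excluded)
    n_markers = sum(len(v) for v in truth.marker_genes.values())
    top = set(rk.sort_values("rank").index[:n_markers])
    planted = {g for v in truth.marker_genes.values() for g in v}
    assert len(top & planted) / n_markers >= 0.9


def test_selection_count_equals_elbow_of_positive_log_residuals(normalized_small):
    norm, _ = normalized_small
    rk = tax.rank_features(norm)
    res = rk.loc[rk["eligible"], "residual"].sort_values(ascending=False).to_numpy()
    expected = tax.find_elbow(np.log(res[res > 0]))
    assert int(rk["selected"].sum()) == expected


# ----------------------------------------------------------- batch correction

def test_single_batch_identity():
    proj = np.random.default_rng(0).normal(size=(30, 4))
    out = tax.correct_batches(proj, ["A"] * 30)
    np.testing.assert_array_equal(out, proj)


def test_batch_shift_reduced_fivefold():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(100, 3))
    b = rng.normal(size=(100, 3)) + np.array([5.0, 0, 0])  # shift along PC1
    proj = np.vstack([a, b])
    batches = np.array(["A"] * 100 + ["B"] * 100)
    before = np.linalg.norm(a.mean(0) - b.mean(0))
    out = tax.correct_batches(proj, batches)
    after = np.linalg.norm(out[:100].mean(0) - out[100:].mean(0))
    assert after < before / 5


def test_tiny_batch_passes_through_with_warning():
    proj = np.random.default_rng(0).normal(size=(12, 2))
    batches = ["A"] * 10 + ["B"] * 2
    with pytest.warns(UserWarning, match="<3 cells"):
        out = tax.correct_batches(proj, batches)
    np.testing.assert_array_equal(out[10:], proj[10:])


def test_batch_correction_improves_cluster_recovery():
    """Two planted clusters with a batch shift: ARI after correction is at
    least as good as before, and the corrected embedding recovers truth."""
    rng = np.random.default_rng(3)
    centers = np.array([[0, 0], [6.0, 6.0]])
    labels = np.repeat([0, 1], 60)
    pts = centers[labels] + rng.normal(0, 0.7, size=(120, 2))
    batches = np.tile(["A", "B"], 60)
    pts[batches == "B"] += np.array([12.0, 0.0])  # batch displacement
    from sklearn.cluster import KMeans

    km = lambda X: KMeans(2, n_init=5, random_state=0).fit_predict(X)
    ari_before = adjusted_rand_score(labels, km(pts))
    corrected = tax.correct_batches(pts, batches)
    ari_after = adjusted_rand_score(labels, km(corrected))
    assert ari_after >= ari_before
    assert ari_after == 1.0


# ------------------------------------------------------- perplexity / t-SNE

def test_perplexity_clip_small_n():
    proj = np.random.default_rng(0).normal(size=(12, 3))
    assert tax.choose_perplexity(proj, k_max=500) == 5.0


def test_perplexity_tracks_planted_cluster_size():
    rng = np.random.default_rng(5)
    centers = rng.normal(scale=20, size=(4, 5))
    proj = np.vstack([c + rng.normal(size=(100, 5)) for c in centers])
    perp = tax.choose_perplexity(proj)
    assert 50 <= perp <= 150  # within +/-50% of the 100-cell cluster size


def test_embedding_separates_planted_clusters():
    rng = np.random.default_rng(8)
    centers = rng.normal(scale=25, size=(4, 6))
    labels = np.repeat(np.arange(4), 50)
    proj = centers[labels] + rng.normal(size=(200, 6))
    coords = tax.embed_2d(proj, tax.EmbeddingConfig(seed=0, perplexity=30))
    from sklearn.metrics import silhouette_score

    assert silhouette_score(coords, labels) > 0.3


def test_identical_cells_embed_together():
    rng = np.random.default_rng(2)
    proj = rng.normal(size=(60, 4))
    proj[1] = proj[0]
    coords = tax.embed_2d(proj, tax.EmbeddingConfig(seed=0, perplexity=10))
    d01 = np.linalg.norm(coords[0] - coords[1])
    typical = np.median(
        np.linalg.norm(coords - coords.mean(0), axis=1)
    )
    assert d01 < typical / 10


# ---------------------------------------------------------------- clustering

def test_dbscan_two_blobs_exact():
    rng = np.random.default_rng(0)
    pts = np.vstack([rng.normal(0, 0.5, (80, 2)), rng.normal(10, 0.5, (80, 2))])
    cs = tax.cluster_embedding(pts, min_pts=5)
    truth = np.repeat([0, 1], 80)
    m = cs.labels.to_numpy() != -1
    assert len(cs.clusters()) == 2
    assert adjusted_rand_score(truth[m], cs.labels.to_numpy()[m]) == 1.0


def test_dbscan_huge_eps_single_cluster():
    pts = np.random.default_rng(1).normal(size=(50, 2))
    cs = tax.cluster_embedding(pts, eps=1e6, min_pts=3)
    assert len(cs.clusters()) == 1


def test_knn_outlier_reassignment_brute_force():
    coords = np.array(
        [[0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10], [0.5, 0.5]], float
    )
    labels = [0, 0, 0, 1, 1, 1, -1]
    out = tax.reassign_outliers_knn(coords, labels, k=3)
    assert out.iloc[6] == 0  # all 3 nearest non-outliers are cluster 0
    ident = tax.reassign_outliers_knn(coords[:6], labels[:6], k=3)
    assert list(ident) == labels[:6]


def test_knn_tie_takes_nearest_neighbor_label():
    coords = np.array([[0, 0], [2, 0], [0.9, 0]], float)
    labels = [0, 1, -1]
    # k=2 vote is tied 1-1; the outlier at x=0.9 is nearer to the x=0 point
    out = tax.reassign_outliers_knn(coords, labels, k=2)
    assert out.iloc[2] == 0


def test_within_cluster_order_follows_gradient():
    rng = np.random.default_rng(4)
    n = 30
    grad = np.linspace(0, 1, n)
    profile_a = np.r_[np.ones(10) * 40, np.ones(10) * 2]
    profile_b = np.r_[np.ones(10) * 2, np.ones(10) * 40]
    X = np.outer(1 - grad, profile_a) + np.outer(grad, profile_b)
    X += rng.normal(0, 0.5, (n, 20))
    ad = make_adata(X, normalized=True)
    order = tax.order_within_cluster(ad, list(ad.obs_names), seed=0)
    pos = np.array([int(c[1:]) for c in order])
    rho = abs(pd.Series(pos).corr(pd.Series(np.arange(n)), method="spearman"))
    assert rho > 0.9  # gradient order or its reverse
    assert tax.order_within_cluster(ad, ["c0", "c1"]) == ["c0", "c1"]


# ---------------------------------------------------------------- dendrogram

def _two_class_adata():
    rng = np.random.default_rng(6)
    base = rng.lognormal(1, 0.3, 30)
    X, labels = [], []
    for cl, (lo, hi) in enumerate([(0, 10), (5, 15), (15, 25), (20, 30)]):
        prof = base.copy()
        prof[lo:hi] *= 8  # clusters 0/1 and 2/3 share elevated blocks
        X.append(rng.poisson(prof, size=(20, 30)))
        labels += [cl] * 20
    ad = make_adata(np.vstack(X).astype(float), normalized=True)
    return ad, pd.Series(labels, index=ad.obs_names)


def test_dendrogram_root_separates_planted_classes():
    ad, labels = _two_class_adata()
    d = tax.build_dendrogram(ad, labels)
    junctions = list(d.junctions())
    _, left, right = junctions[-1]  # root is the last merge
    assert {frozenset(left), frozenset(right)} == {
        frozenset({0, 1}),
        frozenset({2, 3}),
    }
    assert sorted(d.leaf_order) == [0, 1, 2, 3]


def test_two_clusters_single_junction():
    ad, labels = _two_class_adata()
    lab2 = labels.map({0: 0, 1: 0, 2: 1, 3: 1})
    d = tax.build_dendrogram(ad, lab2)
    assert len(list(d.junctions())) == 1
    assert d.to_newick().endswith(";")


def test_leaf_order_optimal_among_tree_consistent_orders():
    """Optimal leaf ordering minimizes the sum of adjacent-leaf distances over
    every order reachable by flipping internal junctions."""
    from itertools import product

    from scipy.spatial.distance import pdist, squareform

    ad, labels = _two_class_adata()
    d = tax.build_dendrogram(ad, labels)
    logX = np.log2(np.asarray(ad.X) + 1)
    means = np.vstack([logX[(labels == c).to_numpy()].mean(0) for c in d.clusters])
    from sklearn.decomposition import PCA

    proj = PCA(n_components=3, random_state=0).fit_transform(means)
    D = squareform(pdist(proj, metric="correlation"))
    cost = lambda order: sum(D[order[i], order[i + 1]] for i in range(len(order) - 1))

    n = len(d.clusters)
    Z = d.linkage

    def orders(node, flips):
        if node < n:
            return [node]
        a, b = int(Z[node - n][0]), int(Z[node - n][1])
        left, right = orders(a, flips), orders(b, flips)
        return right + left if flips[node - n] else left + right

    all_costs = [
        cost(orders(2 * n - 2, f)) for f in product([False, True], repeat=n - 1)
    ]
    opt = cost([d.clusters.index(c) for c in d.leaf_order])
    assert opt <= min(all_costs) + 1e-12


def test_branch_marker_deltas_match_brute_force():
    genes = ["always", "leftonly", "partial"]
    X = np.array(
        # cluster 0        cluster 1        cluster 2        cluster 3
        [[5, 3, 1], [5, 2, 0], [5, 4, 1], [5, 1, 1], [5, 0, 0], [5, 0, 1], [5, 0, 0], [5, 0, 1]],
        float,
    )
    ad = make_adata(X, genes=genes, normalized=True)
    labels = pd.Series([0, 0, 1, 1, 2, 2, 3, 3], index=ad.obs_names)
    d = tax.build_dendrogram(ad, labels)
    table = tax.branch_markers(ad, d, labels, top_k=3)
    # independent recomputation of every junction delta
    frac = {
        c: (X[(labels == c).to_numpy()] > 0).mean(axis=0) for c in [0, 1, 2, 3]
    }
    for jid, left, right in d.junctions():
        lf = np.mean([frac[c] for c in left], axis=0)
        rf = np.mean([frac[c] for c in right], axis=0)
        sub = table[(table["junction"] == jid) & (table["side"] == "left")]
        for _, row in sub.iterrows():
            gi = genes.index(row["gene"])
            assert row["delta"] == pytest.approx(lf[gi] - rf[gi], abs=1e-12)
    assert table["delta"].between(-1, 1).all()
    # a gene positive everywhere has delta exactly 0 at every junction
    always = table[table["gene"] == "always"]
    assert (always["delta"] == 0).all()
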