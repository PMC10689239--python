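"""Activation calling, IEG score, enrichment and trapping DE.

The brute-force oracles here re-derive every statistic with plain Python
loops, independently of the vectorized implementation.
"""

import numpy as np
import pandas as pd
import pytest

from engramap import engram as eng
from engramap import qc
from engramap.simulate import CFC_TIMEPOINTS
from tests.conftest import make_adata

PANEL4 = ("Arc", "Fos", "Npas4", "Nr4a1")


def _toy(seed=0, n_cells=40, n_extra=6):
    rng = np.random.default_rng(seed)
    genes = list(PANEL4) + [f"x{i}" for i in range(n_extra)]
    X = rng.poisson(2.0, size=(n_cells, len(genes))).astype(float)
    X[rng.random(X.shape) < 0.5] = 0
    meta = {
        "timepoint": rng.choice(["HC", "2h", "8h"], n_cells),
        "cluster": rng.choice(["A", "B", "C"], n_cells),
    }
    return make_adata(X, genes=genes, meta=meta, normalized=True)


def test_thresholds_match_numpy_percentile_on_toy():
    ad = _toy()
    th = eng.activation_thresholds(ad, PANEL4, q=90)
    X = np.asarray(ad.X)
    for i, g in enumerate(PANEL4):
        assert th.theta[g] == pytest.approx(np.percentile(X[:, i], 90))


def test_threshold_zero_when_mostly_zero_gene():
    X = np.zeros((20, 4))
    X[0, 0] = 5.0  # zero in 95% of cells -> 90th percentile is 0
    ad = make_adata(X, genes=list(PANEL4), normalized=True)
    th = eng.activation_thresholds(ad, PANEL4, q=90)
    assert th.theta["Arc"] == 0.0
    flags = eng.flag_active(ad, th)
    assert flags["Arc"].sum() == 1  # falls back to expression > 0


def test_missing_panel_gene_reported():
    ad = make_adata(np.ones((3, 2)), genes=["Arc", "Fos"], normalized=True)
    with pytest.raises(KeyError, match="Npas4"):
        eng.activation_thresholds(ad, PANEL4, 90)


def test_flags_match_exhaustive_enumeration():
    ad = _toy(seed=3)
    th = eng.activation_thresholds(ad, PANEL4, q=90)
    flags = eng.flag_active(ad, th)
    X = np.asarray(ad.X)
    for c in range(ad.n_obs):
        any_flag = False
        for gi, g in enumerate(PANEL4):
            t = th.theta[g]
            expected = X[c, gi] > t if t > 0 else X[c, gi] > 0
            assert bool(flags.iloc[c][g]) == expected
            any_flag |= expected
        assert bool(flags.iloc[c]["any"]) == any_flag


def test_activation_tables_match_bruteforce_oracle():
    """F, S and score agree exactly with a plain-Python re-derivation on a
    50-cell matrix."""
    ad = _toy(seed=5, n_cells=50)
    th = eng.activation_thresholds(ad, PANEL4, q=75)
    flags = eng.flag_active(ad, th)
    clusters, tps = ad.obs["cluster"], ad.obs["timepoint"]
    order = ("HC", "2h", "8h")
    tab = eng.activation_tables(
        flags, clusters, tps, tp_order=order, cfc_keys=("2h", "8h"),
        min_cells=10, min_per_group=3,
    )
    for cl in ["A", "B", "C"]:
        for tp in order:
            cells = [
                i for i in range(50)
                if clusters.iloc[i] == cl and tps.iloc[i] == tp
            ]
            for g in PANEL4:
                if cells:
                    frac = sum(bool(flags.iloc[i][g]) for i in cells) / len(cells)
                    assert tab.F[cl].loc[g, tp] == pytest.approx(frac)
            if cells:
                s = sum(
                    sum(bool(flags.iloc[i][g]) for i in cells) / len(cells)
                    for g in PANEL4
                )
                assert tab.S.loc[cl, tp] == pytest.approx(s)
        expected_score = max(
            tab.S.loc[cl, t] - tab.S.loc[cl, "HC"] for t in ("2h", "8h")
        )
        assert tab.score[cl] == pytest.approx(expected_score)


def test_score_formula_forced_example():
    flags = pd.DataFrame(
        {"g1": [True] * 10, "any": [True] * 10},
        index=[f"c{i}" for i in range(10)],
    )
    # craft S directly: one cluster, known fractions per timepoint
    S = pd.Series({"HC": 0.4, "2h": 1.2, "8h": 0.9, "24h": 0.6, "recall": 0.5})
    score = max(S[t] - S["HC"] for t in CFC_TIMEPOINTS)
    assert score == pytest.approx(0.8)


def test_identical_S_gives_zero_score():
    n = 30
    rng = np.random.default_rng(0)
    X = np.tile(rng.poisson(3, size=(1, 4)).astype(float), (n, 1))
    meta = {
        "timepoint": np.tile(["HC", "2h", "8h", "24h", "recall"], n // 5),
        "cluster": ["A"] * n,
    }
    ad = make_adata(X, genes=list(PANEL4), meta=meta, normalized=True)
    th = eng.activation_thresholds(ad, PANEL4, 90)
    flags = eng.flag_active(ad, th)
    tab = eng.activation_tables(
        flags, ad.obs["cluster"], ad.obs["timepoint"], min_cells=5, min_per_group=3
    )
    assert tab.score["A"] == 0.0


def test_small_cluster_masks():
    ad = _toy(seed=1, n_cells=30)
    th = eng.activation_thresholds(ad, PANEL4, 90)
    flags = eng.flag_active(ad, th)
    tab = eng.activation_tables(
        flags, ad.obs["cluster"], ad.obs["timepoint"],
        tp_order=("HC", "2h", "8h"), cfc_keys=("2h", "8h"),
        min_cells=60, min_per_group=20,
    )
    assert tab.low_confidence.all()  # every cluster < 60 cells here
    assert tab.small_group.all()
    assert tab.score.notna().any()  # still reported, just masked


def test_observed_vs_expected_hand_toy():
    flags = pd.Series([True, True, False, False, True, False], index=list("abcdef"))
    clusters = pd.Series(["X", "X", "Y", "Y", "Z", "Z"], index=list("abcdef"))
    tps = pd.Series(["2h"] * 6, index=list("abcdef"))
    out = eng.observed_vs_expected(flags, clusters, tps).set_index("cluster")
    assert out.loc["X", "expected"] == pytest.approx(0.5)
    assert out.loc["X", "ratio"] == pytest.approx(1.0 / 0.5)
    assert out.loc["Y", "ratio"] == pytest.approx(0.0)
    assert out.loc["Z", "ratio"] == pytest.approx(1.0)


def test_uniform_activation_gives_unit_ratios():
    n = 60
    flags = pd.Series([True, False] * (n // 2))
    clusters = pd.Series((["X"] * 2 + ["Y"] * 2) * (n // 4))
    tps = pd.Series(["2h", "2h", "2h", "2h"] * (n // 4))
    out = eng.observed_vs_expected(flags, clusters, tps)
    np.testing.assert_allclose(out["ratio"], 1.0)


def test_cluster_holding_all_flags_ratio_is_inverse_share():
    flags = pd.Series([True] * 5 + [False] * 15)
    clusters = pd.Series(["X"] * 5 + ["Y"] * 15)
    tps = pd.Series(["2h"] * 20)
    out = eng.observed_vs_expected(flags, clusters, tps).set_index("cluster")
    assert out.loc["X", "ratio"] == pytest.approx(1 / 0.25)  # 1 / cluster share


def test_fold_change_identity_and_missing():
    rng = np.random.default_rng(2)
    n = 200
    X = rng.poisson(5.0, size=(n, 4)).astype(float)
    meta = {"timepoint": np.tile(["HC", "2h"], n // 2), "cluster": ["A"] * n}
    ad = make_adata(X, genes=list(PANEL4), meta=meta, normalized=True)
    th = eng.activation_thresholds(ad, PANEL4, 50)
    fc = eng.fold_change_dynamics(ad, th, ad.obs["cluster"], ad.obs["timepoint"])
    vals = fc["A"]["2h"].dropna()
    assert np.allclose(vals, 1.0, atol=0.25)  # identical distributions -> FC ~ 1
    # no qualifying cells: threshold above every observation
    th.theta[:] = X.max() + 1
    fc2 = eng.fold_change_dynamics(ad, th, ad.obs["cluster"], ad.obs["timepoint"])
    assert fc2["A"]["2h"].isna().all()


def test_trap_de_matches_hand_computation():
    X = np.array(
        [
            [8, 1, 0],
            [9, 2, 1],
            [7, 1, 0],
            [6, 3, 1],  # high group (flagged)
            [1, 1, 4],
            [0, 2, 5],
            [1, 1, 4],
            [2, 2, 6],  # low group
        ],
        float,
    )
    ad = make_adata(X, genes=["up", "flat", "down"], normalized=True)
    flags = pd.Series([True] * 4 + [False] * 4, index=ad.obs_names)
    res = eng.trap_de(ad, flags, list(ad.obs_names), min_per_side=4, min_mean_umi=0.0)
    logX = np.log2(X + 1)
    for gi, g in enumerate(["up", "flat", "down"]):
        expected = logX[:4, gi].mean() - logX[4:, gi].mean()
        assert res.table.loc[g, "d"] == pytest.approx(expected, abs=1e-12)
    assert res.top_up[0] == "up"
    assert res.top_down[0] == "down"


def test_trap_de_side_requirements():
    ad = make_adata(np.ones((6, 3)), normalized=True)
    flags = pd.Series([True] * 6, index=ad.obs_names)
    with pytest.raises(ValueError, match="nonempty"):
        eng.trap_de(ad, flags, list(ad.obs_names))


def test_de_frequency_hand_count():
    def mk(d_vals):
        t = pd.DataFrame({"d": pd.Series(d_vals)})
        t["mean_high"] = t["mean_low"] = t["mean_umi"] = 1.0
        return eng.TrapDEResult(table=t)

    results = {
        "c1": mk({"a": 0.6, "b": 0.7, "z": 0.1}),
        "c2": mk({"a": 0.9, "b": 0.2, "z": 0.8}),
        "c3": mk({"a": 0.55, "b": 0.51, "z": 0.0}),
    }
    classes = {"c1": "GABA", "c2": "GABA", "c3": "GABA"}
    out = eng.de_frequency(results, classes)["GABA"]
    assert out.loc["a", "frequency"] == 3
    assert out.loc["b", "frequency"] == 2
    assert out.loc["z", "frequency"] == 1
    assert list(out.index) == ["a", "b", "z"]
    # ties break alphabetically
    results["c2"].table.loc["b", "d"] = 0.9
    results["c1"].table.loc["z", "d"] = 0.9
    results["c3"].table.loc["z", "d"] = 0.9
    out2 = eng.de_frequency(results, classes)["GABA"]
    assert list(out2.index) == ["a", "b", "z"] or out2["frequency"].is_monotonic_decreasing


def test_group_de_shift_and_overlap_guard():
    rng = np.random.default_rng(7)
    a = rng.poisson(8.0, size=(300, 3)).astype(float)
    b = rng.poisson(4.0, size=(300, 3)).astype(float)  # log2FC ~ 1
    ad = make_adata(np.vstack([a, b]), genes=["g0", "g1", "g2"], normalized=True)
    cells_a = list(ad.obs_names[:300])
    cells_b = list(ad.obs_names[300:])
    d = eng.group_de(ad, cells_a, cells_b)
    assert np.allclose(d, np.log2(9 / 5), atol=0.2)  # log2((mu_a+1)/(mu_b+1)) approx
    with pytest.raises(ValueError, match="overlap"):
        eng.group_de(ad, cells_a, cells_a[:5] + cells_b)


def test_planted_engram_scores_track_activation(engram_dataset):
    """The planted engram type has the top IEG score and the score correlates
    with planted activation across types."""
    adata, truth = engram_dataset
    norm = qc.normalize_cells(adata)
    th = eng.activation_thresholds(norm, q=90)
    flags = eng.flag_active(norm, th)
    tab = eng.activation_tables(flags, truth.cells["type"], truth.cells["timepoint"])
    scores = tab.score.dropna()
    assert scores.idxmax() == "GABA-1"
    assert scores["GABA-1"] > scores.drop("GABA-1").max() + 0.2
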