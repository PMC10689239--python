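"""Percentile-based engram statistics.

A neuron is "activated" (IEG-high) if any gene of an eight-IEG activity panel
(Arc, Bdnf, Btg2, Fos, Fosl2, Homer1, Npas4, Nr4a1) exceeds that gene's
percentile threshold computed over all neurons pooled across timepoints
(90th percentile for the IEG score, 95th for in-silico trapping, 99th for
observed/expected enrichment). Per cluster, the fractions of activated cells
per panel gene and timepoint form an 8 x 5 matrix F; their per-timepoint sums
S give the IEG score = max over post-conditioning timepoints of S[t] - S[HC].
In-silico trapping compares IEG-high with IEG-low cells of the same type by
the difference d of mean log2(x+1) normalized expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .genesets import IEG_PANEL
from .simulate import CFC_TIMEPOINTS, DEFAULT_TIMEPOINTS


def _dense(adata: AnnData, genes=None) -> np.ndarray:
    X = adata[:, list(genes)].X if genes is not None else adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X, float)


@dataclass
class ActivationThresholds:
    """Per-panel-gene percentile thresholds over all pooled neurons."""

    panel: tuple[str, ...]
    q: float
    theta: pd.Series  # gene -> threshold in normalized expression units


def activation_thresholds(
    adata: AnnData, panel: tuple[str, ...] = IEG_PANEL, q: float = 90.0
) -> ActivationThresholds:
    """q-th percentile (linear interpolation, zeros included) of each panel
    gene's normalized expression over all cells of ``adata``."""
    missing = [g for g in panel if g not in adata.var_names]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {', '.join(missing)}")
    X = _dense(adata, panel)
    theta = pd.Series(np.percentile(X, q, axis=0), index=list(panel), name="theta")
    return ActivationThresholds(panel=tuple(panel), q=q, theta=theta)


def flag_active(adata: AnnData, thresholds: ActivationThresholds) -> pd.DataFrame:
    """Per-cell per-gene activation flags plus the any-gene OR column.

    A cell is flagged for gene g when expression strictly exceeds theta_g;
    if theta_g is 0 (gene zero in more than q% of cells) the rule falls back
    to expression > 0.
    """
    X = _dense(adata, thresholds.panel)
    th = thresholds.theta.to_numpy()
    flags = X > np.where(th > 0, th, 0.0)
    out = pd.DataFrame(flags, index=adata.obs_names, columns=list(thresholds.panel))
    out["any"] = flags.any(axis=1)
    return out


@dataclass
class ActivationTables:
    """Per-cluster activation fractions, sums and IEG scores."""

    F: dict  # cluster -> DataFrame (panel genes x timepoints)
    S: pd.DataFrame  # clusters x timepoints
    score: pd.Series  # cluster -> IEG score (NaN if HC missing)
    n_cells: pd.DataFrame  # clusters x timepoints
    low_confidence: pd.Series  # cluster too small (<min_cells total)
    small_group: pd.Series  # smallest timepoint group < min_per_group
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    hc_key: str = "HC"


def activation_tables(
    flags: pd.DataFrame,
    clusters: pd.Series,
    timepoints: pd.Series,
    tp_order: tuple[str, ...] = DEFAULT_TIMEPOINTS,
    hc_key: str = "HC",
    cfc_keys: tuple[str, ...] = CFC_TIMEPOINTS,
    min_cells: int = 60,
    min_per_group: int = 20,
) -> ActivationTables:
    """Fraction-activated matrices, their per-timepoint sums, and the IEG
    score per cluster.

    F[g, t] is the fraction of the cluster's cells at timepoint t flagged for
    panel gene g; S[t] = sum_g F[g, t]; the IEG score is the maximum over
    post-conditioning timepoints of S[t] - S[HC]. Clusters below ``min_cells``
    total, or with a timepoint group below ``min_per_group``, are reported but
    masked as low-confidence.
    """
    genes = [c for c in flags.columns if c != "any"]
    clusters = clusters.reindex(flags.index)
    timepoints = timepoints.reindex(flags.index)
    labels = sorted(c for c in clusters.dropna().unique() if c != -1)

    F, S_rows, n_rows, score, lowc, small = {}, {}, {}, {}, {}, {}
    for c in labels:
        m = (clusters == c).to_numpy()
        Fc = pd.DataFrame(index=genes, columns=list(tp_order), dtype=float)
        counts = {}
        for tp in tp_order:
            sel = m & (timepoints == tp).to_numpy()
            counts[tp] = int(sel.sum())
            Fc[tp] = flags.loc[sel, genes].mean(axis=0) if sel.any() else np.nan
        F[c] = Fc
        S = Fc.sum(axis=0, skipna=False)
        S_rows[c] = S
        n_rows[c] = pd.Series(counts)
        if counts.get(hc_key, 0) == 0 or np.isnan(S[hc_key]):
            score[c] = np.nan
        else:
            diffs = [S[t] - S[hc_key] for t in cfc_keys if counts.get(t, 0) > 0]
            score[c] = max(diffs) if diffs else np.nan
        total = sum(counts.values())
        lowc[c] = total < min_cells
        small[c] = min(counts.values()) < min_per_group
    return ActivationTables(
        F=F,
        S=pd.DataFrame(S_rows).T,
        score=pd.Series(score, name="ieg_score"),
        n_cells=pd.DataFrame(n_rows).T,
        low_confidence=pd.Series(lowc, name="low_confidence"),
        small_group=pd.Series(small, name="small_group"),
        timepoints=tuple(tp_order),
        hc_key=hc_key,
    )


def observed_vs_expected(
    any_flags: pd.Series, clusters: pd.Series, timepoints: pd.Series
) -> pd.DataFrame:
    """Observed per-cluster activated fraction per timepoint versus the
    fraction expected by chance (global activated fraction at that timepoint);
    ratio undefined where the expectation is 0."""
    df = pd.DataFrame(
        {"flag": any_flags, "cluster": clusters, "timepoint": timepoints}
    ).dropna()
    expected = df.groupby("timepoint")["flag"].mean()
    obs = df.groupby(["cluster", "timepoint"])["flag"].agg(["mean", "size"])
    obs = obs.rename(columns={"mean": "observed", "size": "n"}).reset_index()
    obs["expected"] = obs["timepoint"].map(expected)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs["ratio"] = np.where(
            obs["expected"] > 0, obs["observed"] / obs["expected"], np.nan
        )
    return obs


def fold_change_dynamics(
    adata: AnnData,
    thresholds: ActivationThresholds,
    clusters: pd.Series,
    timepoints: pd.Series,
    hc_key: str = "HC",
    eps: float = 0.1,
) -> dict:
    """Time-dynamic fold change of each panel gene: mean expression among
    cells exceeding theta_g at timepoint t (plus pseudocount eps) over the
    same conditional mean at HC. Missing where no cell qualifies."""
    X = _dense(adata, thresholds.panel)
    th = thresholds.theta.to_numpy()
    above = X > np.where(th > 0, th, 0.0)
    clusters = clusters.reindex(adata.obs_names)
    timepoints = timepoints.reindex(adata.obs_names)
    out = {}
    for c in sorted(x for x in clusters.dropna().unique() if x != -1):
        mc = (clusters == c).to_numpy()
        rows = {}
        for g_i, g in enumerate(thresholds.panel):
            def _cond_mean(tp):
                sel = mc & (timepoints == tp).to_numpy() & above[:, g_i]
                return X[sel, g_i].mean() if sel.any() else np.nan

            hc = _cond_mean(hc_key)
            rows[g] = {
                tp: ((_cond_mean(tp) + eps) / (hc + eps))
                if not np.isnan(hc) and not np.isnan(_cond_mean(tp))
                else np.nan
                for tp in pd.unique(timepoints.dropna())
            }
        out[c] = pd.DataFrame(rows).T
    return out


@dataclass
class TrapDEResult:
    """IEG-high versus IEG-low differential expression for one cell type."""

    table: pd.DataFrame  # gene-indexed: mean_high, mean_low, d, mean_umi
    top_up: list[str] = field(default_factory=list)
    top_down: list[str] = field(default_factory=list)
    n_high: int = 0
    n_low: int = 0


def _log_means(adata: AnnData, cells) -> pd.Series:
    X = _dense(adata[list(cells)])
    return pd.Series(np.log2(X + 1.0).mean(axis=0), index=adata.var_names)


def trap_de(
    adata: AnnData,
    any_flags: pd.Series,
    cells,
    raw_counts: AnnData | None = None,
    min_per_side: int = 5,
    top_n: int = 100,
    min_mean_umi: float = 1.0,
) -> TrapDEResult:
    """In-silico trapping DE: IEG-high versus IEG-low cells of one type.

    d = mean log2(x+1) normalized expression in the high group minus the low
    group. The top list keeps genes with mean raw UMI > ``min_mean_umi`` over
    the analyzed cells, the ``top_n`` largest d (and smallest, for the
    down-regulated list).
    """
    cells = list(cells)
    flags = any_flags.reindex(cells)
    high = [c for c, f in flags.items() if bool(f)]
    low = [c for c, f in flags.items() if not bool(f)]
    if not high or not low:
        raise ValueError(
            f"both sides must be nonempty (high={len(high)}, low={len(low)})"
        )
    if len(high) < min_per_side or len(low) < min_per_side:
        raise ValueError(
            f"need >= {min_per_side} cells per side (high={len(high)}, low={len(low)})"
        )
    mean_high = _log_means(adata, high)
    mean_low = _log_means(adata, low)
    d = mean_high - mean_low
    umi_src = raw_counts if raw_counts is not None else adata
    Xu = _dense(umi_src[cells])
    mean_umi = pd.Series(Xu.mean(axis=0), index=umi_src.var_names).reindex(d.index)
    table = pd.DataFrame(
        {"mean_high": mean_high, "mean_low": mean_low, "d": d, "mean_umi": mean_umi}
    )
    expressed = table[table["mean_umi"] > min_mean_umi]
    top_up = list(expressed.sort_values("d", ascending=False).head(top_n).index)
    top_down = list(expressed.sort_values("d", ascending=True).head(top_n).index)
    return TrapDEResult(
        table=table, top_up=top_up, top_down=top_down, n_high=len(high), n_low=len(low)
    )


def de_frequency(
    results: dict, classes: dict, d_threshold: float = 0.5
) -> dict[str, pd.DataFrame]:
    """Per class, rank genes by the number of clusters where d exceeds the
    threshold; ties break alphabetically."""
    by_class: dict[str, list] = {}
    for cluster, res in results.items():
        by_class.setdefault(classes[cluster], []).append(res.table["d"])
    out = {}
    for cls, ds in by_class.items():
        freq = sum((d > d_threshold).astype(int) for d in ds)
        tbl = pd.DataFrame({"frequency": freq})
        # alphabetical first, then stable sort by frequency -> ties alphabetical
        tbl = tbl.sort_index(kind="stable").sort_values(
            "frequency", ascending=False, kind="stable"
        )
        tbl["rank"] = np.arange(1, len(tbl) + 1)
        out[cls] = tbl
    return out


def group_de(adata: AnnData, cells_a, cells_b) -> pd.Series:
    """The trapping d statistic between two arbitrary disjoint cell groups
    (used for same-batch recall versus 2 h)."""
    a, b = list(cells_a), list(cells_b)
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"groups overlap on {len(overlap)} cells")
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    return (_log_means(adata, a) - _log_means(adata, b)).rename("d")
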