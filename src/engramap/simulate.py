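"""Synthetic data generator with planted ground truth.

Emulates the statistical structure of a cued-fear-conditioning (CFC)
single-cell experiment: three neurotransmitter classes (GABA, VGLUT1, VGLUT2)
plus optional non-neuronal cells, several cell types per class with
multiplicatively enriched marker genes, a five-timepoint design (home cage,
2 h, 8 h, 24 h post conditioning, and tone recall) collected in two batches
(batch A: HC-8h-24h; batch B: HC-2h-recall), planted IEG-high engram subsets,
planted coregulated gene modules driven by a log-normal latent factor,
per-batch gene-wise effects, cross-class doublets, Visium-style spatial spot
mixtures, voxelized in-situ "energy" atlases and two-channel fiber-photometry
traces.

Counts follow a gamma-Poisson (negative binomial) law with a dispersion shared
across genes; library sizes are log-normal. Every generator is a pure function
of its design and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .genesets import CLASS_MARKERS, IEG_PANEL, NONNEURONAL_MARKERS

NEURON_CLASSES = ("GABA", "VGLUT1", "VGLUT2")
DEFAULT_TIMEPOINTS = ("HC", "2h", "8h", "24h", "recall")
CFC_TIMEPOINTS = ("2h", "8h", "24h", "recall")
# Home-cage controls were collected in both batches; each CFC timepoint in one.
DEFAULT_BATCH_MAP: dict[str, tuple[str, ...]] = {
    "HC": ("A", "B"),
    "2h": ("B",),
    "8h": ("A",),
    "24h": ("A",),
    "recall": ("B",),
}


@dataclass(frozen=True)
class EngramSpec:
    """A planted activated (engram) subpopulation of one cell type.

    ``activation`` maps timepoint -> probability that a cell of this type is in
    the activated state; in activated cells the eight panel IEGs are scaled by
    ``panel_fold``.
    """

    type_id: str
    activation: dict[str, float]
    panel_fold: float = 5.0
    # optional activation signature: extra genes elevated 2**signature_log2fc
    # in activated cells (the coregulated program the trapping DE recovers)
    signature_genes: tuple[str, ...] = ()
    signature_log2fc: float = 1.5


@dataclass(frozen=True)
class ModuleSpec:
    """A planted coregulated gene module.

    In cells of the listed ``(type_id, timepoint)`` groups, all module genes
    share one log-normal latent factor exp(loading * z), z ~ N(0, 1) per cell,
    multiplicative on the expression rate.
    """

    genes: tuple[str, ...]
    # default loading calibrated to give mean pairwise Pearson r ~ 0.3 among
    # module genes in active groups of ~50 cells
    loading: float = 0.45
    active_groups: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class SynthDesign:
    """Full description of a synthetic CFC experiment."""

    n_types_per_class: dict[str, int] = field(
        default_factory=lambda: {"GABA": 4, "VGLUT1": 4, "VGLUT2": 4, "non-neuronal": 0}
    )
    cells_per_type_per_timepoint: int = 60
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    batch_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BATCH_MAP)
    )
    n_genes: int = 2000
    markers_per_type: int = 10
    marker_fold: float = 8.0
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.25
    dispersion: float = 0.3
    engram_spec: tuple[EngramSpec, ...] = ()
    module_spec: tuple[ModuleSpec, ...] = ()
    batch_effect_sd: float = 0.15
    doublet_rate: float = 0.02
    seed: int = 0

    # ------------------------------------------------------------------ layout
    def type_ids(self) -> list[str]:
        out = []
        for cls, n in self.n_types_per_class.items():
            out.extend(f"{cls}-{i + 1}" for i in range(n))
        return out

    def class_of(self, type_id: str) -> str:
        return type_id.rsplit("-", 1)[0]

    def neuron_type_ids(self) -> list[str]:
        return [t for t in self.type_ids() if self.class_of(t) in NEURON_CLASSES]

    def gene_names(self) -> list[str]:
        """Deterministic gene universe: panel IEGs, class markers, a few
        non-neuronal markers, per-type markers, module genes, generic filler."""
        names: list[str] = list(IEG_PANEL)
        for genes in CLASS_MARKERS.values():
            names.extend(genes)
        names.extend(NONNEURONAL_MARKERS[:6])
        for t in self.type_ids():
            names.extend(f"Mrk-{t}-{j + 1}" for j in range(self.markers_per_type))
        for spec in self.module_spec:
            names.extend(g for g in spec.genes if g not in names)
        for es in self.engram_spec:
            names.extend(g for g in es.signature_genes if g not in names)
        # de-dup preserving order
        names = list(dict.fromkeys(names))
        if len(names) > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {len(names)} named genes"
            )
        taken = set(names)
        k = 0
        while len(names) < self.n_genes:
            cand = f"Gene{k:05d}"
            if cand not in taken:
                names.append(cand)
            k += 1
        return names

    def marker_genes(self) -> dict[str, list[str]]:
        return {
            t: [f"Mrk-{t}-{j + 1}" for j in range(self.markers_per_type)]
            for t in self.type_ids()
        }

    def validate(self) -> None:
        if not self.type_ids():
            raise ValueError("design has no cell types")
        if self.cells_per_type_per_timepoint < 1:
            raise ValueError("cells_per_type_per_timepoint must be >= 1")
        if self.marker_fold <= 0 or self.library_size_mean <= 0:
            raise ValueError("folds and library size must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must be in [0, 1)")
        known = set(self.type_ids())
        for es in self.engram_spec:
            if es.type_id not in known:
                raise ValueError(f"engram type {es.type_id!r} not in design")
            if es.panel_fold <= 0:
                raise ValueError("panel_fold must be > 0")
            for tp, p in es.activation.items():
                if tp not in self.timepoints:
                    raise ValueError(f"engram timepoint {tp!r} not in design")
                if not (0.0 <= p <= 1.0):
                    raise ValueError("activation probabilities must be in [0, 1]")
        for ms in self.module_spec:
            if not ms.genes:
                raise ValueError("module gene list empty")
            for t, tp in ms.active_groups:
                if t not in known or tp not in self.timepoints:
                    raise ValueError(f"module group ({t}, {tp}) not in design")
        for tp in self.timepoints:
            if tp not in self.batch_map or not self.batch_map[tp]:
                raise ValueError(f"timepoint {tp!r} has no batch assignment")


@dataclass
class PlantedTruth:
    """Ground truth of a generated dataset."""

    cells: pd.DataFrame  # index=cell id; type, class, timepoint, batch, activated, doublet
    marker_genes: dict[str, list[str]]
    type_regions: dict[str, str]
    module_factors: pd.DataFrame | None = None  # cells x modules, NaN where inactive


# --------------------------------------------------------------------- counts

def _base_rates(design: SynthDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Per-type expression rate profile (types x genes), before normalization."""
    genes = design.gene_names()
    n_genes = len(genes)
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    rates = pd.DataFrame(
        np.tile(baseline, (len(design.type_ids()), 1)),
        index=design.type_ids(),
        columns=genes,
    )
    _apply_marker_rates(design, rates)
    return rates


def _apply_marker_rates(design: SynthDesign, rates: pd.DataFrame) -> None:
    """Set marker-gene rates in place (shared comparable levels).

    Neurotransmitter-class markers get a fixed high in-class rate and a near-
    zero off-class rate (real Gad2/Slc17a7/Slc17a6 are comparably strong, and
    the doublet ratio rule depends on that comparability). Type markers get a
    sparse off-type baseline fold-elevated in-type; signature genes a moderate
    shared level. Rates are expressed via the expected UMI per cell they
    produce at the design's library size.
    """
    # rate units are arbitrary (cells renormalize to probabilities), so the
    # per-count conversion depends on the final rate total; two fixed-point
    # sweeps settle it to well under a percent
    for _ in range(2):
        per_count = rates.sum(axis=1).mean() / design.library_size_mean

        marker_baseline = 0.25 * per_count  # ~0.25 UMI off-type
        for mk in design.marker_genes().values():
            rates.loc[:, mk] = marker_baseline
        for t, mk in design.marker_genes().items():
            rates.loc[t, mk] = marker_baseline * design.marker_fold

        class_hi, class_lo = 6.0 * per_count, 0.05 * per_count
        for cls, mk in CLASS_MARKERS.items():
            for t in design.type_ids():
                level = class_hi if design.class_of(t) == cls else class_lo
                rates.loc[t, list(mk)] = level
        nn_mk = list(NONNEURONAL_MARKERS[:6])
        for t in design.type_ids():
            level = class_hi if design.class_of(t) == "non-neuronal" else class_lo
            rates.loc[t, nn_mk] = level

        for es in design.engram_spec:
            for g in es.signature_genes:
                rates.loc[:, g] = 2.0 * per_count


def _region_assignment(design: SynthDesign, n_regions: int) -> dict[str, str]:
    types = design.type_ids()
    return {t: f"region{(i % n_regions) + 1}" for i, t in enumerate(types)}


def generate_counts(design: SynthDesign) -> tuple[AnnData, PlantedTruth]:
    """Sample a UMI count matrix plus its planted truth.

    Returns an :class:`anndata.AnnData` (cells x genes, integer counts in
    ``X``; ``obs`` columns animal/timepoint/batch) and the matching
    :class:`PlantedTruth`.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rates = _base_rates(design, rng)
    genes = list(rates.columns)
    gene_idx = {g: i for i, g in enumerate(genes)}
    panel_idx = np.array([gene_idx[g] for g in IEG_PANEL if g in gene_idx])
    engram_by_type = {es.type_id: es for es in design.engram_spec}

    batches = sorted({b for bs in design.batch_map.values() for b in bs})
    batch_fx = {
        b: np.exp(rng.normal(0.0, design.batch_effect_sd, size=len(genes)))
        for b in batches
    }

    rows: list[np.ndarray] = []
    meta: list[dict] = []
    mean_vectors: list[np.ndarray] = []
    module_cols = {i: [] for i in range(len(design.module_spec))}

    def _sample_cell(mean_rate: np.ndarray) -> np.ndarray:
        lib = rng.lognormal(
            np.log(design.library_size_mean), design.library_size_sigma
        )
        p = mean_rate / mean_rate.sum()
        lam = lib * p * rng.gamma(1.0 / design.dispersion, design.dispersion, len(p))
        return rng.poisson(lam)

    for t in design.type_ids():
        cls = design.class_of(t)
        base = rates.loc[t].to_numpy()
        es = engram_by_type.get(t)
        for tp in design.timepoints:
            for b in design.batch_map[tp]:
                for j in range(design.cells_per_type_per_timepoint):
                    rate = base * batch_fx[b]  # fresh array per cell
                    p_act = es.activation.get(tp, 0.0) if es is not None else 0.0
                    activated = bool(rng.random() < p_act) if p_act > 0 else False
                    if activated:
                        rate[panel_idx] *= es.panel_fold
                        if es.signature_genes:
                            sig = [gene_idx[g] for g in es.signature_genes]
                            rate[sig] *= 2.0**es.signature_log2fc
                    factors = {}
                    for mi, ms in enumerate(design.module_spec):
                        if (t, tp) in ms.active_groups:
                            z = rng.normal()
                            f = float(np.exp(ms.loading * z))
                            idx = [gene_idx[g] for g in ms.genes]
                            rate[idx] *= f
                            factors[mi] = f
                    rows.append(_sample_cell(rate))
                    mean_vectors.append(rate)
                    for mi in range(len(design.module_spec)):
                        module_cols[mi].append(factors.get(mi, np.nan))
                    meta.append(
                        {
                            "type": t,
                            "class": cls,
                            "timepoint": tp,
                            "batch": b,
                            "animal": f"m-{b}-{tp}-{j % 2 + 1}",
                            "activated": activated,
                            "doublet": False,
                        }
                    )

    n_singlets = len(rows)
    n_doublets = int(round(design.doublet_rate * n_singlets))
    classes = np.array([m["class"] for m in meta])
    for d in range(n_doublets):
        i = int(rng.integers(n_singlets))
        other = np.flatnonzero(classes != classes[i])
        j = int(rng.choice(other)) if other.size else int(rng.integers(n_singlets))
        rate = mean_vectors[i] + mean_vectors[j]
        rows.append(_sample_cell(rate))
        mi, mj = meta[i], meta[j]
        meta.append(
            {
                "type": f"doublet:{mi['type']}+{mj['type']}",
                "class": "doublet",
                "timepoint": mi["timepoint"],
                "batch": mi["batch"],
                "animal": mi["animal"],
                "activated": False,
                "doublet": True,
            }
        )
        for k in range(len(design.module_spec)):
            module_cols[k].append(np.nan)

    X = sparse.csr_matrix(np.vstack(rows).astype(np.int64))
    cell_ids = [f"cell{i:06d}" for i in range(X.shape[0])]
    obs = pd.DataFrame(meta, index=cell_ids)[
        ["animal", "timepoint", "batch", "type", "class", "activated", "doublet"]
    ]
    adata = AnnData(
        X=X,
        obs=obs[["animal", "timepoint", "batch"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["normalized"] = False

    mf = None
    if design.module_spec:
        mf = pd.DataFrame(
            {f"module{k}": v for k, v in module_cols.items()}, index=cell_ids
        )
    truth = PlantedTruth(
        cells=obs[["type", "class", "timepoint", "batch", "activated", "doublet"]],
        marker_genes=design.marker_genes(),
        type_regions=_region_assignment(design, n_regions=4),
        module_factors=mf,
    )
    return adata, truth


# -------------------------------------------------------------------- spatial

def generate_spatial(
    design: SynthDesign,
    n_spots: int = 400,
    n_regions: int = 4,
    library_size: float = 20000.0,
    dominant_alpha: float = 12.0,
    background_alpha: float = 0.3,
    seed: int | None = None,
):
    """Visium-style spot matrix: each spot is a noisy mixture of type profiles,
    dominated by the types assigned to its region.

    Returns ``(SpatialTarget, truth)`` where ``truth`` is a DataFrame of the
    mixture weights (spots x types) plus the type->region map in ``attrs``.
    """
    from .spatial import SpatialTarget

    design.validate()
    types = design.type_ids()
    if n_regions > len(types):
        raise ValueError(f"n_regions={n_regions} exceeds number of types {len(types)}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rates = _base_rates(design, np.random.default_rng(design.seed))
    type_regions = _region_assignment(design, n_regions)
    regions = [f"region{r + 1}" for r in range(n_regions)]

    side = int(np.ceil(np.sqrt(n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.column_stack([xs.ravel(), ys.ravel()])[:n_spots].astype(float)
    # vertical strips of equal width define the region mosaic
    strip = np.minimum((coords[:, 0] * n_regions / side).astype(int), n_regions - 1)
    spot_regions = pd.Series([regions[s] for s in strip], name="region")

    profiles = rates.to_numpy()
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    weights = np.empty((n_spots, len(types)))
    expr = np.empty((n_spots, profiles.shape[1]))
    for s in range(n_spots):
        alpha = np.full(len(types), background_alpha)
        for k, t in enumerate(types):
            if type_regions[t] == spot_regions.iloc[s]:
                alpha[k] = dominant_alpha
        w = rng.dirichlet(alpha)
        weights[s] = w
        mix = w @ profiles
        expr[s] = rng.poisson(library_size * mix)

    spot_ids = [f"spot{s:05d}" for s in range(n_spots)]
    target = SpatialTarget(
        mode="spots",
        expression=pd.DataFrame(expr, index=spot_ids, columns=rates.columns),
        coords=coords,
        regions=pd.Series(spot_regions.to_numpy(), index=spot_ids, name="region"),
    )
    truth = pd.DataFrame(weights, index=spot_ids, columns=types)
    truth.attrs["type_regions"] = type_regions
    return target, truth


def generate_voxel_atlas(
    design: SynthDesign,
    grid_shape: tuple[int, int, int] = (6, 8, 8),
    n_regions: int = 4,
    marker_energy: float = 8.0,
    background_energy: float = 2.0,
    seed: int | None = None,
):
    """Voxel 'energy' atlas: per-gene 3D grids with markers elevated in their
    type's region, plus deliberately invalid genes that violate each of the
    atlas quality thresholds (coverage, peak energy, mean energy).

    Returns ``(SpatialTarget, invalid_genes)``.
    """
    from .spatial import SpatialTarget

    design.validate()
    if np.prod(grid_shape) == 0:
        raise ValueError("empty voxel grid")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rates = _base_rates(design, np.random.default_rng(design.seed))
    type_regions = _region_assignment(design, n_regions)
    regions = [f"region{r + 1}" for r in range(n_regions)]

    n_vox = int(np.prod(grid_shape))
    zi, yi, xi = np.unravel_index(np.arange(n_vox), grid_shape)
    coords = np.column_stack([xi, yi, zi]).astype(float)
    strip = np.minimum(zi * n_regions // grid_shape[0], n_regions - 1)
    vox_regions = np.array([regions[s] for s in strip])

    genes = list(rates.columns)
    energy = rng.gamma(2.0, background_energy / 2.0, size=(len(genes), n_vox))
    region_mask = {r: vox_regions == r for r in regions}
    for t, mk in design.marker_genes().items():
        mask = region_mask[type_regions[t]]
        for g in mk:
            gi = genes.index(g)
            energy[gi, mask] += marker_energy
    # class markers follow their class's regions
    for cls, mks in CLASS_MARKERS.items():
        tps = [t for t in design.type_ids() if design.class_of(t) == cls]
        for g in mks:
            gi = genes.index(g)
            for t in tps:
                energy[gi, region_mask[type_regions[t]]] += marker_energy / max(len(tps), 1)

    # planted invalid genes, one per quality rule (strict > thresholds)
    invalid = {}
    v = np.zeros(n_vox)
    v[:30] = 10.0  # exactly 30 covered voxels -> fails coverage > 30
    invalid["Invalid-coverage"] = v
    v = np.full(n_vox, 4.0)  # wide coverage, high mean, but peak <= 5
    invalid["Invalid-energy"] = v
    v = np.zeros(n_vox)
    v[: max(31, n_vox // 8)] = 6.0  # peak fine, coverage fine, mean <= 0.2
    if v.mean() > 0.2:
        v *= 0.2 / v.mean() * 0.9
        v[0] = 6.0  # keep a peak above the energy threshold
    invalid["Invalid-mean"] = v
    invalid["Invalid-zero"] = np.zeros(n_vox)

    all_genes = genes + list(invalid)
    energy = np.vstack([energy] + [invalid[g][None, :] for g in invalid])

    vox_ids = [f"vox{i:05d}" for i in range(n_vox)]
    target = SpatialTarget(
        mode="voxels",
        expression=pd.DataFrame(energy.T, index=vox_ids, columns=all_genes),
        coords=coords,
        regions=pd.Series(vox_regions, index=vox_ids, name="region"),
        grid_shape=grid_shape,
    )
    return target, sorted(invalid)


# ----------------------------------------------------------------- photometry

def generate_photometry(
    n_events: int = 20,
    response_amp: float = 3.0,
    noise_sd: float = 1.0,
    bleach_rate: float = 1e-3,
    seed: int = 0,
    rate: float = 20.0,
    spacing: float = 30.0,
):
    """Two-channel fiber-photometry trace with planted post-event transients.

    The 465 nm (signal) channel carries an exponential bleaching trend, a
    motion artifact shared with the 405 nm isosbestic control, Gaussian noise,
    and an exponentially decaying transient after each event whose amplitude is
    calibrated so that the event-aligned pipeline reports a mean post-event
    z score of about ``response_amp`` (z units). The control channel has the
    trend, artifact and noise but no transient.
    """
    from .photometry import PhotometryTrace

    if rate <= 0:
        raise ValueError("sampling rate must be > 0")
    rng = np.random.default_rng(seed)
    duration = spacing * (n_events + 1)
    t = np.arange(0.0, duration, 1.0 / rate)
    events = spacing * (np.arange(n_events) + 1.0)

    trend = np.exp(-bleach_rate * t)
    # slow shared motion artifact: smoothed noise
    raw = rng.normal(0.0, 1.0, t.size)
    kernel = np.exp(-np.arange(0, 5 * rate) / rate)
    motion = np.convolve(raw, kernel / kernel.sum(), mode="same") * 0.02

    tau = 2.5
    post_window = 5.0
    # mean of exp(-x/tau) over the post window; used to express amplitude in z units
    mean_decay = tau / post_window * (1 - np.exp(-post_window / tau))
    bins_per = np.sqrt(rate * 0.5)
    f0, c0 = 100.0, 60.0
    # control-channel noise propagates through the affine fit into dF/F,
    # inflating the effective baseline noise by sqrt(1 + (f0/c0)^2)
    eff_noise = noise_sd * np.hypot(1.0, f0 / c0)
    amp_au = response_amp * eff_noise / (bins_per * mean_decay) if response_amp else 0.0
    transient = np.zeros_like(t)
    for ev in events:
        m = t >= ev
        transient[m] += amp_au * np.exp(-(t[m] - ev) / tau)

    signal = f0 * trend * (1 + motion) + transient + rng.normal(0, noise_sd, t.size)
    control = c0 * trend * (1 + motion) + rng.normal(0, noise_sd, t.size)
    trace = PhotometryTrace(time=t, signal_465=signal, control_405=control, rate=rate)
    return trace, events
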