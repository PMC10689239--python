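"""Editable gene-set configuration.

Every gene list used by the pipeline lives here as a plain constant so that
thresholds and panels are configuration, not literals buried in code. All lists
can be overridden per-run through :class:`engramap.config.AnalysisConfig`.
"""

from __future__ import annotations

# Activity panel used for engram (IEG^high) calling.
IEG_PANEL: tuple[str, ...] = (
    "Arc", "Bdnf", "Btg2", "Fos", "Fosl2", "Homer1", "Npas4", "Nr4a1",
)

# Immediate-early genes excluded from feature selection so that activity state
# does not drive cell-type clustering (53 genes).
IEG_EXCLUSION: tuple[str, ...] = (
    "Btg2", "Jun", "Egr4", "Fosb", "Junb", "Gadd45g", "Fos", "Arc", "Nr4a1",
    "Npas4", "Coq10b", "Tns1", "Per2", "Ptgs2", "Rnd3", "Tnfaip6", "Srxn1",
    "Tiparp", "Ccnl1", "Mcl1", "Dnajb5", "Nr4a3", "Fosl2", "Nptx2", "Rasl11a",
    "Mest", "Sertad1", "Egr2", "Midn", "Gadd45b", "Dusp6", "Irs2", "Plat",
    "Ier2", "Rrad", "Tpbg", "Csrnp1", "Peli1", "Per1", "Kdm6b", "Inhba",
    "Plk2", "Ifrd1", "Baz1a", "Trib1", "Pim3", "Lrrk2", "Dusp1", "Cdkn1a",
    "Pim1", "Sik1", "Frat2", "Dusp5",
)

SEX_GENES: tuple[str, ...] = ("Xist", "Tsix", "Eif2s3y", "Ddx3y", "Uty", "Kdm5d")

# Neurotransmitter-class markers for the majority vote.
CLASS_MARKERS: dict[str, tuple[str, ...]] = {
    "GABA": ("Gad2",),
    "VGLUT1": ("Slc17a7",),
    "VGLUT2": ("Slc17a6",),
}

# Combined non-neuronal marker list (25 genes) used both as the fourth vote
# category and as the exclusion set during neuronal feature selection.
NONNEURONAL_MARKERS: tuple[str, ...] = (
    "C1qc", "C1qa", "C1qb", "Gja1", "Cx3cr1", "Acta", "Ly6c1", "Mfge8",
    "Plxnb3", "Cldn11", "Aqp4", "Vtn", "Cldn5", "Pdgfrb", "Flt1", "Slc25a18",
    "Pdgfra", "Foxj1", "Olig1", "Olig2", "Sox10", "Hbb-bs", "Hbb-bt",
    "Hba-a2", "Ttr",
)

# Non-neuronal category markers (second-pass classification).
NONNEURONAL_CATEGORIES: dict[str, tuple[str, ...]] = {
    "immune": ("C1qc", "C1qa", "C1qb", "Mrc1", "Pf4", "Cx3cr1"),
    "astrocytes": ("Gja1", "Aqp4", "Foxj1", "Aldoc", "Mfge8", "Slc25a18"),
    "vascular": ("Vtn", "Cldn5", "Pdgfrb", "Flt1", "Acta2", "Ly6c1"),
    "oligodendrocytes": ("Plxnb3", "Cldn11", "Olig1", "Olig2", "Sox10", "Pdgfra"),
    "blood": ("Hbb-bs", "Hbb-bt", "Hba-a2", "Ttr"),
}

# Representative default packs for the seven coexpression-module categories.
# The shipped lists are editable stand-ins drawn from the activity-dependent
# transcription literature, not a curated supplement.
DEFAULT_MODULES: dict[str, tuple[str, ...]] = {
    "IEG": (
        "Arc", "Fos", "Fosb", "Fosl2", "Jun", "Junb", "Egr1", "Egr2", "Egr4",
        "Npas4", "Nr4a1", "Nr4a3", "Btg2", "Bdnf", "Homer1", "Nptx2", "Per1",
        "Dusp1",
    ),
    "learning_memory": (
        "Bdnf", "Ntrk2", "Vgf", "Camk2a", "Creb1", "Nlgn1", "Ppp3ca",
        "Syt4", "Scg2", "Dclk1", "Clstn3", "Ptprn",
    ),
    "glutamate_receptors": (
        "Gria1", "Gria2", "Gria3", "Gria4", "Grin1", "Grin2a", "Grin2b",
        "Grm1", "Grm5",
    ),
    "gaba_receptors": (
        "Gabra1", "Gabra2", "Gabrb1", "Gabrb2", "Gabrb3", "Gabrg2",
        "Gabbr1", "Gabbr2",
    ),
    "k_channels": (
        "Kcna1", "Kcna2", "Kcnb1", "Kcnc1", "Kcnd2", "Kcnq2", "Kcnv1", "Kcnf1",
    ),
    "ca_channels": (
        "Cacna1a", "Cacna1b", "Cacna1c", "Cacna1e", "Cacna2d1", "Cacnb1",
    ),
    "semaphorins": (
        "Sema3a", "Sema3e", "Sema4a", "Sema4d", "Sema5a", "Sema6a", "Sema7a",
    ),
}


def combined_module(modules: dict[str, tuple[str, ...]] | None = None) -> tuple[str, ...]:
    """All module gene lists combined (the 'correlation summary' set)."""
    modules = DEFAULT_MODULES if modules is None else modules
    seen: dict[str, None] = {}
    for genes in modules.values():
        for g in genes:
            seen.setdefault(g, None)
    return tuple(seen)
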