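import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from hypothesis import HealthCheck, settings

from engramap import qc
from engramap.simulate import EngramSpec, SynthDesign, generate_counts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_adata(counts, genes=None, cells=None, meta=None, normalized=False):
    """Small AnnData from a dense cells x genes array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(g)]
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(n)]
    obs = pd.DataFrame(index=cells)
    if meta is not None:
        for k, v in meta.items():
            obs[k] = list(v)
    ad = AnnData(X=counts.astype(float), obs=obs, var=pd.DataFrame(index=pd.Index(genes)))
    ad.uns["normalized"] = normalized
    return ad


@pytest.fixture(scope="session")
def small_design():
    return SynthDesign(
        n_types_per_class={"GABA": 2, "VGLUT1": 2, "VGLUT2": 2, "non-neuronal": 0},
        cells_per_type_per_timepoint=15,
        n_genes=300,
        doublet_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return generate_counts(small_design)


@pytest.fixture(scope="session")
def engram_design():
    return SynthDesign(
        n_types_per_class={"GABA": 2, "VGLUT1": 2, "VGLUT2": 2, "non-neuronal": 0},
        cells_per_type_per_timepoint=40,
        n_genes=300,
        doublet_rate=0.0,
        engram_spec=(EngramSpec("GABA-1", {"2h": 0.4, "24h": 0.4}, panel_fold=5.0),),
        seed=7,
    )


@pytest.fixture(scope="session")
def engram_dataset(engram_design):
    return generate_counts(engram_design)


@pytest.fixture(scope="session")
def normalized_small(small_dataset):
    adata, truth = small_dataset
    return qc.normalize_cells(adata), truth
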