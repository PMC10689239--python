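"""File I/O: MatrixMarket count matrices with sidecar TSVs, dense TSV
matrices, spot matrices with position CSVs, voxel atlases and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as scio
from scipy import sparse

from .spatial import SpatialTarget

META_COLUMNS = ("animal", "timepoint", "batch")


def _dedup(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}-{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    if any(seen.values()):
        dups = [n for n, k in seen.items() if k]
        warnings.warn(f"duplicate gene symbols disambiguated with suffixes: {dups[:5]}")
    return out


def read_counts(path: str | Path) -> AnnData:
    """Load a count matrix from a directory (matrix.mtx genes x cells,
    genes.tsv, barcodes.tsv, cell_metadata.tsv) or a dense TSV
    (genes x cells; metadata TSV alongside as <stem>_metadata.tsv)."""
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        with open(mtx) as fh:
            first = fh.readline()
        if not first.startswith("%%MatrixMarket"):
            raise ValueError(f"{mtx}:1: not a MatrixMarket header: {first.strip()!r}")
        M = scio.mmread(mtx).tocsr()  # genes x cells
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        meta = pd.read_csv(path / "cell_metadata.tsv", sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        M = sparse.csr_matrix(df.to_numpy())
        genes, barcodes = df.index.tolist(), df.columns.tolist()
        meta_path = path.with_name(path.stem + "_metadata.tsv")
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = [b for b in barcodes if b not in meta.index]
    extra = [b for b in meta.index if b not in barcodes]
    if missing or extra:
        raise ValueError(
            f"metadata/barcode mismatch: missing metadata for {missing[:5]}, "
            f"metadata without barcode for {extra[:5]}"
        )
    genes = _dedup(genes)
    adata = AnnData(
        X=M.T.tocsr(),
        obs=meta.loc[barcodes, [c for c in META_COLUMNS if c in meta.columns]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["normalized"] = False
    return adata


def write_counts(adata: AnnData, path: str | Path) -> None:
    """Write MTX (genes x cells) + genes.tsv + barcodes.tsv + cell_metadata.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    M = sparse.coo_matrix(X.T if sparse.issparse(X) else np.asarray(X).T)
    scio.mmwrite(path / "matrix.mtx", M)
    pd.Series(adata.var_names).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    adata.obs.to_csv(path / "cell_metadata.tsv", sep="\t")


def write_spots(target: SpatialTarget, path: str | Path) -> None:
    """Spot matrix as MTX (genes x spots) + genes.tsv + positions.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(target.expression.to_numpy().T))
    pd.Series(target.expression.columns).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pos = pd.DataFrame(
        {
            "spot_id": target.expression.index,
            "x": target.coords[:, 0],
            "y": target.coords[:, 1],
            "region": target.regions.to_numpy(),
        }
    )
    pos.to_csv(path / "positions.csv", index=False)


def read_spots(path: str | Path) -> SpatialTarget:
    path = Path(path)
    M = scio.mmread(path / "matrix.mtx").toarray().T  # spots x genes
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
    pos = pd.read_csv(path / "positions.csv")
    expr = pd.DataFrame(M, index=pos["spot_id"], columns=_dedup(genes))
    return SpatialTarget(
        mode="spots",
        expression=expr,
        coords=pos[["x", "y"]].to_numpy(float),
        regions=pd.Series(pos["region"].to_numpy(), index=pos["spot_id"], name="region"),
    )


def write_atlas(target: SpatialTarget, path: str | Path) -> None:
    """Voxel atlas as a single .npz container (runtime artifact)."""
    np.savez_compressed(
        Path(path),
        energy=target.expression.to_numpy(),
        genes=np.asarray(target.expression.columns, dtype=object),
        voxels=np.asarray(target.expression.index, dtype=object),
        coords=target.coords,
        regions=target.regions.to_numpy().astype(object),
        grid_shape=np.asarray(target.grid_shape or ()),
    )


def read_atlas(path: str | Path) -> SpatialTarget:
    z = np.load(Path(path), allow_pickle=True)
    vox = list(z["voxels"])
    return SpatialTarget(
        mode="voxels",
        expression=pd.DataFrame(z["energy"], index=vox, columns=list(z["genes"])),
        coords=z["coords"],
        regions=pd.Series(z["regions"], index=vox, name="region"),
        grid_shape=tuple(int(x) for x in z["grid_shape"]) or None,
    )


# ------------------------------------------------------------------ manifest

def config_hash(cfg_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path: str | Path, cfg_dict: dict, seed: int, outputs: dict) -> dict:
    from . import __version__

    manifest = {
        "config_hash": config_hash(cfg_dict),
        "seed": int(seed),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
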