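"""Plain-text readers and writers (MatrixMarket, TSV, TIFF, channel maps)."""

from __future__ import annotations

import pathlib
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile
import yaml


def write_counts(adata: ad.AnnData, outdir: str | pathlib.Path) -> None:
    """Write counts as gene x cell MatrixMarket plus genes/barcodes/annotation TSVs."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.csr_matrix(X.T if not sp.issparse(X) else X.T)  # genes x cells
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat)
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    ann = adata.obs.reset_index().rename(columns={"index": "cell_id"})
    cols = [c for c in ("cell_id", "cell_type", "sample_id", "group_id") if c in ann.columns]
    ann[cols].to_csv(outdir / "annotation.tsv", sep="\t", index=False)


def read_counts(indir: str | pathlib.Path) -> ad.AnnData:
    """Read the layout written by :func:`write_counts` back into an AnnData."""
    indir = pathlib.Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx"))  # genes x cells
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=sp.csr_matrix(mat.T),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    ann_path = indir / "annotation.tsv"
    if ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t").set_index("cell_id")
        adata.obs = adata.obs.join(ann.astype(str))
    return adata


def read_dense_counts(path: str | pathlib.Path) -> ad.AnnData:
    """Read a dense gene x cell TSV (first column gene ids, header cell ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ad.AnnData(
        X=df.to_numpy().T,
        obs=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(df.index.astype(str), name="gene_id")),
    )


def read_annotation(path: str | pathlib.Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "cell_type", "sample_id", "group_id"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return ann.set_index("cell_id")


def write_image(path: str | pathlib.Path, image: np.ndarray, channels: list[str]) -> None:
    """Write a (H, W, C) image as a multichannel TIFF plus a channel-map YAML."""
    path = pathlib.Path(path)
    tifffile.imwrite(
        path, np.moveaxis(image, -1, 0), photometric="minisblack"
    )  # CHW planes
    channel_map = {name: i for i, name in enumerate(channels)}
    with open(path.with_suffix(".channels.yaml"), "w") as fh:
        yaml.safe_dump(channel_map, fh)


def read_channel_map(path: str | pathlib.Path) -> dict[str, int]:
    with open(path) as fh:
        cm = yaml.safe_load(fh)
    if not isinstance(cm, Mapping) or not all(isinstance(v, int) for v in cm.values()):
        raise ValueError("channel map must be a mapping of marker name -> channel index")
    return dict(cm)


def read_image(path: str | pathlib.Path, channel_map: Mapping[str, int]) -> "MultichannelImage":
    from tmekit.mxif import MultichannelImage

    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None, :, :]
    names = [None] * planes.shape[0]
    for marker, idx in channel_map.items():
        if idx < 0 or idx >= planes.shape[0]:
            raise ValueError(f"channel map index {idx} for {marker!r} out of range")
        names[idx] = marker
    names = [n if n is not None else f"channel{i}" for i, n in enumerate(names)]
    return MultichannelImage(pixels=np.moveaxis(planes, 0, -1), channel_names=names)
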