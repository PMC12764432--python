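"""Readers and writers for the pipeline's on-disk formats.

Single-cell counts travel as a 10x-style Matrix Market triplet
(``matrix.mtx`` genes × cells, ``features.tsv``, ``barcodes.tsv``) plus a
cell-metadata TSV; repertoires as contig TSVs; signatures as GMT (two
records per signature, ``NAME_UP`` and ``NAME_DN``). All writers are
deterministic (fixed float formatting, sorted JSON keys) so that repeated
runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .de import GeneSignature

__all__ = [
    "write_mtx_dir", "read_mtx_dir", "write_tsv", "read_tsv",
    "write_gmt", "read_gmt", "write_json",
]

FLOAT_FORMAT = "%.6g"


def write_mtx_dir(cells: ad.AnnData, outdir: str | Path) -> Path:
    """Write counts as a 10x-style MTX triplet plus ``cell_metadata.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = cells.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64))  # genes x cells
    pd.Series(cells.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(cells.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    cells.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t")
    return outdir


def read_mtx_dir(indir: str | Path) -> ad.AnnData:
    """Read a triplet written by :func:`write_mtx_dir` back into AnnData."""
    indir = Path(indir)
    X = spio.mmread(indir / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=cells.astype(str))
    meta_path = indir / "cell_metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    return ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=genes.astype(str))
    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gmt(signatures: list[GeneSignature], path: str | Path) -> Path:
    """Write signatures as GMT, one ``_UP`` and one ``_DN`` record each."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for sig in signatures:
            desc = sig.provenance.get("mode", "na")
            fh.write("\t".join([f"{sig.name}_UP", str(desc)] + list(sig.up_genes)) + "\n")
            fh.write("\t".join([f"{sig.name}_DN", str(desc)] + list(sig.down_genes)) + "\n")
    return path


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read GMT records, pairing ``NAME_UP``/``NAME_DN`` into signatures."""
    records: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            full, genes = parts[0], [g for g in parts[2:] if g]
            if full.endswith("_UP"):
                records.setdefault(full[:-3], {})["up"] = genes
            elif full.endswith("_DN"):
                records.setdefault(full[:-3], {})["down"] = genes
            else:
                records.setdefault(full, {})["up"] = genes
    return [
        GeneSignature(
            name=name,
            up_genes=rec.get("up", []),
            down_genes=rec.get("down", []),
            provenance={"source": str(path)},
        )
        for name, rec in records.items()
    ]


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_to_jsonable(v) for v in sorted(obj, key=str) ] \
            if isinstance(obj, set) else [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_to_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
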