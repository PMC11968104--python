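"""Reading and writing the on-disk formats used across the pipeline.

Count matrices travel as Matrix Market MTX (cells x genes) with TSV sidecars
``cells.tsv`` (genotype, run, cluster) and ``genes.tsv`` (symbol, mito flag);
in memory they are :class:`anndata.AnnData` objects with those columns in
``.obs`` / ``.var``. DE tables, orthologue maps and reference panels are plain
TSV read into pandas DataFrames.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

OBS_COLUMNS = ("genotype", "run", "cluster")
VAR_COLUMNS = ("mito",)


def write_cohort(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write a cohort as ``matrix.mtx`` + ``cells.tsv`` + ``genes.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X, field="integer")
    obs = adata.obs.copy()
    obs.index.name = "cell_id"
    obs.to_csv(outdir / "cells.tsv", sep="\t")
    var = adata.var.copy()
    var.index.name = "gene"
    var.to_csv(outdir / "genes.tsv", sep="\t")
    return outdir


def read_cohort(indir: str | Path) -> ad.AnnData:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0, dtype={"cluster": str})
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    if "mito" in var:
        var["mito"] = var["mito"].astype(bool)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    for col in ("genotype", "run", "cluster"):
        if col in obs:
            obs[col] = obs[col].astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table (columns gene, lfc, p, p_adj, method) as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ortholog_map(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write an orthologue map TSV with columns fly_gene, human_gene, score."""
    pairs.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["score"] = df["score"].astype(int)
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a reference panel (genes x profiles) as TSV."""
    panel.to_csv(path, sep="\t", index_label="gene")


def read_panel(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
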