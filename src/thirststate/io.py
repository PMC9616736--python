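"""Readers and writers for the on-disk exchange formats.

Counts travel as Matrix Market (genes x cells, CellRanger orientation)
with ``genes.tsv`` / ``barcodes.tsv`` label files and a cell-metadata
CSV; traces as long-format CSV (cell, frame, F); synapse tables as CSV;
skeletons as SWC (see :mod:`thirststate.vicinity`).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .errors import DataError
from .synthetic_data import TraceSet

__all__ = ["write_counts", "read_counts", "write_traces", "read_traces"]


def write_counts(adata: AnnData, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(os.path.join(outdir, "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    adata.obs.to_csv(os.path.join(outdir, "cells.csv"))


def read_counts(indir) -> AnnData:
    mtx = os.path.join(indir, "matrix.mtx")
    if not os.path.exists(mtx):
        raise DataError(f"no matrix.mtx in {indir}")
    X = sparse.csr_matrix(spio.mmread(mtx)).T
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", header=None)[0]
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)[0]
    obs_path = os.path.join(indir, "cells.csv")
    obs = (
        pd.read_csv(obs_path, index_col=0)
        if os.path.exists(obs_path)
        else pd.DataFrame(index=barcodes)
    )
    obs.index = obs.index.astype(str)
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes.astype(str)))
    return adata


def write_traces(traces: TraceSet, path) -> None:
    traces.to_frame().to_csv(path, index=False)


def read_traces(path, frame_rate: float, onset_s: float, offset_s: float,
                drug: str = "drug") -> TraceSet:
    df = pd.read_csv(path)
    for col in ("cell", "frame", "F"):
        if col not in df.columns:
            raise DataError(f"trace table missing column: {col}")
    wide = df.pivot(index="cell", columns="frame", values="F").sort_index(axis=1)
    if wide.isna().any().any():
        raise DataError("trace table has missing frames")
    return TraceSet(
        values=wide.to_numpy(float),
        frame_rate=frame_rate,
        onset_s=onset_s,
        offset_s=offset_s,
        cell_ids=wide.index.tolist(),
        drug=drug,
    )
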