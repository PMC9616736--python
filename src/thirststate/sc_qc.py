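"""Barcode-level QC, bimodal expression thresholding, and marker
co-expression doublet detection.

The QC rule discards barcodes with fewer than 300 or more than 4,500
detected features, more than 20,000 UMIs, or excessive mitochondrial,
rRNA, or ribosomal-protein fractions.  Boundary values are kept: only
strict violations are discarded.

Doublet detection exploits mutual exclusivity of the glial marker nrv2
and the fast-transmitter markers VAChT, VGlut, and Gad1: a barcode with
two or more of these genes above their per-gene thresholds is flagged as
a class doublet.  Within Kenyon cells, co-expression of more than one
subtype marker (Ca-alpha1T for alpha/beta, ab for gamma, CG8641 for
alpha'/beta') flags a KC doublet.  Per-gene thresholds are estimated as
the local density minimum between the two modes of each gene's
non-zero expression distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.stats import gaussian_kde

from .errors import DataError, InsufficientDataError

__all__ = [
    "QCThresholds",
    "MarkerThresholds",
    "compute_qc_metrics",
    "filter_barcodes",
    "lognormalize",
    "zscale",
    "estimate_bimodal_threshold",
    "marker_frame",
    "flag_coexpression_doublets",
    "merge_doublet_calls",
]

MITO_PREFIXES = ("mt:",)
RRNA_PREFIXES = ("lncRNA:rRNA",)
RIBO_PREFIXES = ("RpL", "RpS")

QC_METRIC_COLUMNS = ("n_features", "total_umis", "frac_mito", "frac_rrna", "frac_ribo")


@dataclass
class QCThresholds:
    min_features: int = 300
    max_features: int = 4500
    max_umis: int = 20000
    max_mito: float = 0.15
    max_rrna: float = 0.10
    max_ribo: float = 0.15

    def __post_init__(self):
        if self.min_features >= self.max_features:
            raise DataError("min_features must be < max_features")
        for f in (self.max_mito, self.max_rrna, self.max_ribo):
            if not (0.0 <= f <= 1.0):
                raise DataError("QC fraction thresholds must be in [0, 1]")


@dataclass
class MarkerThresholds:
    """Per-marker thresholds on the normalized/scaled expression layer.

    Defaults are the reference values estimated on the original study's
    data; on other data (or synthetic data) re-estimate them with
    :func:`estimate_bimodal_threshold`.
    """

    class_markers: dict = field(
        default_factory=lambda: {"nrv2": 3.0, "VAChT": 1.5, "VGlut": 2.1, "Gad1": 2.3}
    )
    kc_markers: dict = field(
        default_factory=lambda: {"Ca-alpha1T": 1.5, "ab": 1.5, "CG8641": 2.2}
    )

    def __post_init__(self):
        for d in (self.class_markers, self.kc_markers):
            for g, t in d.items():
                if t < 0:
                    raise DataError(f"marker threshold for {g} must be >= 0")


def _frac(counts_sub, totals):
    out = np.zeros_like(totals, dtype=float)
    nz = totals > 0
    out[nz] = counts_sub[nz] / totals[nz]
    return out


def compute_qc_metrics(
    adata: AnnData,
    mito_prefixes=MITO_PREFIXES,
    rrna_prefixes=RRNA_PREFIXES,
    ribo_prefixes=RIBO_PREFIXES,
) -> pd.DataFrame:
    """Add per-cell QC metrics to ``adata.obs`` and return them.

    Gene families are identified by name prefix (configurable: the
    mito/rRNA/ribosomal gene sets are not hard-coded).
    """
    X = adata.X
    if sparse.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
        n_feat = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        totals = X.sum(axis=1)
        n_feat = (X > 0).sum(axis=1)
    names = np.asarray(adata.var_names)

    def family(prefixes):
        mask = np.zeros(len(names), dtype=bool)
        for p in prefixes:
            mask |= np.char.startswith(names.astype(str), p)
        sub = X[:, mask]
        s = np.asarray(sub.sum(axis=1)).ravel() if sparse.issparse(sub) else sub.sum(axis=1)
        return _frac(s, totals)

    adata.obs["n_features"] = n_feat
    adata.obs["total_umis"] = totals
    adata.obs["frac_mito"] = family(mito_prefixes)
    adata.obs["frac_rrna"] = family(rrna_prefixes)
    adata.obs["frac_ribo"] = family(ribo_prefixes)
    return adata.obs[list(QC_METRIC_COLUMNS)]


def filter_barcodes(cells: pd.DataFrame, thr: QCThresholds = None) -> np.ndarray:
    """Boolean keep-mask over cells; True = barcode passes QC.

    ``cells`` must carry the columns of ``QC_METRIC_COLUMNS`` (as
    produced by :func:`compute_qc_metrics`).  Boundary values are kept.
    """
    thr = thr or QCThresholds()
    if isinstance(cells, AnnData):
        cells = cells.obs
    missing = [c for c in QC_METRIC_COLUMNS if c not in cells.columns]
    if missing:
        raise DataError(f"missing QC metric column(s): {missing}")
    f = cells["n_features"].to_numpy()
    u = cells["total_umis"].to_numpy()
    return (
        (f >= thr.min_features)
        & (f <= thr.max_features)
        & (u <= thr.max_umis)
        & (cells["frac_mito"].to_numpy() <= thr.max_mito)
        & (cells["frac_rrna"].to_numpy() <= thr.max_rrna)
        & (cells["frac_ribo"].to_numpy() <= thr.max_ribo)
    )


def lognormalize(adata: AnnData, scale: float = 1e4, layer: str = "lognorm") -> AnnData:
    """log1p of counts-per-``scale`` library-size normalization."""
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals = np.where(totals > 0, totals, 1.0)
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X, float)
    adata.layers[layer] = np.log1p(dense * (scale / totals[:, None]))
    return adata

def zscale(adata: AnnData, source: str = "lognorm", layer: str = "scaled") -> AnnData:
    """Per-gene z-scaling of a normalized layer (zero-variance genes stay 0)."""
    X = adata.layers[source]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    adata.layers[layer] = (X - mu) / sd
    return adata


def estimate_bimodal_threshold(
    values,
    min_n: int = 50,
    bw_method="scott",
    grid_size: int = 512,
):
    """Threshold separating the two modes of a (putatively) bimodal sample.

    A Gaussian KDE is evaluated on a regular grid over the data range;
    if at least two local maxima exist, the abscissa of the density
    minimum between the two highest maxima is returned with flag
    ``"bimodal"``; otherwise ``(None, "unimodal")``.

    Intended for the non-zero normalized/scaled expression values of one
    gene, mirroring manual threshold setting on a bimodal histogram.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < min_n:
        raise InsufficientDataError(
            f"need >= {min_n} values for threshold estimation, got {v.size}"
        )
    if np.ptp(v) == 0:
        return None, "unimodal"
    kde = gaussian_kde(v, bw_method=bw_method)
    xs = np.linspace(v.min(), v.max(), grid_size)
    d = kde(xs)
    # interior local maxima (endpoints count if they dominate their neighbor)
    maxima = [0] if d[0] > d[1] else []
    maxima += [
        i for i in range(1, grid_size - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    if d[-1] > d[-2]:
        maxima.append(grid_size - 1)
    if len(maxima) < 2:
        return None, "unimodal"
    top_two = sorted(sorted(maxima, key=lambda i: d[i], reverse=True)[:2])
    lo, hi = top_two
    j = lo + int(np.argmin(d[lo : hi + 1]))
    return float(xs[j]), "bimodal"


def marker_frame(adata: AnnData, genes, layer: str = "lognorm") -> pd.DataFrame:
    """Cells x markers expression table from a named layer."""
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise DataError(f"marker gene(s) absent from data: {missing}")
    idx = [adata.var_names.get_loc(g) for g in genes]
    X = adata.layers[layer] if layer is not None else adata.X
    sub = X[:, idx]
    if sparse.issparse(sub):
        sub = sub.toarray()
    return pd.DataFrame(sub, index=adata.obs_names, columns=list(genes))


def flag_coexpression_doublets(
    expr: pd.DataFrame,
    thresholds: MarkerThresholds = None,
    kc_mask: Optional[np.ndarray] = None,
):
    """Flag doublets by marker co-expression.

    ``expr`` is a cells x markers table of normalized/scaled expression
    (see :func:`marker_frame`).  A cell is a "class-doublet" when two or
    more of the class markers strictly exceed their thresholds; among
    cells in ``kc_mask`` (Kenyon-cell-designated), a "KC-doublet" when
    more than one KC subtype marker exceeds its threshold.

    Returns ``(mask, reasons)`` where ``reasons`` is a per-cell Series of
    comma-joined fired markers prefixed by the rule that flagged them
    (empty string for singlets).
    """
    thresholds = thresholds or MarkerThresholds()
    missing = [g for g in thresholds.class_markers if g not in expr.columns]
    if missing:
        raise DataError(f"marker gene(s) absent from expression table: {missing}")

    n = len(expr)
    reasons = np.full(n, "", dtype=object)
    mask = np.zeros(n, dtype=bool)

    cls = thresholds.class_markers
    fired = np.column_stack([expr[g].to_numpy() > t for g, t in cls.items()])
    is_class_doublet = fired.sum(axis=1) >= 2
    mask |= is_class_doublet
    genes = list(cls)
    for i in np.flatnonzero(is_class_doublet):
        which = [genes[k] for k in np.flatnonzero(fired[i])]
        reasons[i] = "class-doublet:" + "+".join(which)

    if kc_mask is not None:
        kc_mask = np.asarray(kc_mask, bool)
        kcg = [g for g in thresholds.kc_markers if g in expr.columns]
        if len(kcg) < len(thresholds.kc_markers):
            missing = sorted(set(thresholds.kc_markers) - set(kcg))
            raise DataError(f"KC marker gene(s) absent from expression table: {missing}")
        kc_fired = np.column_stack(
            [expr[g].to_numpy() > thresholds.kc_markers[g] for g in kcg]
        )
        is_kc_doublet = kc_mask & (kc_fired.sum(axis=1) > 1)
        mask |= is_kc_doublet
        for i in np.flatnonzero(is_kc_doublet):
            which = [kcg[k] for k in np.flatnonzero(kc_fired[i])]
            tag = "KC-doublet:" + "+".join(which)
            reasons[i] = (reasons[i] + ";" + tag) if reasons[i] else tag

    return mask, pd.Series(reasons, index=expr.index, name="doublet_reason")


def merge_doublet_calls(coexpr_mask, external_mask=None):
    """Union of co-expression doublet calls with external (e.g. score-based)
    calls, plus a summary of per-method counts, overlap, and the removed
    fraction."""
    a = np.asarray(coexpr_mask, bool)
    if external_mask is None:
        b = np.zeros_like(a)
    else:
        b = np.asarray(external_mask, bool)
        if b.shape != a.shape:
            raise DataError(
                f"doublet call length mismatch: {a.shape} vs {b.shape}"
            )
    final = a | b
    summary = {
        "n_cells": int(a.size),
        "n_coexpression": int(a.sum()),
        "n_external": int(b.sum()),
        "n_overlap": int((a & b).sum()),
        "n_removed": int(final.sum()),
        "fraction_removed": float(final.sum() / a.size) if a.size else 0.0,
    }
    return final, summary
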