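"""Pseudo-bulk expression profiles.

A cell type is represented by the per-gene arithmetic mean of per-cell
log(CPM+1); no cross-cell-type comparison or specificity measure is
computed.  Filtering happens once on the annotated matrix: cell types
represented by too few cells are dropped first, then genes that are zero
in more than ``max_zero_fraction`` of the remaining cells.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import RunConfig

logger = logging.getLogger(__name__)


def filter_counts(adata: ad.AnnData, config: RunConfig) -> ad.AnnData:
    """Drop under-represented cell types, then near-silent genes.

    Cell types with fewer than ``config.min_cells_per_type`` cells are
    removed; then genes whose zero fraction across all retained cells is
    strictly greater than ``config.max_zero_fraction`` are removed.

    Raises
    ------
    ValueError
        If no cell type or no gene survives.
    """
    if "cell_type" not in adata.obs:
        raise ValueError("counts must carry a cell_type annotation")
    sizes = adata.obs["cell_type"].value_counts()
    keep_types = sizes.index[sizes >= config.min_cells_per_type]
    if len(keep_types) == 0:
        raise ValueError(
            f"no cell type has >= {config.min_cells_per_type} cells "
            f"(largest: {sizes.max() if len(sizes) else 0})"
        )
    out = adata[adata.obs["cell_type"].isin(keep_types)].copy()

    X = out.X
    n_cells = out.n_obs
    if sp.issparse(X):
        nonzero_per_gene = X.getnnz(axis=0)
    else:
        nonzero_per_gene = np.count_nonzero(X, axis=0)
    zero_fraction = 1.0 - nonzero_per_gene / n_cells
    keep_genes = zero_fraction <= config.max_zero_fraction  # "more than" is strict
    if not keep_genes.any():
        raise ValueError(
            f"no gene passes the zero-fraction filter "
            f"({config.max_zero_fraction:.0%}) across {n_cells} cells"
        )
    out = out[:, keep_genes].copy()
    logger.info(
        "expression filters: kept %d/%d cell types, %d/%d cells, %d/%d genes",
        len(keep_types), len(sizes), out.n_obs, adata.n_obs, out.n_vars, adata.n_vars,
    )
    return out


def pseudobulk(adata: ad.AnnData, config: RunConfig) -> pd.DataFrame:
    """Average per-cell log(CPM+1) within each cell type.

    Each cell's counts are scaled to sum to 1e6 (CPM), log-transformed
    with ``log(x + 1)`` in the configured base, and averaged per gene over
    the cells of each type.  Cells with zero total counts cannot be
    CPM-scaled and are dropped with a warning.

    Returns a genes x cell-types DataFrame; the per-type cell counts are
    stored in ``df.attrs["n_cells"]``.
    """
    X = adata.X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    totals = dense.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d cells with zero total counts", (~keep).sum())
        dense = dense[keep]
        totals = totals[keep]
    cell_types = adata.obs["cell_type"].values[keep]

    cpm = dense / totals[:, None] * 1e6
    logcpm = np.log1p(cpm)
    if config.log_base == "2":
        logcpm /= np.log(2.0)

    profiles = {}
    n_cells = {}
    for ct in sorted(pd.unique(cell_types)):
        mask = cell_types == ct
        profiles[ct] = logcpm[mask].mean(axis=0)
        n_cells[ct] = int(mask.sum())
    out = pd.DataFrame(profiles, index=pd.Index(adata.var_names, name="gene"))
    out.attrs["n_cells"] = n_cells
    return out
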