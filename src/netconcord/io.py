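"""Readers and writers for the external file formats.

Everything downstream consumes in-memory objects only: a gene-score
``DataFrame``, an edge-list ``DataFrame``, an :class:`anndata.AnnData` for
counts, a coordinates ``DataFrame`` and plain gene sets.  Identifier
matching across inputs is exact string match after whitespace trimming;
users must pre-harmonize gene symbols (no alias resolution is attempted).
"""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import DEFAULT_EXCLUDED_INTERACTION_TYPES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene-level GWAS scores
# ---------------------------------------------------------------------------

def read_gwas_gene_scores(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene -> p-value table (e.g. MAGMA gene output).

    Returns a DataFrame indexed by gene with columns ``p`` and
    ``neglog10_p``.  Duplicate gene rows are resolved by keeping the
    smallest p-value (most significant).  Genes with p = 1 are retained;
    their score is exactly 0 and they are flagged in column ``p_is_one``.

    Raises
    ------
    ValueError
        On an empty file, a non-numeric p-value, or p outside (0, 1],
        naming the offending line.
    """
    records: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty gene-score file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene and p-value")
            gene = fields[0].strip()
            try:
                p = float(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric p-value {fields[1]!r}"
                ) from None
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{path}:{lineno}: p-value out of range (0, 1]: {p}")
            if gene in records:
                records[gene] = min(records[gene], p)
            else:
                records[gene] = p
    if not records:
        raise ValueError(f"{path}: no gene records found")
    genes = sorted(records)
    p = np.array([records[g] for g in genes])
    table = pd.DataFrame(
        {"p": p, "neglog10_p": -np.log10(p), "p_is_one": p == 1.0},
        index=pd.Index(genes, name="gene"),
    )
    return table


# ---------------------------------------------------------------------------
# interaction network (SIF / edge list)
# ---------------------------------------------------------------------------

def read_network_sif(
    path: str | Path,
    excluded_interaction_types: frozenset[str] | set[str] = DEFAULT_EXCLUDED_INTERACTION_TYPES,
) -> pd.DataFrame:
    """Read a SIF (geneA, type, geneB) or 2-column edge list.

    Edges are undirected and deduplicated; self-loops are removed; edges
    whose interaction type is excluded are dropped.  Returns a DataFrame
    with columns ``gene_a`` and ``gene_b`` (``gene_a < gene_b``) sorted for
    reproducibility, with drop counters in ``df.attrs``.
    """
    excluded = set(excluded_interaction_types)
    pairs: set[tuple[str, str]] = set()
    n_excluded_type = 0
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 2:
                a, b = fields[0].strip(), fields[1].strip()
            elif len(fields) == 3:
                a, itype, b = (f.strip() for f in fields)
                if itype in excluded:
                    n_excluded_type += 1
                    continue
            else:
                raise ValueError(
                    f"{path}:{lineno}: malformed line with {len(fields)} fields"
                )
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene identifier")
            if a == b:
                n_self += 1
                continue
            pairs.add((a, b) if a < b else (b, a))
    edges = pd.DataFrame(sorted(pairs), columns=["gene_a", "gene_b"])
    edges.attrs["n_dropped_interaction_type"] = n_excluded_type
    edges.attrs["n_dropped_self_loop"] = n_self
    logger.info(
        "read %d undirected edges from %s (%d dropped by interaction type, "
        "%d self-loops)", len(edges), path, n_excluded_type, n_self,
    )
    return edges


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def read_cell_annotation(path: str | Path) -> pd.Series:
    """Read a two-column cell_id -> cell_type table (with header)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs cell_id and cell_type columns")
    ann = pd.Series(
        table.iloc[:, 1].str.strip().values,
        index=table.iloc[:, 0].str.strip().values,
        name="cell_type",
    )
    if ann.index.duplicated().any():
        dup = ann.index[ann.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated cell id {dup!r}")
    return ann


def read_expression_input(
    matrix_path: str | Path,
    cell_annotation_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ad.AnnData:
    """Read a count matrix plus cell-type annotation into an AnnData.

    ``matrix_path`` may be a MatrixMarket triplet (genes x cells, 1-based
    indices; ``genes_path``/``cells_path`` name the row/column sidecar
    files) or a dense TSV with genes as rows and cell ids as the header.

    The returned AnnData is cells x genes with raw counts in ``X`` and the
    cell type in ``obs["cell_type"]``.  Cells without annotation are
    dropped (logged); if more than half of the annotated cells are missing
    from the matrix the input is likely transposed and a hard error is
    raised.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            genes_path = matrix_path.with_name("genes.txt")
            cells_path = matrix_path.with_name("barcodes.txt")
        counts = sp.csr_matrix(scipy.io.mmread(matrix_path)).T  # -> cells x genes
        genes = [l.strip() for l in open(genes_path) if l.strip()]
        cells = [l.strip() for l in open(cells_path) if l.strip()]
        if counts.shape != (len(cells), len(genes)):
            raise ValueError(
                f"{matrix_path}: matrix shape {counts.shape[::-1]} does not match "
                f"{len(genes)} genes x {len(cells)} cells in sidecar files"
            )
    else:
        dense = pd.read_csv(matrix_path, sep="\t", index_col=0)
        genes = [str(g).strip() for g in dense.index]
        cells = [str(c).strip() for c in dense.columns]
        counts = sp.csr_matrix(dense.values.T)
    if (counts.data < 0).any():
        raise ValueError(f"{matrix_path}: negative counts")

    annotation = read_cell_annotation(cell_annotation_path)
    matched = [c for c in cells if c in annotation.index]
    if not matched:
        raise ValueError(
            f"{cell_annotation_path}: annotation matches zero matrix cells"
        )
    if len(annotation) and len(set(annotation.index) & set(cells)) < 0.5 * len(annotation):
        raise ValueError(
            "fewer than half of the annotated cells appear in the matrix; "
            "the matrix is likely transposed or uses a different id space"
        )
    n_dropped = len(cells) - len(matched)
    if n_dropped:
        logger.info("dropped %d cells lacking annotation", n_dropped)
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata = adata[matched].copy()
    adata.obs["cell_type"] = annotation.loc[adata.obs_names].values
    adata.uns["n_cells_dropped_unannotated"] = n_dropped
    return adata


# ---------------------------------------------------------------------------
# coordinates and gene lists
# ---------------------------------------------------------------------------

def read_gene_coordinates(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open; name column = gene id).

    Returns a DataFrame indexed by gene with columns chrom/start/end.
    Duplicate genes keep the first occurrence.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "gene": str},
    )
    if bed.empty:
        raise ValueError(f"{path}: empty BED file")
    bed["gene"] = bed["gene"].str.strip()
    bed = bed.drop_duplicates("gene", keep="first").set_index("gene")
    if (bed["end"] <= bed["start"]).any():
        bad = bed.index[bed["end"] <= bed["start"]][0]
        raise ValueError(f"{path}: empty interval for gene {bad!r}")
    return bed


def read_gene_list(path: str | Path) -> set[str]:
    """Read a newline-delimited gene list into a set."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV; floats use shortest-roundtrip repr (lossless re-read)."""
    df.to_csv(path, sep="\t", index=index)


def write_sif(edges, path: str | Path, interaction_type: str = "interacts-with") -> None:
    """Write an undirected edge list as a 3-column SIF."""
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{interaction_type}\t{b}\n")
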