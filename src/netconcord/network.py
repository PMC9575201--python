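"""Background network construction and node weighting.

The raw interaction edge list (already stripped of excluded interaction
types and self-loops by the reader) passes three further filters, in a
fixed order so the provenance accounting is deterministic:

1. exclusion list — edges touching housekeeping/ribosomal genes;
2. genomic proximity — same-chromosome pairs whose gene bodies lie within
   ``flank_kb_pair_exclusion`` kb of each other (the gene flank used for
   SNP-to-gene mapping; such pairs would double-count proximal SNPs);
3. MHC — edges with an endpoint overlapping the MHC interval, whose
   complex LD inflates association scores.

Each dropped edge is attributed to the first filter that removes it.
Genes without coordinates cannot be evaluated by the location filters and
pass them (counted in the provenance log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class ReferenceNetwork:
    """Filtered undirected background network with provenance counters."""

    nodes: list[str]
    edges: list[tuple[str, str]]  # each tuple sorted, list sorted
    dropped: dict[str, int] = field(default_factory=dict)
    n_genes_without_coords: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


class WeightedNetwork:
    """Background network restricted to weighted genes.

    Nodes are the intersection of the network genes, the GWAS-scored
    genes and the expression-profiled genes; every node carries the
    calibrated weight pair (v_g, v_s).  Internally nodes are integer
    indices over the sorted gene list with adjacency sets, which keeps the
    greedy module search fast.
    """

    def __init__(
        self,
        genes: list[str],
        edges: list[tuple[str, str]],
        v_g: np.ndarray,
        v_s: np.ndarray,
    ):
        self.genes = list(genes)
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.v_g = np.asarray(v_g, dtype=float)
        self.v_s = np.asarray(v_s, dtype=float)
        if len(self.genes) != self.v_g.size or len(self.genes) != self.v_s.size:
            raise ValueError("weight vectors must match the gene list")
        self.adj: list[set[int]] = [set() for _ in self.genes]
        self.edge_index: list[tuple[int, int]] = []
        for a, b in edges:
            i, j = self.index[a], self.index[b]
            if j not in self.adj[i]:
                self.adj[i].add(j)
                self.adj[j].add(i)
                self.edge_index.append((i, j) if i < j else (j, i))
        self.edge_index.sort()

    @property
    def n_nodes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    def edges(self) -> list[tuple[str, str]]:
        return [(self.genes[i], self.genes[j]) for i, j in self.edge_index]

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"v_g": self.v_g, "v_s": self.v_s},
            index=pd.Index(self.genes, name="gene"),
        )

    def with_weights(self, v_g: np.ndarray, v_s: np.ndarray) -> "WeightedNetwork":
        """Copy sharing the graph structure but carrying new weights."""
        new = object.__new__(WeightedNetwork)
        new.genes = self.genes
        new.index = self.index
        new.adj = self.adj
        new.edge_index = self.edge_index
        new.v_g = np.asarray(v_g, dtype=float)
        new.v_s = np.asarray(v_s, dtype=float)
        return new


def _gene_body_gap(row_a, row_b) -> int | None:
    """Gap in bp between two gene bodies, or None on different chromosomes."""
    if row_a[0] != row_b[0]:
        return None
    gap = max(row_a[1], row_b[1]) - min(row_a[2], row_b[2])
    return max(0, gap)


def apply_network_filters(
    edges: pd.DataFrame,
    coords: pd.DataFrame | None,
    exclusion_list: set[str],
    config: RunConfig,
) -> ReferenceNetwork:
    """Apply exclusion-list, proximity and MHC filters to an edge list.

    ``coords`` is a gene-indexed DataFrame with chrom/start/end (0-based
    half-open) or None to skip the location filters entirely.
    """
    mhc_chrom, mhc_start, mhc_end = config.mhc_region
    max_gap = int(config.flank_kb_pair_exclusion * 1000)

    coord_map: dict[str, tuple[str, int, int]] = {}
    in_mhc: set[str] = set()
    if coords is not None:
        for gene, row in coords.iterrows():
            coord_map[gene] = (row["chrom"], int(row["start"]), int(row["end"]))
        for gene, (chrom, start, end) in coord_map.items():
            if chrom == mhc_chrom and start < mhc_end and end > mhc_start:
                in_mhc.add(gene)

    dropped = {"exclusion_list": 0, "proximity": 0, "mhc": 0}
    genes_without_coords: set[str] = set()
    kept: list[tuple[str, str]] = []
    for a, b in edges.itertuples(index=False):
        if a in exclusion_list or b in exclusion_list:
            dropped["exclusion_list"] += 1
            continue
        ca, cb = coord_map.get(a), coord_map.get(b)
        for gene, c in ((a, ca), (b, cb)):
            if coords is not None and c is None:
                genes_without_coords.add(gene)
        if ca is not None and cb is not None:
            gap = _gene_body_gap(ca, cb)
            if gap is not None and gap <= max_gap:
                dropped["proximity"] += 1
                continue
        if a in in_mhc or b in in_mhc:
            dropped["mhc"] += 1
            continue
        kept.append((a, b))

    nodes = sorted({g for e in kept for g in e})
    net = ReferenceNetwork(
        nodes=nodes,
        edges=sorted(kept),
        dropped=dropped,
        n_genes_without_coords=len(genes_without_coords),
    )
    logger.info(
        "network filters: %d -> %d edges (exclusion list %d, proximity %d, "
        "MHC %d); %d genes had no coordinates and passed location filters",
        len(edges), net.n_edges, dropped["exclusion_list"], dropped["proximity"],
        dropped["mhc"], len(genes_without_coords),
    )
    return net


def assemble_weighted_network(
    net: ReferenceNetwork,
    v_g: pd.Series,
    v_s: pd.Series,
    min_genes: int = 100,
) -> WeightedNetwork:
    """Restrict the network to weighted genes and attach the weight pair.

    ``v_g`` and ``v_s`` are gene-indexed calibrated weights (produced on
    the shared universe, so they normally cover the same genes).  Nodes
    left isolated by the restriction stay in the network as potential
    single-node seeds.

    Raises
    ------
    ValueError
        If the triple intersection holds fewer than ``min_genes`` genes
        (the identifier spaces are probably mismatched).
    """
    weighted = set(v_g.index) & set(v_s.index)
    keep = sorted(set(net.nodes) & weighted)
    if len(keep) < min_genes:
        raise ValueError(
            f"only {len(keep)} genes are shared between the network and both "
            f"weight tables (expected >= {min_genes}); check that all inputs "
            "use the same gene identifiers"
        )
    keep_set = set(keep)
    edges = [(a, b) for a, b in net.edges if a in keep_set and b in keep_set]
    wn = WeightedNetwork(
        genes=keep,
        edges=edges,
        v_g=v_g.loc[keep].to_numpy(dtype=float),
        v_s=v_s.loc[keep].to_numpy(dtype=float),
    )
    logger.info(
        "weighted network: %d nodes, %d edges (dropped %d network genes "
        "without weights)", wn.n_nodes, wn.n_edges, net.n_nodes - len(keep),
    )
    return wn
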