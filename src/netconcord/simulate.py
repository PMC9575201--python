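"""Synthetic input generator with controllable ground truth.

Emits exactly the five input files the readers consume (gene-score TSV,
MatrixMarket counts with sidecars, cell annotation TSV, SIF network, BED
coordinates, exclusion gene list) plus a truth TSV naming the planted
module genes and their designated cell type, so the whole pipeline can be
exercised and benchmarked offline.

The generative model:

* GWAS p-values are i.i.d. Uniform(0, 1); planted genes have their
  -log10 p shifted upward by the module's GWAS effect.
* Counts are negative-binomial with gene-specific log-normal base means
  (the right-skewed, zero-inflated shape the calibration step expects);
  planted genes have their mean multiplied by exp(expression effect) in
  the designated cell type only.
* The network is a preferential-attachment (Barabasi-Albert) graph;
  each planted module is additionally wired as a connected subgraph
  (random spanning tree plus a few extra edges).
* Coordinates are synthetic, widely spaced (1 Mb apart on chr1..chr5,
  10 kb gene bodies) except for a configurable number of deliberately
  close pairs (40 kb apart) and a block of genes inside a fake
  chr6:26-34 Mb MHC region, so the location filters are exercised.
  Special-region genes and exclusion-list genes are never planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.io
import scipy.sparse as sp


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_genes: int = 500
    n_cell_types: int = 3
    n_cells_per_type: int = 60
    ba_attachment: int = 2           # preferential-attachment parameter
    planted_modules: list[tuple[int, float, float]] = field(default_factory=list)
    # each entry: (size, gwas effect on -log10 p, expression effect on log mean)
    nb_mean_log: float = 1.5         # log-normal location of gene base means
    nb_mean_sdlog: float = 1.0       # log-normal scale of gene base means
    nb_dispersion: float = 2.0       # NB shape; var = mu + mu^2 / dispersion
    n_close_pairs: int = 3           # <50-kb gene pairs to exercise the filter
    n_mhc_genes: int = 4             # genes placed inside the fake MHC block
    n_excluded_genes: int = 5        # genes on the exclusion list
    rng_seed: int = 0

    def validate(self) -> None:
        special = 2 * self.n_close_pairs + self.n_mhc_genes + self.n_excluded_genes
        planted = sum(size for size, _, _ in self.planted_modules)
        if planted + special > self.n_genes:
            raise ValueError(
                f"planted modules ({planted} genes) plus special genes "
                f"({special}) exceed n_genes={self.n_genes}"
            )
        for size, eg, es in self.planted_modules:
            if size < 1 or size > self.n_genes:
                raise ValueError(f"infeasible planted module size {size}")
            if eg < 0 or es < 0:
                raise ValueError("planted effects must be non-negative")


@dataclass
class Fixture:
    """In-memory form of a simulated dataset (before writing files)."""

    genes: list[str]
    gwas_p: np.ndarray
    counts: sp.csr_matrix          # cells x genes
    cell_ids: list[str]
    cell_types: list[str]
    edges: list[tuple[str, str]]
    coords: dict[str, tuple[str, int, int]]
    excluded_genes: list[str]
    truth: list[tuple[str, int, str]]   # (gene, module_id, cell_type)
    designated_cell_type: str


def simulate(spec: FixtureSpec) -> Fixture:
    """Draw one dataset from the generative model."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    width = len(str(spec.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]

    # --- reserve special genes: close pairs, MHC block, exclusion list,
    # planted modules; all drawn from disjoint random index blocks (random
    # so that no block coincides with the early hub nodes of the
    # preferential-attachment graph) and never overlapping, so the planted
    # signal is never silently removed by a filter.
    shuffled = list(rng.permutation(spec.n_genes))
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        out = [int(i) for i in shuffled[cursor:cursor + k]]
        cursor += k
        return out

    close_pair_idx = [take(2) for _ in range(spec.n_close_pairs)]
    mhc_idx = take(spec.n_mhc_genes)
    excluded_idx = take(spec.n_excluded_genes)
    planted_idx: list[list[int]] = [
        take(size) for size, _, _ in spec.planted_modules
    ]

    # --- network: preferential attachment + planted wiring
    m = min(spec.ba_attachment, spec.n_genes - 1)
    graph = nx.barabasi_albert_graph(
        spec.n_genes, m, seed=int(rng.integers(2**31))
    )
    for idx in planted_idx:
        for k in range(1, len(idx)):
            graph.add_edge(idx[k], idx[int(rng.integers(k))])  # spanning tree
        for _ in range(len(idx)):
            i, j = rng.choice(idx, size=2, replace=False)
            graph.add_edge(int(i), int(j))
    edges = sorted(
        (genes[min(i, j)], genes[max(i, j)]) for i, j in graph.edges() if i != j
    )

    # --- GWAS p-values
    u = rng.uniform(size=spec.n_genes)
    neglog = -np.log10(u)
    for idx, (_, effect_g, _) in zip(planted_idx, spec.planted_modules):
        neglog[idx] += effect_g
    gwas_p = 10.0 ** (-neglog)

    # --- counts
    cell_types = [f"CT{k + 1}" for k in range(spec.n_cell_types)]
    designated = cell_types[0]
    base_mean = rng.lognormal(spec.nb_mean_log, spec.nb_mean_sdlog, spec.n_genes)
    blocks = []
    labels: list[str] = []
    for ct in cell_types:
        mu = base_mean.copy()
        if ct == designated:
            for idx, (_, _, effect_s) in zip(planted_idx, spec.planted_modules):
                mu[idx] *= np.exp(effect_s)
        theta = spec.nb_dispersion
        p_nb = theta / (theta + mu)
        block = rng.negative_binomial(
            theta, p_nb[None, :], size=(spec.n_cells_per_type, spec.n_genes)
        )
        blocks.append(block)
        labels.extend([ct] * spec.n_cells_per_type)
    counts = sp.csr_matrix(np.vstack(blocks))
    cell_ids = [f"cell{i + 1:05d}" for i in range(counts.shape[0])]

    # --- coordinates: widely spaced gene bodies except the special blocks
    coords: dict[str, tuple[str, int, int]] = {}
    chroms = [f"chr{c}" for c in range(1, 6)]
    pos = {c: 1_000_000 for c in chroms}
    special = {i for pair in close_pair_idx for i in pair} | set(mhc_idx)
    for i, gene in enumerate(genes):
        if i in special:
            continue
        chrom = chroms[i % len(chroms)]
        start = pos[chrom]
        coords[gene] = (chrom, start, start + 10_000)
        pos[chrom] = start + 1_000_000
    for k, (i, j) in enumerate(close_pair_idx):
        start = 5_000_000 + k * 1_000_000
        coords[genes[i]] = ("chr9", start, start + 10_000)
        coords[genes[j]] = ("chr9", start + 50_000, start + 60_000)  # 40-kb gap
        graph_has = graph.has_edge(i, j)
        if not graph_has:
            edges.append((genes[min(i, j)], genes[max(i, j)]))
    for k, i in enumerate(mhc_idx):
        start = 27_000_000 + k * 500_000
        coords[genes[i]] = ("chr6", start, start + 10_000)
    edges = sorted(set(edges))

    truth = [
        (genes[i], mod_id + 1, designated)
        for mod_id, idx in enumerate(planted_idx)
        for i in idx
    ]
    return Fixture(
        genes=genes,
        gwas_p=gwas_p,
        counts=counts,
        cell_ids=cell_ids,
        cell_types=labels,
        edges=edges,
        coords=coords,
        excluded_genes=[genes[i] for i in excluded_idx],
        truth=truth,
        designated_cell_type=designated,
    )


def simulate_inputs(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Simulate a dataset and write all input files plus the truth table.

    Returns a dict of file paths keyed by input kind.
    """
    fx = simulate(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas": outdir / "gwas.tsv",
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.txt",
        "barcodes": outdir / "barcodes.txt",
        "annotation": outdir / "annotation.tsv",
        "network": outdir / "network.sif",
        "coords": outdir / "coords.bed",
        "exclude": outdir / "exclude.txt",
        "truth": outdir / "truth.tsv",
    }

    with open(paths["gwas"], "w") as fh:
        fh.write("gene\tp\n")
        for gene, p in zip(fx.genes, fx.gwas_p):
            fh.write(f"{gene}\t{p:.17g}\n")

    scipy.io.mmwrite(
        str(paths["matrix"]), sp.coo_matrix(fx.counts.T.astype(np.int64))
    )  # genes x cells, integer triplets
    paths["genes"].write_text("".join(g + "\n" for g in fx.genes))
    paths["barcodes"].write_text("".join(c + "\n" for c in fx.cell_ids))

    with open(paths["annotation"], "w") as fh:
        fh.write("cell_id\tcell_type\n")
        for cell, ct in zip(fx.cell_ids, fx.cell_types):
            fh.write(f"{cell}\t{ct}\n")

    with open(paths["network"], "w") as fh:
        for a, b in fx.edges:
            fh.write(f"{a}\tinteracts-with\t{b}\n")

    with open(paths["coords"], "w") as fh:
        for gene in fx.genes:
            if gene in fx.coords:
                chrom, start, end = fx.coords[gene]
                fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")

    paths["exclude"].write_text("".join(g + "\n" for g in fx.excluded_genes))

    with open(paths["truth"], "w") as fh:
        fh.write("gene\tmodule_id\tcell_type\n")
        for gene, mod_id, ct in fx.truth:
            fh.write(f"{gene}\t{mod_id}\t{ct}\n")
    return paths
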