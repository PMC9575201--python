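"""Trait x cell-type decision layer.

A trait is declared associated with a cell type when the fraction of
*concordant* modules found in the real data significantly exceeds the
fraction among the random modules from the permutation null.  Concordant
means both size-normalized component scores (z_g, z_s) exceed the 95th
percentile of the normalized random pool — top 5% by GWAS and top 5% by
expression simultaneously.  Normalized rather than raw scores are used
because raw m_g and m_s both scale with sqrt(module size), so raw
cutoffs are dominated by large random modules and a signal in a single
weight system that merely inflates module size would drag the other
score over its cutoff as well.

Both module pools are counted at seed level (one search outcome per seed
gene; random rounds pooled), so A is the number of network nodes and B
is nodes x rounds.  The comparison is a pooled two-proportion z test;
the default cutoff z > 5 reflects a Bonferroni correction over a large
trait x cell-type grid.

Significant modules are merged into one subnetwork per (trait, cell
type); the subnetwork is summarized with a GSEA normalized enrichment
score against each weight system, averaged into a combined NES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .mebe import Module
from .network import WeightedNetwork
from .nulls import NullDistribution, ScoredModule

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# concordance cutoffs and the proportional test
# ---------------------------------------------------------------------------

def empirical_q95(values: np.ndarray) -> float:
    """Empirical 95th percentile with linear (type-7) interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise ValueError(
            f"only {values.size} values; the 95th percentile is unreliable "
            "below 20"
        )
    return float(np.percentile(values, 95))


def concordance_cutoffs(null: NullDistribution) -> tuple[float, float]:
    """Q95 of the size-normalized z_g and z_s over the random-module pool."""
    pool = null.normalized_pool()
    return empirical_q95(pool["z_g"]), empirical_q95(pool["z_s"])


@dataclass
class AssociationResult:
    """Outcome of the proportional test for one (trait, cell type) pair."""

    trait: str
    cell_type: str
    a: int      # concordant real modules
    A: int      # all real modules
    b: int      # concordant random modules
    B: int      # all random modules
    p1: float
    p2: float
    p_hat: float
    z: float
    significant: bool
    degenerate: bool
    q95_zg: float
    q95_zs: float


def two_proportion_z(a: int, A: int, b: int, B: int) -> tuple[float, bool]:
    """Pooled two-proportion z statistic; degenerate pools give z = 0."""
    if A < 1 or B < 1:
        raise ValueError("both module pools must be non-empty")
    p1 = a / A
    p2 = b / B
    p_hat = (a + b) / (A + B)
    if p_hat in (0.0, 1.0):
        return 0.0, True
    z = (p1 - p2) / sqrt(p_hat * (1.0 - p_hat) * (1.0 / A + 1.0 / B))
    return z, False


def module_concordance(
    modules: list[Module],
    null: NullDistribution,
    cutoffs: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean concordance flag per module.

    A module is concordant when its size-normalized z_g exceeds Q95(z_g)
    and its z_s exceeds Q95(z_s), quantiles taken over the normalized
    random pool.
    """
    if cutoffs is None:
        cutoffs = concordance_cutoffs(null)
    q95_zg, q95_zs = cutoffs
    flags = np.zeros(len(modules), dtype=bool)
    for k, mod in enumerate(modules):
        st, _ = null.stats_for(mod.size)
        z_g = (mod.m_g - st["u_m_g"]) / st["sd_m_g"]
        z_s = (mod.m_s - st["u_m_s"]) / st["sd_m_s"]
        flags[k] = z_g > q95_zg and z_s > q95_zs
    return flags


def proportional_test(
    real_modules: list[Module],
    null: NullDistribution,
    cutoffs: tuple[float, float] | None = None,
    z_cutoff: float = 5.0,
    trait: str = "trait",
    cell_type: str = "cell_type",
) -> AssociationResult:
    """Compare the concordant-module fraction in real vs random searches.

    Counting is seed-level on both sides: each real module contributes
    its seed multiplicity to a/A, and the random pool already holds one
    outcome per (seed, round).
    """
    if cutoffs is None:
        cutoffs = concordance_cutoffs(null)
    q95_zg, q95_zs = cutoffs
    flags = module_concordance(real_modules, null, (q95_zg, q95_zs))
    a = int(sum(mod.n_seeds for mod, f in zip(real_modules, flags) if f))
    A = int(sum(mod.n_seeds for mod in real_modules))
    pool = null.normalized_pool()
    b = int(np.sum((pool["z_g"] > q95_zg) & (pool["z_s"] > q95_zs)))
    B = null.n_modules
    z, degenerate = two_proportion_z(a, A, b, B)
    return AssociationResult(
        trait=trait, cell_type=cell_type,
        a=a, A=A, b=b, B=B,
        p1=a / A, p2=b / B, p_hat=(a + b) / (A + B),
        z=z, significant=bool(z > z_cutoff), degenerate=degenerate,
        q95_zg=q95_zg, q95_zs=q95_zs,
    )


# ---------------------------------------------------------------------------
# merged subnetwork and its GSEA assessment
# ---------------------------------------------------------------------------

@dataclass
class Subnetwork:
    """Union of significant-module genes and their induced edges."""

    genes: list[str]
    edges: list[tuple[str, str]]
    nes_gwas: float | None = None
    nes_expr: float | None = None

    @property
    def nes_combined(self) -> float | None:
        if self.nes_gwas is None or self.nes_expr is None:
            return None
        return 0.5 * (self.nes_gwas + self.nes_expr)


def merge_significant_modules(
    scored: list[ScoredModule],
    network: WeightedNetwork,
    min_size: int = 1,
    concordant: np.ndarray | None = None,
) -> Subnetwork | None:
    """Merge significant modules into one subnetwork.

    Returns None when no module of at least ``min_size`` genes is
    significant.  Edges are the reference-network edges induced on the
    gene union.  An optional boolean mask (aligned with ``scored``)
    restricts the merge to concordant modules, the recommended reporting
    mode for associated pairs.
    """
    union: set[str] = set()
    for k, sm in enumerate(scored):
        if concordant is not None and not concordant[k]:
            continue
        if sm.significant and sm.module.size >= min_size:
            union |= set(sm.module.genes)
    if not union:
        return None
    idx = {network.index[g] for g in union}
    edges = [
        (network.genes[i], network.genes[j])
        for i, j in network.edge_index
        if i in idx and j in idx
    ]
    return Subnetwork(genes=sorted(union), edges=edges)


def enrichment_score(scores: pd.Series, gene_set: set[str]) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score.

    Genes are ranked by score (descending, ties broken by gene id for
    determinism); the running sum steps up by |score| / sum(|scores| in
    set) at each set member and down by 1 / (N - Nh) otherwise.  The ES
    is the signed extremum of the walk.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    missing = gene_set - set(scores.index)
    if missing:
        raise ValueError(f"gene set members absent from the ranking: {sorted(missing)[:5]}")
    n = len(scores)
    nh = len(gene_set)
    if nh >= n:
        return 0.0  # a set spanning the whole universe has a degenerate walk
    ordered = scores.sort_index().sort_values(ascending=False, kind="stable")
    is_hit = ordered.index.isin(gene_set)
    weights = np.abs(ordered.to_numpy())[is_hit]
    denom = weights.sum()
    steps = np.full(n, -1.0 / (n - nh))
    if denom > 0:
        steps[is_hit] = np.abs(ordered.to_numpy())[is_hit] / denom
    else:  # all-zero hit scores: fall back to equal hit steps
        steps[is_hit] = 1.0 / nh
    walk = np.cumsum(steps)
    extremum = walk[np.argmax(np.abs(walk))]
    return float(extremum)


def gsea_nes(
    scores: pd.Series,
    gene_set: set[str],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Enrichment score and its gene-label-permutation normalization.

    NES = ES / mean(|ES*|) over the permuted enrichment scores with the
    same sign as ES, the canonical GSEA normalization.

    Returns ``(es, nes)``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations for a stable NES")
    if rng is None:
        rng = np.random.default_rng(0)
    es = enrichment_score(scores, set(gene_set))
    genes = np.array(scores.index)
    nh = len(gene_set)
    perm_es = np.empty(n_perm)
    for k in range(n_perm):
        random_set = set(rng.choice(genes, size=nh, replace=False))
        perm_es[k] = enrichment_score(scores, random_set)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if same_sign.size == 0:
        same_sign = perm_es
    denom = float(np.mean(np.abs(same_sign)))
    nes = es / denom if denom > 0 else 0.0
    return es, float(nes)


def assess_subnetwork(
    sub: Subnetwork,
    network: WeightedNetwork,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> Subnetwork:
    """Attach GWAS- and expression-ranked NES values to a subnetwork."""
    weights = network.weights_frame()
    gene_set = set(sub.genes)
    if rng is None:
        rng = np.random.default_rng(0)
    _, sub.nes_gwas = gsea_nes(weights["v_g"], gene_set, n_perm, rng)
    _, sub.nes_expr = gsea_nes(weights["v_s"], gene_set, n_perm, rng)
    return sub


# ---------------------------------------------------------------------------
# trait-trait similarity
# ---------------------------------------------------------------------------

def jaccard(set1: set[str], set2: set[str]) -> float:
    union = set1 | set2
    if not union:
        return 0.0
    return len(set1 & set2) / len(union)


def trait_similarity(
    module_gene_sets: dict[tuple[str, str], set[str]]
) -> pd.DataFrame:
    """Mean Jaccard index of module genes across shared cell types.

    ``module_gene_sets`` maps (trait, cell_type) to the module gene set of
    that pair.  For two traits the Jaccard index is computed in every cell
    type where both have a non-empty gene set and averaged; pairs with no
    shared cell type are NaN (undefined, not zero).  The diagonal is 1.
    """
    traits = sorted({t for t, _ in module_gene_sets})
    by_trait: dict[str, dict[str, set[str]]] = {t: {} for t in traits}
    for (trait, cell_type), genes in module_gene_sets.items():
        if genes:
            by_trait[trait][cell_type] = set(genes)
    mat = pd.DataFrame(np.nan, index=traits, columns=traits)
    for i, t1 in enumerate(traits):
        mat.loc[t1, t1] = 1.0
        for t2 in traits[i + 1:]:
            shared = set(by_trait[t1]) & set(by_trait[t2])
            if not shared:
                continue
            value = float(
                np.mean([jaccard(by_trait[t1][c], by_trait[t2][c]) for c in shared])
            )
            mat.loc[t1, t2] = value
            mat.loc[t2, t1] = value
    return mat
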