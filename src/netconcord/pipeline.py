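"""End-to-end orchestration for one trait against one expression panel.

Stage order: calibrate weights -> restrict the filtered network ->
seed-by-seed module search -> permutation null (virtual search) ->
size-normalized module significance -> concordance proportional test ->
merged subnetwork (optionally GSEA-assessed).  The virtual null depends
on the calibrated weights, so it is recomputed per (trait, cell type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association, mebe, nulls, transform
from .config import RunConfig
from .network import ReferenceNetwork, WeightedNetwork, assemble_weighted_network
from .nulls import NullDistribution, ScoredModule

logger = logging.getLogger(__name__)


@dataclass
class CellTypeResult:
    """Everything computed for one (trait, cell type) pair."""

    trait: str
    cell_type: str
    network: WeightedNetwork
    modules: list[mebe.Module]
    scored: list[ScoredModule]
    concordant: np.ndarray            # mask aligned with modules/scored
    null: NullDistribution
    assoc: association.AssociationResult
    subnetwork: association.Subnetwork | None
    lambda_g: float
    lambda_s: float


def run_cell_type(
    gwas_scores: pd.DataFrame,
    profile: pd.Series,
    reference: ReferenceNetwork,
    config: RunConfig,
    trait: str,
    cell_type: str,
    null_seed: int | None = None,
    min_network_genes: int = 100,
    compute_nes: bool = False,
) -> CellTypeResult:
    """Run the full method for one trait and one cell-type profile.

    Parameters
    ----------
    gwas_scores
        Gene-indexed table with a ``neglog10_p`` column.
    profile
        Gene-indexed pseudo-bulk expression vector (mean log(CPM+1)).
    reference
        The filtered background network.
    null_seed
        Seed for the virtual search; defaults to ``config.rng_seed``.
    """
    universe = sorted(
        set(reference.nodes) & set(gwas_scores.index) & set(profile.index)
    )
    if len(universe) < min_network_genes:
        raise ValueError(
            f"only {len(universe)} genes shared by network, GWAS table and "
            f"expression profile (need >= {min_network_genes})"
        )
    raw_g = gwas_scores.loc[universe, "neglog10_p"].to_numpy(dtype=float)
    raw_s = profile.loc[universe].to_numpy(dtype=float)
    cal = transform.calibrate_weight_pair(raw_g, raw_s, config.boxcox_epsilon)
    v_g = pd.Series(cal["v_g"], index=universe)
    v_s = pd.Series(cal["v_s"], index=universe)

    net = assemble_weighted_network(reference, v_g, v_s, min_genes=min_network_genes)
    modules = mebe.search_all_seeds(net, config.r1, config.r2)
    sizes = {mod.size for mod in modules}
    null = nulls.run_virtual_search(net, sizes, config, seed=null_seed)
    scored = nulls.normalize_and_test(modules, null, config.module_p_cutoff)
    cutoffs = association.concordance_cutoffs(null)
    concordant = association.module_concordance(modules, null, cutoffs)
    assoc = association.proportional_test(
        modules, null, cutoffs, z_cutoff=config.association_z_cutoff,
        trait=trait, cell_type=cell_type,
    )
    # reported subnetwork: significant AND concordant modules — the genes
    # that actually carry the joint enrichment the association is about
    subnetwork = association.merge_significant_modules(
        scored, net, min_size=config.min_reported_module_size,
        concordant=concordant,
    )
    if compute_nes and subnetwork is not None:
        rng = np.random.default_rng((config.rng_seed + 987_653) % (2**31))
        association.assess_subnetwork(subnetwork, net, rng=rng)
    return CellTypeResult(
        trait=trait, cell_type=cell_type, network=net,
        modules=modules, scored=scored, concordant=concordant,
        null=null, assoc=assoc, subnetwork=subnetwork,
        lambda_g=cal["lambda_g"], lambda_s=cal["lambda_s"],
    )


def run_synthetic(
    spec,
    config: RunConfig,
    cell_type: str | None = None,
    null_seed: int | None = None,
) -> tuple[CellTypeResult, set[str]]:
    """Simulate a synthetic dataset in memory and run one cell type.

    Convenience wrapper used for benchmarking and calibration studies:
    draws a dataset from a :class:`~netconcord.simulate.FixtureSpec`,
    applies the standard preprocessing (expression filters, pseudo-bulk,
    network filters), and runs the designated cell type (or the one
    given).  Returns the result and the set of planted (truth) genes.
    """
    import anndata as ad

    from . import expression as expr_mod
    from . import network as net_mod
    from .simulate import simulate

    fx = simulate(spec)
    gwas = pd.DataFrame(
        {"p": fx.gwas_p, "neglog10_p": -np.log10(fx.gwas_p)},
        index=pd.Index(fx.genes, name="gene"),
    )
    adata = ad.AnnData(
        X=fx.counts,
        obs=pd.DataFrame({"cell_type": fx.cell_types}, index=fx.cell_ids),
        var=pd.DataFrame(index=pd.Index(fx.genes, name="gene")),
    )
    profiles = expr_mod.pseudobulk(expr_mod.filter_counts(adata, config), config)
    edges = pd.DataFrame(fx.edges, columns=["gene_a", "gene_b"])
    coords = pd.DataFrame(
        [(c, s, e, g) for g, (c, s, e) in fx.coords.items()],
        columns=["chrom", "start", "end", "gene"],
    ).set_index("gene")
    reference = net_mod.apply_network_filters(
        edges, coords, set(fx.excluded_genes), config
    )
    ct = cell_type or fx.designated_cell_type
    result = run_cell_type(
        gwas, profiles[ct], reference, config,
        trait="synthetic", cell_type=ct, null_seed=null_seed,
    )
    truth = {g for g, _, _ in fx.truth}
    return result, truth


def modules_table(result: CellTypeResult) -> pd.DataFrame:
    """Flatten scored modules into the output table schema."""
    rows = []
    for i, sm in enumerate(result.scored):
        mod = sm.module
        rows.append({
            "module_id": f"{result.cell_type}.M{i + 1}",
            "seed": mod.seed,
            "n_seeds": mod.n_seeds,
            "size": mod.size,
            "genes": ",".join(mod.genes),
            "m_g": mod.m_g, "m_s": mod.m_s, "m": mod.m,
            "z_m": sm.z_m, "z_g": sm.z_g, "z_s": sm.z_s,
            "p_m": sm.p_m, "p_g": sm.p_g, "p_s": sm.p_s,
            "stratum_fallback": sm.stratum_fallback,
            "significant": sm.significant,
            "concordant": bool(result.concordant[i]),
        })
    return pd.DataFrame(rows)


def association_row(result: CellTypeResult) -> dict:
    a = result.assoc
    return {
        "trait": a.trait, "cell_type": a.cell_type,
        "A": a.A, "a": a.a, "B": a.B, "b": a.b,
        "p1": a.p1, "p2": a.p2, "z": a.z,
        "q95_zg": a.q95_zg, "q95_zs": a.q95_zs,
        "degenerate": a.degenerate, "significant": a.significant,
        "n_significant_modules": sum(1 for sm in result.scored if sm.significant),
        "null_rounds": result.null.rounds_executed,
        "lambda_g": result.lambda_g, "lambda_s": result.lambda_s,
    }
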