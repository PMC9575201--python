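"""Permutation null for module scores (virtual search).

Analytic null distributions for greedy subnetwork scores are intractable,
so the null is built empirically: in each round both weight vectors are
permuted over the nodes independently (breaking the gene-weight pairing
while keeping the graph intact) and the full seed-by-seed search is
re-run.  Rounds repeat until every module size observed in the real data
has at least ``min_random_per_size`` random modules, or a round cap is
hit.  Real-module scores are then z-normalized against the size-matched
random moments, which removes the strong dependence of raw module scores
on module size, and empirical p-values are read off the pooled normalized
random scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .mebe import Module, search_all_seeds
from .network import WeightedNetwork

logger = logging.getLogger(__name__)


def permute_weights(
    network: WeightedNetwork, rng: np.random.Generator
) -> WeightedNetwork:
    """Permute v_g and v_s independently over the nodes; edges unchanged."""
    n = network.n_nodes
    return network.with_weights(
        network.v_g[rng.permutation(n)], network.v_s[rng.permutation(n)]
    )


@dataclass
class NullDistribution:
    """Size-stratified pool of random-module score triples.

    ``sizes``, ``m``, ``m_g``, ``m_s`` are parallel arrays over all random
    modules from all rounds, counted at seed level: every seed contributes
    one outcome per round, and rounds are independent draws (no
    deduplication across rounds).
    """

    sizes: np.ndarray
    m: np.ndarray
    m_g: np.ndarray
    m_s: np.ndarray
    min_random_per_size: int
    rounds_executed: int = 0
    rng_seed: int | None = None
    deficient_sizes: set[int] = field(default_factory=set)

    def __post_init__(self):
        self._stats: dict[int, dict[str, float]] = {}
        for size in np.unique(self.sizes):
            mask = self.sizes == size
            self._stats[int(size)] = self._moments(mask)

    def _moments(self, mask: np.ndarray) -> dict[str, float]:
        out = {"n": int(mask.sum())}
        for name, arr in (("m", self.m), ("m_g", self.m_g), ("m_s", self.m_s)):
            vals = arr[mask]
            out[f"u_{name}"] = float(vals.mean())
            out[f"sd_{name}"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return out

    @property
    def n_modules(self) -> int:
        return self.sizes.size

    def stratum_counts(self) -> dict[int, int]:
        return {s: st["n"] for s, st in self._stats.items()}

    def stratum_for(self, size: int) -> tuple[int, bool]:
        """Size stratum used to normalize a module of the given size.

        Returns ``(stratum_size, fallback)``.  A stratum is usable when it
        holds at least ``min_random_per_size`` members (or, if no stratum
        does, at least 2, so a standard deviation exists).  A module whose
        own size has no usable stratum borrows the nearest usable size,
        preferring the larger size on ties; ``fallback`` marks borrowing.
        """
        usable = [
            s for s, st in self._stats.items() if st["n"] >= self.min_random_per_size
        ]
        if not usable:
            usable = [s for s, st in self._stats.items() if st["n"] >= 2]
        if not usable:
            raise ValueError("null distribution has no stratum with >= 2 modules")
        if size in usable:
            return size, False
        nearest = min(usable, key=lambda s: (abs(s - size), -s))
        return nearest, True

    def stats_for(self, size: int) -> tuple[dict[str, float], bool]:
        stratum, fallback = self.stratum_for(size)
        return self._stats[stratum], fallback

    def normalized_pool(self) -> dict[str, np.ndarray]:
        """z-normalize every random module by its own size stratum.

        Returns arrays ``z_m``, ``z_g``, ``z_s`` over the full pool; this
        is the collection against which empirical p-values are computed.
        """
        z = {"z_m": np.empty(self.n_modules), "z_g": np.empty(self.n_modules),
             "z_s": np.empty(self.n_modules)}
        for size in np.unique(self.sizes):
            mask = self.sizes == size
            st, _ = self.stats_for(int(size))
            for zname, name, arr in (
                ("z_m", "m", self.m), ("z_g", "m_g", self.m_g),
                ("z_s", "m_s", self.m_s),
            ):
                sd = st[f"sd_{name}"]
                if sd == 0.0:
                    raise ValueError(
                        f"zero-variance null stratum for size {int(size)}"
                    )
                z[zname][mask] = (arr[mask] - st[f"u_{name}"]) / sd
        return z


def run_virtual_search(
    network: WeightedNetwork,
    sizes_required: set[int],
    config: RunConfig,
    seed: int | None = None,
) -> NullDistribution:
    """Repeat {permute weights -> full module search} to build the null.

    ``sizes_required`` are the module sizes observed in the real search.
    Rounds stop as soon as every required size stratum holds at least
    ``config.min_random_per_size`` random modules, or after
    ``config.max_virtual_rounds`` rounds (deficient sizes are recorded and
    later borrow the nearest stratum).
    """
    if seed is None:
        seed = config.rng_seed
    sizes_required = {int(s) for s in sizes_required}
    all_sizes: list[int] = []
    all_m: list[float] = []
    all_mg: list[float] = []
    all_ms: list[float] = []
    counts: dict[int, int] = {}
    rounds = 0
    while rounds < config.max_virtual_rounds:
        # per-round child seed: deterministic given the master seed
        rng = np.random.default_rng((seed + rounds) % (2**31))
        permuted = permute_weights(network, rng)
        modules = search_all_seeds(permuted, config.r1, config.r2)
        # the pool is seed-level: one outcome per seed, so a module found
        # from k seeds enters the null k times
        for mod in modules:
            all_sizes.extend([mod.size] * mod.n_seeds)
            all_m.extend([mod.m] * mod.n_seeds)
            all_mg.extend([mod.m_g] * mod.n_seeds)
            all_ms.extend([mod.m_s] * mod.n_seeds)
            counts[mod.size] = counts.get(mod.size, 0) + mod.n_seeds
        rounds += 1
        if all(
            counts.get(s, 0) >= config.min_random_per_size for s in sizes_required
        ):
            break
    deficient = {
        s for s in sizes_required if counts.get(s, 0) < config.min_random_per_size
    }
    if deficient:
        logger.warning(
            "virtual search hit the round cap (%d rounds); sizes %s remain "
            "below %d random modules and will borrow the nearest stratum",
            rounds, sorted(deficient), config.min_random_per_size,
        )
    null = NullDistribution(
        sizes=np.array(all_sizes, dtype=int),
        m=np.array(all_m),
        m_g=np.array(all_mg),
        m_s=np.array(all_ms),
        min_random_per_size=config.min_random_per_size,
        rounds_executed=rounds,
        rng_seed=seed,
        deficient_sizes=deficient,
    )
    logger.info(
        "virtual search: %d rounds, %d random modules over %d size strata",
        rounds, null.n_modules, len(null.stratum_counts()),
    )
    return null


@dataclass(frozen=True)
class ScoredModule:
    """A real module with size-normalized scores and empirical p-values."""

    module: Module
    z_m: float
    z_g: float
    z_s: float
    p_m: float
    p_g: float
    p_s: float
    stratum_fallback: bool
    significant: bool


def normalize_and_test(
    modules: list[Module],
    null: NullDistribution,
    p_cutoff: float = 0.05,
) -> list[ScoredModule]:
    """Size-normalize real module scores and compute empirical p-values.

    Each score (m, m_g, m_s) is z-normalized with the mean and sample
    standard deviation of the size-matched random modules.  The empirical
    p-value is the fraction of all random modules (pooled across sizes
    after the same size-matched normalization) whose normalized score
    strictly exceeds the module's; p = 0 is attainable for modules beyond
    the whole pool.  A module is significant when all three p-values fall
    below ``p_cutoff``.
    """
    pool = null.normalized_pool()
    n_pool = null.n_modules
    out = []
    for mod in modules:
        st, fallback = null.stats_for(mod.size)
        zs = {}
        for name, value in (("m", mod.m), ("m_g", mod.m_g), ("m_s", mod.m_s)):
            sd = st[f"sd_{name}"]
            if sd == 0.0:
                raise ValueError(f"zero-variance null stratum for size {mod.size}")
            zs[name] = (value - st[f"u_{name}"]) / sd
        p_m = float(np.sum(pool["z_m"] > zs["m"])) / n_pool
        p_g = float(np.sum(pool["z_g"] > zs["m_g"])) / n_pool
        p_s = float(np.sum(pool["z_s"] > zs["m_s"])) / n_pool
        out.append(
            ScoredModule(
                module=mod,
                z_m=zs["m"], z_g=zs["m_g"], z_s=zs["m_s"],
                p_m=p_m, p_g=p_g, p_s=p_s,
                stratum_fallback=fallback,
                significant=(p_m < p_cutoff and p_g < p_cutoff and p_s < p_cutoff),
            )
        )
    return out
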