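"""Penalized module scoring and the seed-anchored greedy search.

A module is a connected gene set scored by

    m = m_g + m_s - sd(m_g, m_s)

with m_g = sum(v_g) / sqrt(|v|), m_s = sum(v_s) / sqrt(|v|) and the
penalty sd(m_g, m_s) = |m_g - m_s| / sqrt(2), the distance of the two
component scores from their common mean.  The penalty forces joint
enrichment: a module driven by only one weight system pays for the
deviation.

The search (module expansion with backward examination) starts from every
node as a seed.  At each step the neighbour whose addition maximizes the
new score is added if the score grows by more than a factor (1 + r1);
each successful expansion triggers a trim pass that repeatedly removes
the least-contributing leaf whose removal keeps the score above a factor
(1 - r2) of the current score.  The search stops when no neighbour
qualifies for inclusion; because of the trim step the seed itself may be
absent from the final module.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .network import WeightedNetwork

_SQRT2 = sqrt(2.0)


@dataclass(frozen=True)
class Module:
    """A connected gene set with its penalized score triple.

    ``n_seeds`` records how many seed genes converged on this gene set
    during a full search; it is the module's multiplicity in seed-level
    counts (the proportional test counts one outcome per seed).
    """

    genes: tuple[str, ...]  # insertion order of the search
    seed: str
    m_g: float
    m_s: float
    m: float
    n_seeds: int = 1

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def _score(sum_g: float, sum_s: float, n: int) -> tuple[float, float, float]:
    rn = sqrt(n)
    m_g = sum_g / rn
    m_s = sum_s / rn
    return m_g, m_s, m_g + m_s - abs(m_g - m_s) / _SQRT2


def module_score(
    genes, network: WeightedNetwork
) -> tuple[float, float, float]:
    """Score a gene set on the weighted network; returns (m_g, m_s, m)."""
    genes = list(genes)
    if not genes:
        raise ValueError("cannot score an empty module")
    try:
        idx = [network.index[g] for g in genes]
    except KeyError as exc:
        raise ValueError(f"gene {exc.args[0]!r} is not in the network") from None
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate genes in module")
    return _score(
        float(network.v_g[idx].sum()), float(network.v_s[idx].sum()), len(idx)
    )


def _passes_inclusion(new_m: float, cur_m: float, r1: float) -> bool:
    # For non-positive current scores the multiplicative test is
    # ill-behaved; any strict improvement is accepted instead.
    if cur_m > 0:
        return new_m > cur_m * (1.0 + r1)
    return new_m > cur_m


def _trim_threshold(cur_m: float, r2: float) -> float:
    if cur_m > 0:
        return cur_m * (1.0 - r2)
    return cur_m


def _mebe_indices(
    network: WeightedNetwork, seed_idx: int, r1: float, r2: float
) -> list[int]:
    """Greedy expansion/trim loop over integer node indices."""
    v_g, v_s, adj = network.v_g, network.v_s, network.adj
    total = v_g + v_s
    genes = network.genes

    members: set[int] = {seed_idx}
    order: list[int] = [seed_idx]
    sum_g = float(v_g[seed_idx])
    sum_s = float(v_s[seed_idx])
    _, _, cur_m = _score(sum_g, sum_s, 1)
    # Guard against expansion/trim oscillation (possible when
    # (1 + r1)(1 - r2) < 1): stop if a gene-set state repeats.
    visited: set[frozenset[int]] = {frozenset(members)}

    while True:
        # --- expansion: best-scoring neighbour, ties to the smaller gene id
        candidates: set[int] = set()
        for i in members:
            candidates |= adj[i]
        candidates -= members
        best_idx = -1
        best_m = -np.inf
        best_gene = None
        n_new = len(members) + 1
        for j in candidates:
            _, _, m_new = _score(sum_g + v_g[j], sum_s + v_s[j], n_new)
            if m_new > best_m or (m_new == best_m and genes[j] < best_gene):
                best_idx, best_m, best_gene = j, m_new, genes[j]
        if best_idx < 0 or not _passes_inclusion(best_m, cur_m, r1):
            break
        members.add(best_idx)
        order.append(best_idx)
        sum_g += float(v_g[best_idx])
        sum_s += float(v_s[best_idx])
        cur_m = best_m

        # --- trim: remove marginal leaves, least contributing first
        while len(members) > 1:
            leaves = [
                i for i in members if len(adj[i] & members) <= 1
            ]
            leaves.sort(key=lambda i: (total[i], genes[i]))
            threshold = _trim_threshold(cur_m, r2)
            removed = False
            for i in leaves:
                _, _, m_without = _score(
                    sum_g - v_g[i], sum_s - v_s[i], len(members) - 1
                )
                if m_without > threshold:
                    members.remove(i)
                    order.remove(i)
                    sum_g -= float(v_g[i])
                    sum_s -= float(v_s[i])
                    cur_m = m_without
                    removed = True
                    break
            if not removed:
                break

        state = frozenset(members)
        if state in visited:
            break
        visited.add(state)

    return order


def mebe_from_seed(
    network: WeightedNetwork, seed: str, r1: float, r2: float
) -> Module:
    """Run the expansion/trim search from one seed gene."""
    if seed not in network.index:
        raise ValueError(f"seed gene {seed!r} is not in the network")
    order = _mebe_indices(network, network.index[seed], r1, r2)
    idx = np.array(order)
    m_g, m_s, m = _score(
        float(network.v_g[idx].sum()), float(network.v_s[idx].sum()), len(order)
    )
    return Module(
        genes=tuple(network.genes[i] for i in order),
        seed=seed,
        m_g=m_g,
        m_s=m_s,
        m=m,
    )


def search_all_seeds(
    network: WeightedNetwork, r1: float, r2: float
) -> list[Module]:
    """Run the search from every node and deduplicate identical modules.

    Different seeds frequently converge on the same gene set; each
    distinct set is reported once, attributed to the lexicographically
    smallest seed that produced it.  Output order is deterministic
    (sorted by gene set).
    """
    found: dict[frozenset[int], tuple[str, list[int]]] = {}
    counts: dict[frozenset[int], int] = {}
    v_g, v_s = network.v_g, network.v_s
    for seed_idx, seed in enumerate(network.genes):
        order = _mebe_indices(network, seed_idx, r1, r2)
        key = frozenset(order)
        counts[key] = counts.get(key, 0) + 1
        if key not in found or seed < found[key][0]:
            found[key] = (seed, order)
    modules = []
    for key in sorted(found, key=lambda k: tuple(sorted(network.genes[i] for i in k))):
        seed, order = found[key]
        idx = np.array(order)
        m_g, m_s, m = _score(float(v_g[idx].sum()), float(v_s[idx].sum()), len(order))
        modules.append(
            Module(
                genes=tuple(network.genes[i] for i in order),
                seed=seed,
                m_g=m_g,
                m_s=m_s,
                m=m,
                n_seeds=counts[key],
            )
        )
    return modules
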