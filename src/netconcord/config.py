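"""Run configuration.

All tunable parameters of the analysis live in a single :class:`RunConfig`
dataclass.  A plain YAML key-value file can populate it; command-line flags
override individual fields.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: PathwayCommons interaction types removed from the background network by
#: default.  Genes annotated as being in the same complex tend to be
#: co-expressed and would inflate module scores.
DEFAULT_EXCLUDED_INTERACTION_TYPES = frozenset({"in-complex-with"})

_REGION_RE = re.compile(r"^(\w+):(\d+)[-_](\d+)$")


@dataclass
class RunConfig:
    """Parameters controlling the module search and association test.

    Attributes
    ----------
    r1
        Inclusion threshold of the greedy expansion step: a neighbour is
        added only if the module score grows by more than a factor
        ``(1 + r1)``.
    r2
        Exclusion threshold of the backward trim step: a leaf is removed
        only if the score after removal stays above ``(1 - r2)`` times the
        current score.
    min_random_per_size
        Minimum number of random modules required in every size stratum of
        the permutation null before the virtual search stops.
    max_virtual_rounds
        Hard cap on the number of permutation rounds; deficient strata fall
        back to the nearest populated size.
    module_p_cutoff
        Empirical p-value threshold below which a module counts as
        significant (applied jointly to p_m, p_g and p_s).
    association_z_cutoff
        Two-proportion z statistic above which a trait-cell-type pair is
        declared associated.  The default 5 corresponds to a Bonferroni
        correction over roughly 17,000 trait x cell-type tests.
    rng_seed
        Master seed; all randomness (permutation rounds, GSEA label
        permutations) derives child seeds from it.
    flank_kb_pair_exclusion
        Interacting gene pairs whose gene bodies lie within this distance
        (kb, same chromosome) are removed from the network so that shared
        proximal SNPs are not counted twice.
    mhc_region
        ``(chrom, start, end)`` interval excluded from the network because
        of its complex LD; default is the extended MHC on hg19.
    log_base
        Base of the log(CPM+1) transform: ``"natural"`` or ``"2"``.
    min_cells_per_type
        Cell types represented by fewer cells are dropped.
    max_zero_fraction
        Genes with a zero count in more than this fraction of cells
        (strictly greater) are dropped.
    min_reported_module_size
        Modules smaller than this are kept in all counts but flagged and
        excluded from reported subnetwork genes.
    boxcox_epsilon
        Small positive constant added before the Box-Cox transform so that
        exact zeros (p = 1 genes, silent genes) remain in the domain.
    """

    r1: float = 0.1
    r2: float = 0.1
    min_random_per_size: int = 1000
    max_virtual_rounds: int = 100
    module_p_cutoff: float = 0.05
    association_z_cutoff: float = 5.0
    rng_seed: int = 0
    flank_kb_pair_exclusion: float = 50.0
    mhc_region: tuple[str, int, int] = ("chr6", 26_000_000, 34_000_000)
    log_base: str = "natural"
    min_cells_per_type: int = 30
    max_zero_fraction: float = 0.95
    min_reported_module_size: int = 2
    boxcox_epsilon: float = 1e-6
    excluded_interaction_types: frozenset[str] = DEFAULT_EXCLUDED_INTERACTION_TYPES

    def __post_init__(self) -> None:
        if not (0.0 < self.r1 < 1.0):
            raise ValueError(f"r1 must lie in (0, 1), got {self.r1}")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError(f"r2 must lie in (0, 1), got {self.r2}")
        if not (0.0 < self.module_p_cutoff < 1.0):
            raise ValueError(
                f"module_p_cutoff must lie in (0, 1), got {self.module_p_cutoff}"
            )
        if self.min_random_per_size < 1:
            raise ValueError("min_random_per_size must be >= 1")
        if self.log_base not in ("natural", "2"):
            raise ValueError(f"log_base must be 'natural' or '2', got {self.log_base!r}")
        if isinstance(self.mhc_region, str):
            self.mhc_region = parse_region(self.mhc_region)
        self.mhc_region = (
            str(self.mhc_region[0]),
            int(self.mhc_region[1]),
            int(self.mhc_region[2]),
        )
        if not isinstance(self.excluded_interaction_types, frozenset):
            self.excluded_interaction_types = frozenset(self.excluded_interaction_types)

    def replace(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a YAML key-value file, applying overrides."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a key-value mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mhc_region"] = "{}:{}-{}".format(*self.mhc_region)
        d["excluded_interaction_types"] = sorted(self.excluded_interaction_types)
        return d


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (or ``chrom:start_end``) into a tuple."""
    match = _REGION_RE.match(text.strip())
    if match is None:
        raise ValueError(f"cannot parse genomic region {text!r}")
    chrom, start, end = match.groups()
    start, end = int(start), int(end)
    if end <= start:
        raise ValueError(f"empty region {text!r}")
    return chrom, start, end
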