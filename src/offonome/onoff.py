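"""On/off state calling, offonome gene sets, Venn partitions, and the
count-based filter comparison.

A gene is *on* in a sample iff its LSS is strictly greater than the
threshold (default 0.6, chosen from the bimodal LSS distributions of
sex-specific genes such as XIST); otherwise it is *off*.  The offonome of
a cohort is the set of genes that are off in at least ``min_off_frac``
(default 20%) of samples — genes living near the detection limit that
count-based pre-filters usually discard wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lss import LSSMatrix

__all__ = [
    "OnOffParams",
    "OnOffMatrix",
    "OffonomeSet",
    "CountFilterRule",
    "VennResult",
    "call_on_off",
    "define_offonome",
    "venn_partition",
    "count_filter",
    "overlap_fraction",
]


@dataclass(frozen=True)
class OnOffParams:
    """Binarization rule: on iff LSS strictly greater than ``lss_threshold``."""

    lss_threshold: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.lss_threshold < 1:
            raise ValueError("lss_threshold must be in (0, 1)")


@dataclass
class OnOffMatrix:
    """Binary genes x samples state matrix (1 = on, 0 = off)."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    state: np.ndarray
    params: OnOffParams = field(default_factory=OnOffParams)

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.state.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("state shape does not match gene/sample ids")
        if self.state.size and not np.isin(self.state, (0, 1)).all():
            raise ValueError("state entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.state, index=list(self.gene_ids), columns=list(self.sample_ids))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class OffonomeSet:
    """Offonome of one cohort: genes off in at least ``min_off_frac`` of samples.

    ``off_fraction`` is recorded for *every* gene of the source matrix, not
    just members, so exclusion decisions can be reported.
    """

    cohort_name: str
    gene_ids: frozenset[str]
    off_fraction: dict[str, float]
    min_off_frac: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "cohort_name": self.cohort_name,
            "gene_ids": sorted(self.gene_ids),
            "off_fraction": self.off_fraction,
            "min_off_frac": self.min_off_frac,
            "n_samples": self.n_samples,
        }


@dataclass(frozen=True)
class CountFilterRule:
    """Default parameters of the edgeR-style low-count filter."""

    min_count: float = 10
    min_total_count: float = 15
    min_prop: float = 0.7
    large_n: int = 10

    def __post_init__(self) -> None:
        if min(self.min_count, self.min_total_count, self.min_prop, self.large_n) < 0:
            raise ValueError("count-filter parameters must be non-negative")


@dataclass
class VennResult:
    """Exclusive region counts of 2 or 3 named sets."""

    regions: dict[str, int]
    union_size: int


def call_on_off(lss: LSSMatrix, params: OnOffParams = OnOffParams()) -> OnOffMatrix:
    """Binarize an LSS matrix: state 1 iff value > threshold (equality -> off)."""
    values = lss.values
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("LSS values outside [0, 1]")
    return OnOffMatrix(
        gene_ids=lss.gene_ids,
        sample_ids=lss.sample_ids,
        state=(values > params.lss_threshold).astype(np.int8),
        params=params,
    )


def define_offonome(
    states: OnOffMatrix,
    min_off_frac: float = 0.20,
    cohort_name: str = "",
) -> OffonomeSet:
    """Genes off in at least ``min_off_frac`` of samples (inclusive boundary)."""
    if not 0 < min_off_frac <= 1:
        raise ValueError("min_off_frac must be in (0, 1]")
    n = len(states.sample_ids)
    if n == 0:
        raise ValueError("state matrix has no samples")
    # integer off-counts over n keeps the inclusive boundary exact (2/10 == 0.2)
    off_frac = (n - states.state.sum(axis=1, dtype=np.int64)) / n
    fractions = {gid: float(f) for gid, f in zip(states.gene_ids, off_frac)}
    members = frozenset(gid for gid, f in fractions.items() if f >= min_off_frac)
    return OffonomeSet(
        cohort_name=cohort_name,
        gene_ids=members,
        off_fraction=fractions,
        min_off_frac=min_off_frac,
        n_samples=n,
    )


def venn_partition(sets: Mapping[str, set]) -> VennResult:
    """Exclusive Venn region counts and union size of 2 or 3 named gene sets.

    Region keys are sorted set names joined by ``&`` (e.g. ``"HNSC&LUAD"``);
    each element is counted in exactly one region, so the counts sum to the
    union size and pairwise unions obey inclusion-exclusion.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_partition requires 2 or 3 named sets")
    names = sorted(sets)
    sets = {name: set(sets[name]) for name in names}
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if r < len(names) else set()
            regions["&".join(combo)] = len(inside - outside)
    return VennResult(regions=regions, union_size=len(universe))


def count_filter(
    counts: pd.DataFrame,
    rule: CountFilterRule = CountFilterRule(),
    group: Sequence | None = None,
    lib_size: Sequence[float] | None = None,
) -> frozenset[str]:
    """Genes retained by the edgeR-default low-count rule (filterByExpr semantics).

    ``counts`` is genes x samples.  The CPM cutoff is ``min_count`` scaled
    by the median library size; a gene is kept iff its CPM reaches the
    cutoff in at least ``min_sample_size`` samples — the smallest group
    size, shrunk toward ``large_n + (size - large_n) * min_prop`` for large
    groups — and its total count reaches ``min_total_count``.  With no
    ``group``, all samples form one group.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size and mat.min() < 0:
        raise ValueError("counts must be non-negative")
    lib = np.asarray(lib_size, dtype=float) if lib_size is not None else mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every library must have a positive total count")

    if group is None:
        min_sample_size = float(mat.shape[1])
    else:
        _, counts_per_group = np.unique(np.asarray(group), return_counts=True)
        min_sample_size = float(counts_per_group.min())
    if min_sample_size > rule.large_n:
        min_sample_size = rule.large_n + (min_sample_size - rule.large_n) * rule.min_prop

    cpm_cutoff = rule.min_count / np.median(lib) * 1e6
    cpm = mat / lib * 1e6
    tol = 1e-14
    keep_cpm = (cpm >= cpm_cutoff).sum(axis=1) >= min_sample_size - tol
    keep_total = mat.sum(axis=1) >= rule.min_total_count - tol
    return frozenset(counts.index[keep_cpm & keep_total])


def overlap_fraction(a: set, b: set) -> float:
    """|a ∩ b| / |a| — the fraction of ``a`` that ``b`` also contains."""
    a, b = set(a), set(b)
    if not a:
        raise ValueError("overlap_fraction requires a non-empty first set")
    return len(a & b) / len(a)
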