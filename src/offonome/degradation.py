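"""RNA-degradation (3'-bias) sample filtering.

Degraded RNA loses coverage toward the 5' end of transcripts.  Each
(sample, gene) pair gets a decay rate — here the sign-flipped ordinary
least-squares slope of log10(depth + 1) against normalized 5'->3' exonic
position, so that higher values mean more severe degradation.  The filter
then proceeds in three steps: pool all finite decay rates of the cohort,
take the value at the top ``top_frac`` rank (default 5%) of the descending
sort as the global degraded/non-degraded cut, and exclude any sample in
which more than ``max_degraded_gene_frac`` (default 10%) of its scored
genes exceed that cut.

The decay statistic is a transparent surrogate with the required ordering
semantics (flat coverage -> 0, 3'-biased coverage -> positive); it is
isolated in :func:`decay_rate` so an alternative formula can be swapped in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CohortStore, CoverageMatrix, GeneModel

__all__ = [
    "DecayTable",
    "SampleFilterResult",
    "decay_rate",
    "decay_table",
    "pooled_decay_threshold",
    "flag_degraded",
    "filter_samples",
]

#: minimum exonic positions with nonzero depth for a finite decay value
MIN_COVERED_POSITIONS = 50


@dataclass
class DecayTable:
    """Samples x genes decay rates; NaN marks pairs with too little coverage."""

    decay: pd.DataFrame  # index = sample ids, columns = gene ids

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.decay.index)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.decay.columns)

    @property
    def n_pooled(self) -> int:
        return int(self.decay.notna().sum().sum())


@dataclass
class SampleFilterResult:
    threshold: float
    degraded_gene_frac: dict[str, float]
    retained: tuple[str, ...]
    excluded: tuple[str, ...]
    top_frac: float
    max_degraded_gene_frac: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "degraded_gene_frac": self.degraded_gene_frac,
            "retained": list(self.retained),
            "excluded": list(self.excluded),
            "params": {
                "top_frac": self.top_frac,
                "max_degraded_gene_frac": self.max_degraded_gene_frac,
            },
        }


def decay_rate(
    matrix: CoverageMatrix,
    sample: str,
    model: GeneModel,
    min_covered: int = MIN_COVERED_POSITIONS,
) -> float:
    """Decay rate of one sample at one gene; NaN if coverage is too sparse.

    Exonic depths are taken 5'->3' (genomic order reversed for minus-strand
    genes), positions normalized to [0, 1], and the OLS slope of
    log10(depth + 1) is sign-flipped: loss of coverage toward the 5' end
    yields a positive value.
    """
    if sample not in matrix.sample_ids:
        raise KeyError(f"sample {sample!r} not in coverage matrix of {matrix.gene_id}")
    j = matrix.sample_ids.index(sample)
    col = matrix.depth[matrix.exon_mask, j].astype(float)
    if model.strand == "-":
        col = col[::-1]
    if int(np.count_nonzero(col)) < min_covered or col.size < 2:
        return float("nan")
    x = np.linspace(0.0, 1.0, col.size)
    y = np.log10(col + 1.0)
    # closed-form OLS slope: cov(x, y) / var(x)
    xc = x - x.mean()
    slope = float(np.dot(xc, y) / np.dot(xc, xc))
    return -slope


def decay_table(store: CohortStore, min_covered: int = MIN_COVERED_POSITIONS) -> DecayTable:
    """Decay rates of every (sample, gene) pair of a cohort store."""
    gene_ids = store.gene_ids
    sample_ids = store.sample_ids
    out = np.full((len(sample_ids), len(gene_ids)), np.nan)
    for gi, gid in enumerate(gene_ids):
        matrix = store.get(gid)
        model = store.get_model(gid)
        for si, sid in enumerate(sample_ids):
            out[si, gi] = decay_rate(matrix, sid, model, min_covered=min_covered)
    return DecayTable(pd.DataFrame(out, index=list(sample_ids), columns=list(gene_ids)))


def pooled_decay_threshold(table: DecayTable, top_frac: float = 0.05) -> float:
    """Global degraded/non-degraded cut: pooled decay value at the
    ``ceil(top_frac * n)``-th rank of the descending sort (1-based)."""
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must be in (0, 1)")
    pooled = table.decay.to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("decay table has no finite values to pool")
    pooled = np.sort(pooled)[::-1]
    rank = math.ceil(top_frac * pooled.size)
    return float(pooled[rank - 1])


def flag_degraded(
    table: DecayTable,
    threshold: float,
    max_degraded_gene_frac: float = 0.10,
    top_frac: float = 0.05,
) -> SampleFilterResult:
    """Partition samples into retained/excluded by their degraded-gene fraction.

    A (sample, gene) entry is degraded iff decay > threshold; a sample is
    excluded iff its degraded fraction is strictly greater than
    ``max_degraded_gene_frac``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    fracs: dict[str, float] = {}
    retained, excluded = [], []
    for sid in table.sample_ids:
        row = table.decay.loc[sid].to_numpy()
        finite = np.isfinite(row)
        n_scored = int(finite.sum())
        if n_scored == 0:
            warnings.warn(f"sample {sid!r} has no scored genes; retained with fraction 0")
            frac = 0.0
        else:
            frac = float((row[finite] > threshold).sum() / n_scored)
        fracs[sid] = frac
        (excluded if frac > max_degraded_gene_frac else retained).append(sid)
    return SampleFilterResult(
        threshold=float(threshold),
        degraded_gene_frac=fracs,
        retained=tuple(retained),
        excluded=tuple(excluded),
        top_frac=top_frac,
        max_degraded_gene_frac=max_degraded_gene_frac,
    )


def filter_samples(
    store: CohortStore,
    top_frac: float = 0.05,
    max_degraded_gene_frac: float = 0.10,
    min_covered: int = MIN_COVERED_POSITIONS,
) -> SampleFilterResult:
    """Run the full 3-step degradation filter on a cohort store."""
    table = decay_table(store, min_covered=min_covered)
    threshold = pooled_decay_threshold(table, top_frac=top_frac)
    return flag_degraded(table, threshold, max_degraded_gene_frac, top_frac=top_frac)
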