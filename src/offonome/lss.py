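"""Level of Shape Similarity (LSS).

LSS scores how closely a sample's base-resolution coverage profile for a
gene matches the cohort consensus shape.  Each pileup column is
log10(depth + k)-transformed (k = 1 by default, so zero depth maps to 0),
a consensus mean profile is estimated by iteratively trimming the
least-similar samples, and each sample is scored by the cosine of the angle
between its log-adjusted vector and the consensus.  Values lie in [0, 1]:
1 means the sample's coverage is an exact scalar multiple of the consensus
shape; 0 means no shared structure (or no reads at all).

Genes with zero reads in every sample — and genes expressed in fewer than
``min_expressed_frac`` of samples, for which no consensus shape is
defensible — receive LSS 0 for all samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import CohortStore, CoverageMatrix

__all__ = [
    "LSSParams",
    "MeanProfile",
    "LSSMatrix",
    "log_adjust",
    "shape_cosine",
    "mean_profile",
    "compute_lss",
    "compute_lss_cohort",
]


@dataclass(frozen=True)
class LSSParams:
    """Tunable parameters of the LSS computation.

    k
        pseudo-offset inside the log transform, ``log10(depth + k)``.
    min_expressed_frac
        minimum fraction of samples with any reads for the gene's mean
        profile to be defined; below it every sample scores 0.
    max_iter, tol
        cap and L2 convergence tolerance of the trimmed mean-profile
        iteration.
    trim_quantile
        fraction of least-similar expressed samples excluded when the mean
        is re-estimated (floor of ``trim_quantile * n_expressed`` samples).
    domain
        ``"full_locus"`` scores coverage over exons and introns;
        ``"exons_only"`` restricts to exonic positions.
    """

    k: float = 1.0
    min_expressed_frac: float = 0.05
    max_iter: int = 20
    tol: float = 1e-6
    trim_quantile: float = 0.05
    domain: str = "full_locus"

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be > 0")
        if not 0 <= self.min_expressed_frac < 1:
            raise ValueError("min_expressed_frac must be in [0, 1)")
        if not 0 < self.trim_quantile < 0.5:
            raise ValueError("trim_quantile must be in (0, 0.5)")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.domain not in ("full_locus", "exons_only"):
            raise ValueError("domain must be 'full_locus' or 'exons_only'")


@dataclass
class MeanProfile:
    """Cohort-consensus coverage shape of one gene (log-adjusted space)."""

    gene_id: str
    vector: np.ndarray | None
    expressed_fraction: float
    defined: bool
    n_iterations: int = 0
    converged: bool = False


@dataclass
class LSSMatrix:
    """Genes x samples matrix of LSS values in [0, 1]."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("LSS values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    def to_tsv(self, path) -> None:
        self.to_frame().round(6).to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LSSMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))


def log_adjust(depth, k: float = 1.0):
    """Elementwise ``log10(depth + k)``; with k=1, zero depth maps to 0."""
    if k <= 0:
        raise ValueError("k must be > 0")
    arr = np.asarray(depth, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("read depth must be non-negative")
    out = np.log10(arr + k)
    return out if out.ndim else float(out)


def shape_cosine(u, v) -> float:
    """Cosine similarity of two non-negative vectors; 0 if either has zero norm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    if (u.size and u.min() < 0) or (v.size and v.min() < 0):
        raise ValueError("shape_cosine requires non-negative entries")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def mean_profile(
    logged: np.ndarray,
    params: LSSParams = LSSParams(),
    sample_ids: Sequence[str] | None = None,
    gene_id: str = "",
) -> MeanProfile:
    """Estimate the consensus coverage shape from log-adjusted columns.

    Expressed samples are those with any positive (log-adjusted) signal.
    The mean over the current sample set is computed, every expressed
    sample is scored against it, the lowest ``trim_quantile`` are dropped,
    and the mean re-estimated — until the L2 change of the mean falls below
    ``tol`` or ``max_iter`` rounds elapse.  Trim ties are broken by
    sample-id lexicographic order so the result is deterministic.
    """
    logged = np.asarray(logged, dtype=float)
    if logged.ndim != 2 or logged.size == 0:
        raise ValueError("mean_profile requires a non-empty positions x samples matrix")
    n_samples = logged.shape[1]
    if sample_ids is None:
        sample_ids = [f"s{i:06d}" for i in range(n_samples)]

    expressed = np.flatnonzero(logged.sum(axis=0) > 0)
    frac = expressed.size / n_samples
    if frac < params.min_expressed_frac or expressed.size == 0:
        return MeanProfile(gene_id=gene_id, vector=None, expressed_fraction=frac, defined=False)

    n_drop = math.floor(params.trim_quantile * expressed.size)
    active = expressed
    mean_vec = logged[:, active].mean(axis=1)
    n_iter = 0
    converged = False
    for _ in range(params.max_iter):
        n_iter += 1
        if n_drop > 0:
            cos = np.array([shape_cosine(logged[:, j], mean_vec) for j in expressed])
            order = sorted(range(expressed.size), key=lambda i: (cos[i], sample_ids[expressed[i]]))
            active = np.array(sorted(expressed[order[n_drop:]]))
        new_mean = logged[:, active].mean(axis=1)
        if np.linalg.norm(new_mean - mean_vec) < params.tol:
            mean_vec = new_mean
            converged = True
            break
        mean_vec = new_mean
    return MeanProfile(
        gene_id=gene_id,
        vector=mean_vec,
        expressed_fraction=frac,
        defined=True,
        n_iterations=n_iter,
        converged=converged,
    )


def compute_lss(
    matrix: CoverageMatrix,
    params: LSSParams = LSSParams(),
    return_profile: bool = False,
):
    """LSS of every sample of one gene.

    All-zero genes and genes whose mean profile is undefined score exactly
    0 everywhere; zero-depth samples score 0 through the zero-norm rule.
    """
    if params.domain == "exons_only":
        matrix = matrix.exons_only()
    depth = matrix.depth
    n = matrix.n_samples
    profile = MeanProfile(gene_id=matrix.gene_id, vector=None, expressed_fraction=0.0, defined=False)
    if depth.size == 0 or not depth.any():
        values = np.zeros(n)
    else:
        logged = log_adjust(depth, params.k)
        profile = mean_profile(logged, params, sample_ids=matrix.sample_ids, gene_id=matrix.gene_id)
        if not profile.defined:
            values = np.zeros(n)
        else:
            values = np.array([shape_cosine(logged[:, j], profile.vector) for j in range(n)])
            values = np.clip(values, 0.0, 1.0)
    return (values, profile) if return_profile else values


def compute_lss_cohort(
    store: CohortStore,
    params: LSSParams = LSSParams(),
    gene_ids: Sequence[str] | None = None,
    sample_subset: Sequence[str] | None = None,
) -> LSSMatrix:
    """LSS matrix for every gene in a cohort store, with per-gene diagnostics.

    ``sample_subset`` restricts the computation (including mean-profile
    estimation) to the given samples, e.g. those retained by the
    degradation filter.
    """
    if len(store) == 0:
        raise ValueError("cohort store is empty")
    gene_ids = tuple(gene_ids) if gene_ids is not None else store.gene_ids
    sample_ids = tuple(sample_subset) if sample_subset is not None else store.sample_ids
    values = np.zeros((len(gene_ids), len(sample_ids)))
    diagnostics: dict[str, dict] = {}
    for i, gid in enumerate(gene_ids):
        matrix = store.get(gid)
        if sample_subset is not None:
            matrix = matrix.subset_samples(sample_ids)
        elif matrix.sample_ids != sample_ids:
            raise ValueError(f"gene {gid!r} has an inconsistent sample set")
        vec, profile = compute_lss(matrix, params, return_profile=True)
        values[i] = vec
        diagnostics[gid] = {
            "expressed_fraction": profile.expressed_fraction,
            "defined": profile.defined,
            "n_iterations": profile.n_iterations,
            "converged": profile.converged,
        }
    return LSSMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values, diagnostics=diagnostics)
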