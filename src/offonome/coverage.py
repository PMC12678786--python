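"""Gene models, base-resolution coverage extraction, and cohort storage.

A gene's coverage is represented at single-base resolution over the full
genomic locus (exons *and* introns): one integer read-depth vector per
sample, assembled into a positions x samples matrix.  This is the "pileup
data object" every downstream shape computation operates on.

Coordinates are 0-based half-open internally.  GTF input is interpreted as
1-based inclusive, BED12 as 0-based half-open, per their standards.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pysam

__all__ = [
    "GeneModel",
    "CoverageMatrix",
    "CohortStore",
    "CoverageError",
    "MissingGeneError",
    "load_gene_models",
    "extract_gene_coverage",
]


class CoverageError(Exception):
    """Raised on malformed annotation, alignment, or store input."""


class MissingGeneError(CoverageError):
    """A requested gene id is absent from the annotation."""


@dataclass(frozen=True)
class GeneModel:
    """Genomic locus and exon structure of one gene.

    ``exons`` are absolute genomic intervals, 0-based half-open, sorted and
    non-overlapping, all contained in ``[start, end)``.  The locus (including
    introns) defines the coordinate axis of every coverage vector.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CoverageError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.end > self.start >= 0:
            raise CoverageError(f"{self.gene_id}: empty or inverted locus [{self.start}, {self.end})")
        prev_end = self.start - 1
        for s, e in self.exons:
            if s >= e:
                raise CoverageError(f"{self.gene_id}: empty exon ({s}, {e})")
            if s <= prev_end:
                raise CoverageError(f"{self.gene_id}: exons unsorted or overlapping at ({s}, {e})")
            if s < self.start or e > self.end:
                raise CoverageError(f"{self.gene_id}: exon ({s}, {e}) outside locus")
            prev_end = e

    @property
    def locus_length(self) -> int:
        return self.end - self.start

    @property
    def exons_local(self) -> tuple[tuple[int, int], ...]:
        """Exon intervals relative to the locus start."""
        return tuple((s - self.start, e - self.start) for s, e in self.exons)

    def exon_mask(self) -> np.ndarray:
        mask = np.zeros(self.locus_length, dtype=bool)
        for s, e in self.exons:
            mask[s - self.start : e - self.start] = True
        return mask


@dataclass
class CoverageMatrix:
    """Per-gene positions x samples integer read-depth matrix.

    Rows are consecutive genomic positions of the full gene locus;
    ``exon_mask`` marks exonic rows.
    """

    gene_id: str
    sample_ids: tuple[str, ...]
    depth: np.ndarray
    exon_mask: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        self.exon_mask = np.asarray(self.exon_mask, dtype=bool)
        if self.depth.ndim != 2:
            raise CoverageError("depth must be 2-D (positions x samples)")
        if self.depth.shape[1] != len(self.sample_ids):
            raise CoverageError("depth column count != number of sample ids")
        if self.depth.shape[0] != self.exon_mask.shape[0]:
            raise CoverageError("exon_mask length != number of positions")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CoverageError("duplicate sample ids")
        if self.depth.size and self.depth.min() < 0:
            raise CoverageError("negative read depth")

    @property
    def n_positions(self) -> int:
        return self.depth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.depth.shape[1]

    def subset_samples(self, keep: Sequence[str]) -> "CoverageMatrix":
        """Restrict to the given samples, in the given order."""
        idx = []
        for sid in keep:
            if sid not in self.sample_ids:
                raise CoverageError(f"sample {sid!r} not in matrix of {self.gene_id}")
            idx.append(self.sample_ids.index(sid))
        return CoverageMatrix(
            gene_id=self.gene_id,
            sample_ids=tuple(keep),
            depth=self.depth[:, idx],
            exon_mask=self.exon_mask,
        )

    def exons_only(self) -> "CoverageMatrix":
        """Project onto exonic positions (concatenated in genomic order)."""
        return CoverageMatrix(
            gene_id=self.gene_id,
            sample_ids=self.sample_ids,
            depth=self.depth[self.exon_mask],
            exon_mask=np.ones(int(self.exon_mask.sum()), dtype=bool),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write ``position<TAB>sample1<TAB>...`` rows (0-based locus positions)."""
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(self.sample_ids) + "\n")
            for i in range(self.n_positions):
                fh.write(str(i) + "\t" + "\t".join(str(int(v)) for v in self.depth[i]) + "\n")


# ---------------------------------------------------------------------------
# Gene-model loading


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _load_gtf(path: Path, gene_ids: Sequence[str] | None) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise CoverageError(f"failed to parse GTF {path}: {exc}") from exc

    per_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise CoverageError(f"GTF exon record without gene_id near {feat.seqid}:{feat.start}")
        rec = per_gene.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": []})
        # GTF is 1-based inclusive -> 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))
    return _finalize_models(per_gene, gene_ids)


def _load_bed12(path: Path, gene_ids: Sequence[str] | None) -> list[GeneModel]:
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise CoverageError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(cols)}")
            try:
                chrom, chrom_start, chrom_end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
                strand = cols[5]
                n_blocks = int(cols[9])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise CoverageError(f"{path}:{lineno}: malformed BED12 record: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise CoverageError(f"{path}:{lineno}: blockCount does not match block lists")
            exons = [(chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)]
            rec = per_gene.setdefault(name, {"chrom": chrom, "strand": strand, "exons": []})
            rec["exons"].extend(exons)
    return _finalize_models(per_gene, gene_ids)


def _finalize_models(per_gene: dict[str, dict], gene_ids: Sequence[str] | None) -> list[GeneModel]:
    if gene_ids is not None:
        missing = [g for g in gene_ids if g not in per_gene]
        if missing:
            raise MissingGeneError(f"gene id(s) not found in annotation: {', '.join(missing)}")
        per_gene = {g: per_gene[g] for g in gene_ids}
    models = []
    for gid, rec in per_gene.items():
        exons = _merge_intervals(rec["exons"])
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=exons[0][0],
                end=exons[-1][1],
                exons=exons,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def load_gene_models(
    path: str | Path,
    format: str | None = None,
    gene_ids: Sequence[str] | None = None,
) -> list[GeneModel]:
    """Load gene models from a GTF or BED12 annotation.

    Overlapping exon records of one gene are merged; output is ordered by
    (chrom, locus start, gene id).  ``format`` may be ``"gtf"`` or
    ``"bed12"``; when ``None`` it is inferred from the file suffix.
    """
    path = Path(path)
    if gene_ids is not None and len(gene_ids) == 0:
        raise CoverageError("gene_ids filter must be non-empty if given")
    if format is None:
        suffix = path.suffix.lower()
        format = {".gtf": "gtf", ".gff": "gtf", ".bed": "bed12", ".bed12": "bed12"}.get(suffix)
        if format is None:
            raise CoverageError(f"cannot infer annotation format from suffix {suffix!r}")
    format = format.lower()
    if format == "gtf":
        return _load_gtf(path, gene_ids)
    if format in ("bed", "bed12"):
        return _load_bed12(path, gene_ids)
    raise CoverageError(f"unknown annotation format {format!r} (expected 'gtf' or 'bed12')")


# ---------------------------------------------------------------------------
# Coverage extraction


def _iter_region(af: pysam.AlignmentFile, chrom: str, start: int, end: int):
    """Yield reads overlapping [start, end); falls back to a full scan for
    un-indexed (e.g. plain SAM) inputs."""
    if af.has_index():
        yield from af.fetch(chrom, start, end)
        return
    if af.is_bam:
        raise CoverageError(f"BAM file {af.filename!r} has no index (.bai); index it first")
    for read in af.fetch(until_eof=True):
        if read.is_unmapped or read.reference_name != chrom:
            continue
        if read.reference_start < end and read.reference_end is not None and read.reference_end > start:
            yield read


def extract_gene_coverage(
    alignment_files: Sequence[str | Path],
    model: GeneModel,
    sample_ids: Sequence[str] | None = None,
    min_mapq: int = 0,
    count_mode: str = "primary_only",
    keep_duplicates: bool = True,
) -> CoverageMatrix:
    """Build the per-base coverage matrix of one gene from BAM/SAM files.

    ``depth[p, s]`` counts aligned bases of retained reads of sample ``s``
    covering locus position ``p``; spliced reads (CIGAR ``N``) and deletions
    contribute nothing to skipped reference positions.  Counting is
    strand-agnostic.  ``count_mode`` is ``"primary_only"`` (default: skip
    secondary and supplementary alignments) or ``"all_reads"``.
    """
    if count_mode not in ("primary_only", "all_reads"):
        raise CoverageError(f"unknown count_mode {count_mode!r}")
    paths = [Path(p) for p in alignment_files]
    if sample_ids is None:
        sample_ids = [p.name.split(".")[0] for p in paths]
    if len(sample_ids) != len(paths):
        raise CoverageError("sample_ids length must match alignment_files")

    L = model.locus_length
    depth = np.zeros((L, len(paths)), dtype=np.int64)
    for j, path in enumerate(paths):
        with pysam.AlignmentFile(str(path)) as af:
            if model.chrom not in af.references:
                raise CoverageError(f"contig {model.chrom!r} absent from {path}")
            for read in _iter_region(af, model.chrom, model.start, model.end):
                if read.is_unmapped:
                    continue
                if count_mode == "primary_only" and (read.is_secondary or read.is_supplementary):
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                if not keep_duplicates and read.is_duplicate:
                    continue
                for blk_start, blk_end in read.get_blocks():
                    s = max(blk_start, model.start) - model.start
                    e = min(blk_end, model.end) - model.start
                    if s < e:
                        depth[s:e, j] += 1
    return CoverageMatrix(
        gene_id=model.gene_id,
        sample_ids=tuple(sample_ids),
        depth=depth,
        exon_mask=model.exon_mask(),
    )


# ---------------------------------------------------------------------------
# Cohort storage


class CohortStore:
    """HDF5-backed container of per-gene coverage matrices for one cohort.

    Every gene shares one sample order; per-gene groups store the integer
    depth matrix bit-exactly alongside the gene model.  A JSON manifest
    (cohort name, provenance, extraction parameters) lives in file attrs.
    """

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, mode)

    # -- lifecycle ---------------------------------------------------------
    @classmethod
    def create(
        cls,
        path: str | Path,
        cohort_name: str,
        sample_ids: Sequence[str],
        provenance: dict | None = None,
    ) -> "CohortStore":
        store = cls(path, mode="w")
        store._h5.attrs["cohort_name"] = cohort_name
        store._h5.attrs["sample_ids"] = json.dumps(list(sample_ids))
        store._h5.attrs["provenance"] = json.dumps(provenance or {})
        store._h5.create_group("genes")
        return store

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "CohortStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- accessors ---------------------------------------------------------
    @property
    def cohort_name(self) -> str:
        return str(self._h5.attrs["cohort_name"])

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(json.loads(self._h5.attrs["sample_ids"]))

    @property
    def provenance(self) -> dict:
        return json.loads(self._h5.attrs["provenance"])

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._h5["genes"].keys()))

    def __len__(self) -> int:
        return len(self._h5["genes"])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._h5["genes"]

    # -- I/O ---------------------------------------------------------------
    def add(self, matrix: CoverageMatrix, model: GeneModel | None = None) -> None:
        if tuple(matrix.sample_ids) != self.sample_ids:
            raise CoverageError(
                f"sample order of {matrix.gene_id} does not match the cohort manifest"
            )
        grp = self._h5["genes"].create_group(matrix.gene_id)
        grp.create_dataset("depth", data=matrix.depth.astype(np.int64), compression="gzip")
        grp.create_dataset("exon_mask", data=matrix.exon_mask)
        if model is not None:
            grp.attrs["chrom"] = model.chrom
            grp.attrs["strand"] = model.strand
            grp.attrs["start"] = model.start
            grp.attrs["end"] = model.end
            grp.create_dataset("exons", data=np.asarray(model.exons, dtype=np.int64))

    def get(self, gene_id: str) -> CoverageMatrix:
        if gene_id not in self:
            raise MissingGeneError(f"gene {gene_id!r} not in store")
        grp = self._h5["genes"][gene_id]
        return CoverageMatrix(
            gene_id=gene_id,
            sample_ids=self.sample_ids,
            depth=grp["depth"][...],
            exon_mask=grp["exon_mask"][...].astype(bool),
        )

    def get_model(self, gene_id: str) -> GeneModel:
        if gene_id not in self:
            raise MissingGeneError(f"gene {gene_id!r} not in store")
        grp = self._h5["genes"][gene_id]
        if "exons" not in grp:
            raise CoverageError(f"gene {gene_id!r} stored without a gene model")
        exons = tuple((int(s), int(e)) for s, e in grp["exons"][...])
        return GeneModel(
            gene_id=gene_id,
            chrom=str(grp.attrs["chrom"]),
            strand=str(grp.attrs["strand"]),
            start=int(grp.attrs["start"]),
            end=int(grp.attrs["end"]),
            exons=exons,
        )
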