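"""Gene-model parsing, coverage extraction, and cohort-store roundtrips."""

import re

import numpy as np
import pysam
import pytest

from offonome import (
    CohortStore,
    CoverageError,
    CoverageMatrix,
    GeneModel,
    MissingGeneError,
    extract_gene_coverage,
    load_gene_models,
)

from conftest import TOY_SAM, single_gene_matrix


# ---------------------------------------------------------------------------
# gene models


def test_bed12_block_decoding(toy_bed12):
    models = load_gene_models(toy_bed12, format="bed12", gene_ids=["gX"])
    (m,) = models
    assert m.exons_local == ((0, 100), (200, 250))
    assert m.locus_length == 250
    assert m.strand == "+"


def test_gtf_overlapping_exons_merged(toy_gtf):
    models = {m.gene_id: m for m in load_gene_models(toy_gtf, format="gtf")}
    # gA transcripts have exons 101-200 and 191-250 (1-based) overlapping by 10 bp
    assert models["gA"].exons == ((100, 250), (300, 400))
    assert models["gB"].strand == "-"


def test_gtf_ordering_matches_hand_parsed_fixture(toy_gtf):
    # independent hand parse of the 3-gene toy annotation
    expected = [
        ("gA", "chr1", 100, 400),
        ("gB", "chr1", 1000, 1100),
        ("gC", "chr2", 50, 150),
    ]
    models = load_gene_models(toy_gtf)
    assert [(m.gene_id, m.chrom, m.start, m.end) for m in models] == expected


def test_missing_gene_and_unknown_format(toy_gtf):
    with pytest.raises(MissingGeneError, match="nosuch"):
        load_gene_models(toy_gtf, gene_ids=["gA", "nosuch"])
    with pytest.raises(CoverageError, match="format"):
        load_gene_models(toy_gtf, format="gff3z")


def test_bed12_malformed_record_names_line(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t0\t100\tg\t0\t+\t0\t100\t0\t2\t100\t0\n")
    with pytest.raises(CoverageError, match=":1:"):
        load_gene_models(bad, format="bed12")


def test_gene_model_invariants_rejected():
    with pytest.raises(CoverageError):
        GeneModel("g", "chr1", "+", 0, 100, exons=((0, 50), (40, 80)))  # overlap
    with pytest.raises(CoverageError):
        GeneModel("g", "chr1", "+", 10, 10, exons=())  # empty locus


# ---------------------------------------------------------------------------
# coverage extraction


def naive_pileup(sam_text, chrom, start, end):
    """Independent oracle: per-base overlap counting by walking CIGAR ops."""
    depth = np.zeros(end - start, dtype=int)
    for line in sam_text.splitlines():
        if line.startswith("@"):
            continue
        f = line.split("\t")
        if f[2] != chrom:
            continue
        pos = int(f[3]) - 1
        for n, op in re.findall(r"(\d+)([MIDNSHP=X])", f[5]):
            n = int(n)
            if op in "M=X":
                for p in range(pos, pos + n):
                    if start <= p < end:
                        depth[p - start] += 1
                pos += n
            elif op in "DN":
                pos += n
    return depth


def test_extraction_matches_naive_cigar_oracle(toy_sam, toy_model):
    matrix = extract_gene_coverage([toy_sam], toy_model, sample_ids=["s1"])
    expected = naive_pileup(TOY_SAM, "chr1", 100, 400)
    assert np.array_equal(matrix.depth[:, 0], expected)
    # column sum equals total aligned bases of retained reads inside the locus
    assert matrix.depth[:, 0].sum() == expected.sum()


def test_single_read_pileup(tmp_path, toy_model):
    sam = tmp_path / "one.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n"
        "r\t0\tchr1\t106\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
    )
    matrix = extract_gene_coverage([sam], toy_model)
    expected = np.zeros(300, dtype=int)
    expected[5:15] = 1  # locus positions 5..14
    assert np.array_equal(matrix.depth[:, 0], expected)


def test_empty_alignment_gives_zero_column(tmp_path, toy_model):
    sam = tmp_path / "empty.sam"
    sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:10000\n")
    matrix = extract_gene_coverage([sam], toy_model)
    assert not matrix.depth.any()


def test_missing_contig_is_error(tmp_path):
    sam = tmp_path / "c.sam"
    sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chr9\tLN:1000\n")
    model = GeneModel("g", "chr1", "+", 0, 100, exons=((0, 100),))
    with pytest.raises(CoverageError, match="chr1"):
        extract_gene_coverage([sam], model)


def test_extraction_additive_over_read_partition(tmp_path, toy_model):
    """Coverage of a file equals the sum over any read-disjoint split of it."""
    lines = TOY_SAM.splitlines()
    header = [l for l in lines if l.startswith("@")]
    reads = [l for l in lines if not l.startswith("@")]
    full = tmp_path / "full.sam"
    full.write_text("\n".join(header + reads) + "\n")
    part1 = tmp_path / "p1.sam"
    part1.write_text("\n".join(header + reads[:2]) + "\n")
    part2 = tmp_path / "p2.sam"
    part2.write_text("\n".join(header + reads[2:]) + "\n")
    shuffled = tmp_path / "shuf.sam"
    shuffled.write_text("\n".join(header + reads[::-1]) + "\n")

    d_full = extract_gene_coverage([full], toy_model).depth[:, 0]
    d_sum = (
        extract_gene_coverage([part1], toy_model).depth[:, 0]
        + extract_gene_coverage([part2], toy_model).depth[:, 0]
    )
    d_shuf = extract_gene_coverage([shuffled], toy_model).depth[:, 0]
    assert np.array_equal(d_full, d_sum)
    assert np.array_equal(d_full, d_shuf)


def test_indexed_bam_fetch_agrees_with_sam_scan(tmp_path, toy_sam, toy_model):
    bam = tmp_path / "toy.bam"
    pysam.sort("-o", str(bam), str(toy_sam))
    pysam.index(str(bam))
    d_sam = extract_gene_coverage([toy_sam], toy_model).depth
    d_bam = extract_gene_coverage([bam], toy_model).depth
    assert np.array_equal(d_sam, d_bam)


# ---------------------------------------------------------------------------
# cohort store


def test_store_roundtrip_bit_identical(tmp_path):
    rng = np.random.default_rng(0)
    matrix = single_gene_matrix(rng.integers(0, 1000, size=(40, 3)))
    matrix.depth[0, 0] = 2**31 - 1  # dtype bound preserved exactly
    with CohortStore.create(tmp_path / "c.h5", "c", matrix.sample_ids) as store:
        store.add(matrix)
    with CohortStore(tmp_path / "c.h5") as store:
        back = store.get("g1")
    assert np.array_equal(back.depth, matrix.depth)
    assert back.sample_ids == matrix.sample_ids
    assert np.array_equal(back.exon_mask, matrix.exon_mask)


def test_store_roundtrip_many_genes(tmp_path):
    rng = np.random.default_rng(1)
    sample_ids = ("a", "b", "c", "d")
    matrices = {
        f"g{i:02d}": single_gene_matrix(
            rng.integers(0, 50, size=(rng.integers(10, 30), 4)),
            gene_id=f"g{i:02d}",
            sample_ids=sample_ids,
        )
        for i in range(50)
    }
    with CohortStore.create(tmp_path / "c.h5", "c", sample_ids) as store:
        for m in matrices.values():
            store.add(m)
    with CohortStore(tmp_path / "c.h5") as store:
        assert len(store) == 50
        for gid, m in matrices.items():
            assert np.array_equal(store.get(gid).depth, m.depth)


def test_store_rejects_sample_order_mismatch(tmp_path):
    matrix = single_gene_matrix(np.ones((5, 2), dtype=int), sample_ids=("a", "b"))
    with CohortStore.create(tmp_path / "c.h5", "c", ("b", "a")) as store:
        with pytest.raises(CoverageError, match="sample order"):
            store.add(matrix)


def test_subset_and_exon_projection():
    depth = np.arange(12).reshape(4, 3)
    m = CoverageMatrix("g", ("a", "b", "c"), depth, np.array([True, False, True, False]))
    sub = m.subset_samples(["c", "a"])
    assert np.array_equal(sub.depth, depth[:, [2, 0]])
    ex = m.exons_only()
    assert np.array_equal(ex.depth, depth[[0, 2]])
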