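import numpy as np
import pytest

from offonome import CoverageMatrix, GeneModel, SimParams, simulate_cohort

TOY_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\ttest\texon\t191\t250\t.\t+\t.\tgene_id "gA"; transcript_id "gA.2";
chr1\ttest\texon\t1001\t1100\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";
chr2\ttest\texon\t51\t150\t.\t+\t.\tgene_id "gC"; transcript_id "gC.1";
"""

TOY_BED12 = (
    "chr1\t0\t250\tgX\t0\t+\t0\t250\t0\t2\t100,50,\t0,200,\n"
    "chr1\t500\t800\tgY\t0\t-\t500\t800\t0\t3\t50,50,50\t0,100,250\n"
)

# five hand-written reads over a 2-exon locus, one with a 100N splice junction
TOY_SAM = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:chr1\tLN:10000
r5\t0\tchr1\t90\t60\t5M2D15M\t*\t0\t0\t{seq20}\t*
r1\t0\tchr1\t106\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*
r2\t0\tchr1\t151\t60\t30M\t*\t0\t0\t{seq30}\t*
r3\t0\tchr1\t151\t60\t50M100N50M\t*\t0\t0\t{seq100}\t*
r4\t0\tchr1\t395\t60\t20M\t*\t0\t0\t{seq20}\t*
""".format(seq30="A" * 30, seq100="A" * 100, seq20="A" * 20)


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture
def toy_bed12(tmp_path):
    path = tmp_path / "toy.bed"
    path.write_text(TOY_BED12)
    return path


@pytest.fixture
def toy_sam(tmp_path):
    path = tmp_path / "toy.sam"
    path.write_text(TOY_SAM)
    return path


@pytest.fixture
def toy_model():
    """2-exon gene spanning the toy SAM reads (locus chr1:100-400, 0-based)."""
    return GeneModel(
        gene_id="gA",
        chrom="chr1",
        strand="+",
        start=100,
        end=400,
        exons=((100, 200), (300, 400)),
    )


def single_gene_matrix(depth, gene_id="g1", sample_ids=None):
    depth = np.asarray(depth)
    if sample_ids is None:
        sample_ids = tuple(f"s{j}" for j in range(depth.shape[1]))
    return CoverageMatrix(
        gene_id=gene_id,
        sample_ids=tuple(sample_ids),
        depth=depth,
        exon_mask=np.ones(depth.shape[0], dtype=bool),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort at default study conditions, shared across tests."""
    return simulate_cohort(SimParams(seed=20260920, n_genes=30, n_samples=50))


@pytest.fixture(scope="session")
def default_store(default_cohort, tmp_path_factory):
    from offonome import CohortStore

    path = tmp_path_factory.mktemp("cohort") / "cohort.h5cov"
    default_cohort.to_store(path)
    store = CohortStore(path)
    yield store
    store.close()
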