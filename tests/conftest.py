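import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from spliceqtl.io import TranscriptModel, VariantRecord, GenotypeMatrix


VCF_FIXTURE = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tA\tG\t.\t.\t.\tGT\t0/1\t./.\t0/0
1\t300\trs3\tG\tA\t.\t.\t.\tGT\t1/1\t1/1\t0/1
2\t150\trs4\tT\tC\t.\t.\t.\tGT\t0/0\t0/0\t0/1
2\t400\trs5\tC\tG\t.\t.\t.\tGT\t0/1\t1/1\t0/0
"""

GTF_FIXTURE = """\
1\ttest\texon\t100\t199\t.\t+\t.\tgene_id "GX"; transcript_id "GX.T1";
1\ttest\texon\t300\t399\t.\t+\t.\tgene_id "GX"; transcript_id "GX.T1";
1\ttest\texon\t500\t599\t.\t+\t.\tgene_id "GX"; transcript_id "GX.T1";
1\ttest\tCDS\t150\t199\t.\t+\t0\tgene_id "GX"; transcript_id "GX.T1";
1\ttest\tCDS\t300\t399\t.\t+\t0\tgene_id "GX"; transcript_id "GX.T1";
1\ttest\tCDS\t500\t549\t.\t+\t0\tgene_id "GX"; transcript_id "GX.T1";
2\ttest\texon\t1000\t1099\t.\t-\t.\tgene_id "GY"; transcript_id "GY.T1";
2\ttest\texon\t1300\t1399\t.\t-\t.\tgene_id "GY"; transcript_id "GY.T1";
"""

JUNC_FIXTURE = """\
chrom\tintron_start\tintron_end\tstrand\tS1\tS2\tS3
1\t200\t299\t+\t12\t0\t7
1\t400\t499\t+\t3\t25\t0
"""


@pytest.fixture
def vcf_text():
    return VCF_FIXTURE


@pytest.fixture
def gtf_text():
    return GTF_FIXTURE


@pytest.fixture
def junc_text():
    return JUNC_FIXTURE


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_genotypes(dosage, positions=None, chrom="1", populations=None):
    """Build a GenotypeMatrix from a (samples x variants) dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n_samples, n_variants = dosage.shape
    positions = positions or [100 * (j + 1) for j in range(n_variants)]
    variants = [
        VariantRecord(chrom, positions[j], f"v{j + 1}", "C", "T") for j in range(n_variants)
    ]
    samples = [f"s{i + 1}" for i in range(n_samples)]
    pop = populations or {}
    return GenotypeMatrix(variants, samples, dosage, pop)


def make_transcript(exons, strand="+", gene="G", tid=None, cds=None, chrom="1"):
    tx = TranscriptModel(gene, tid or f"{gene}.T", chrom, strand, list(exons))
    if cds is not None:
        tx.cds = cds
        tx.__post_init__()
    return tx
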