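import textwrap

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from archhap import SimConfig, simulate_dataset  # noqa: E402

TOY_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
    chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
    chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|0
    chr1\t300\t.\tG\tGA\t.\tPASS\t.\tGT\t0|0\t0|1\t0|0
    chr1\t400\trs3\tT\tA\t.\tPASS\t.\tGT\t1|1\t0|0\t0|1
    chr1\t500\trs4\tG\tC\t.\tPASS\t.\tGT\t0|1\t0|1\t0|0
    """)

PANEL_TSV = textwrap.dedent("""\
    sample\tpop\tsuper_pop
    S1\tCEU\tEUR
    S2\tCEU\tEUR
    S3\tYRI\tAFR
    S4\tYRI\tAFR
    S5\tLWK\tAFR
    """)


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_panel(tmp_path):
    p = tmp_path / "panel.tsv"
    p.write_text(PANEL_TSV)
    return p


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default planted-introgression dataset (seed 1), files on disk."""
    out = tmp_path_factory.mktemp("simdefault")
    return simulate_dataset(SimConfig(), out_dir=out)


def random_haplotype_columns(rng, n):
    """Two aligned polymorphic 0/1 columns of length n (no missing)."""
    while True:
        a = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(np.int8)
        b = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(np.int8)
        if 0 < a.sum() < n and 0 < b.sum() < n:
            return a, b
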