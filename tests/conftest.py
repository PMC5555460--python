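import numpy as np
import pytest

import eqtlsim as es


@pytest.fixture(scope="session")
def independent_panel():
    """Small panel of mutually independent SNPs (rho = 0)."""
    spec = es.LDBlockSpec([50], [0.0])
    return es.simulate_locus(2000, 50, block_spec=spec, seed=101)


@pytest.fixture(scope="session")
def block_panel():
    """Default block-LD cis-window panel at cohort scale."""
    return es.simulate_locus(1839, 200, seed=202)


@pytest.fixture()
def vcf_text(tmp_path):
    """Tiny hand-written VCF with GT genotypes (one variant needs flipping)."""
    text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        "s0\ts1\ts2\ts3\ts4\ts5\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\t0/1\t0/0\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t0/1\t1/1\t1/1\n"
        "1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0\t0/1\n"
    )
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
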