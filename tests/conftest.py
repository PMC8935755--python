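import numpy as np
import pytest
from hypothesis import settings

from poolhaf.io_formats import ChromosomeTable

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def chrom_table():
    return ChromosomeTable({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20220321)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPOOL
"""


def write_vcf_text(path, rows, chrom="chr1", length=1_000_000):
    """Hand-rolled VCF text fixture (deliberately independent of pysam).

    rows: (pos, ref, alt, qual, ad_string) tuples; alt may be a comma list.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(chrom=chrom, length=length))
        for pos, ref, alt, qual, ad in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tAD\t{ad}\n")
    return path
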