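import pytest

from chalm.reads import MethRead
from chalm.regions import GenomicInterval

# the two-population promoter toy: 5 CpGs, 10 reads spanning all of them
PROMOTER = GenomicInterval("chr1", 1000, 1100)
CPGS = (1010, 1030, 1050, 1070, 1090)


def mk_read(read_id, states, cpgs=CPGS, chrom="chr1", start=1000, end=1100):
    """Build a full-span read from a string of call states ('M'/'U'/'N')."""
    calls = tuple(
        (pos, {"M": "M", "U": "U", "N": "NA"}[s]) for pos, s in zip(cpgs, states)
    )
    return MethRead(read_id, chrom, start, end, "+", calls)


@pytest.fixture
def promoter():
    return PROMOTER


@pytest.fixture
def population_a():
    """20% of cells fully methylated, the rest fully unmethylated."""
    reads = [mk_read(f"m{i}", "MMMMM") for i in range(2)]
    reads += [mk_read(f"u{i}", "UUUUU") for i in range(8)]
    return reads


@pytest.fixture
def population_b():
    """Every cell carries exactly one dispersed mCpG."""
    reads = []
    for i in range(10):
        states = ["U"] * 5
        states[i % 5] = "M"
        reads.append(mk_read(f"b{i}", "".join(states)))
    return reads
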