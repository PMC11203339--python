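import numpy as np
import pytest

from ampedit import synthetic_cybb_allele_set
from ampedit.merge import Read, ReadPair
from ampedit.amplicon import revcomp


@pytest.fixture(scope="session")
def alleles_guide():
    return synthetic_cybb_allele_set()


@pytest.fixture(scope="session")
def alleles(alleles_guide):
    return alleles_guide[0]


@pytest.fixture(scope="session")
def guide(alleles_guide):
    return alleles_guide[1]


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def pair_from_template(template: str, read_length: int, rid: str = "p", q: int = 38) -> ReadPair:
    """Error-free pair read from a template's two ends."""
    r1 = template[:read_length]
    r2 = revcomp(template)[:read_length]
    return ReadPair(
        Read(f"{rid}/1", r1, np.full(len(r1), q)),
        Read(f"{rid}/2", r2, np.full(len(r2), q)),
    )
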