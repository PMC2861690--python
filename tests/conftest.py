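import numpy as np
import pytest
from hypothesis import settings

from contactzone import Genotypes, MISSING

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_genotypes(calls_by_pop: dict[str, list[list[tuple[int, int]]]],
                   loci: list[str] | None = None) -> Genotypes:
    """Build Genotypes from {pop: [per-individual list of (a1, a2) calls]}."""
    ids, site_of, rows = [], {}, []
    for pop, inds in calls_by_pop.items():
        for j, calls in enumerate(inds):
            ind = f"{pop}_i{j + 1}"
            ids.append(ind)
            site_of[ind] = pop
            rows.append(calls)
    n_loci = len(rows[0])
    return Genotypes(
        individual_ids=ids,
        site_of=site_of,
        loci=loci or [f"loc{l + 1}" for l in range(n_loci)],
        calls=np.array(rows, dtype=np.int64),
    )


@pytest.fixture
def toy_three_pop() -> Genotypes:
    """8 individuals, 3 populations, 2 loci — small enough for brute-force
    distance-matrix AMOVA and exhaustive permutation."""
    return make_genotypes({
        "p1": [
            [(1, 1), (2, 2)],
            [(1, 2), (2, 3)],
            [(1, 1), (3, 3)],
        ],
        "p2": [
            [(2, 2), (2, 2)],
            [(2, 3), (2, 3)],
            [(3, 3), (2, 2)],
        ],
        "p3": [
            [(1, 3), (4, 4)],
            [(3, 3), (4, 2)],
        ],
    })


@pytest.fixture
def fixed_difference_pops() -> Genotypes:
    """Two populations fixed for different alleles at every locus."""
    return make_genotypes({
        "A": [[(1, 1), (1, 1), (1, 1)]] * 6,
        "B": [[(2, 2), (2, 2), (2, 2)]] * 6,
    })


GENEPOP_SMALL = """\
two-locus demo
locA
locB
Pop
ind1 , 001002 003003
ind2 , 001001 003004
Pop
ind3 , 002002 004004
"""

GENEPOP_3DIGIT = """\
microsat demo
locA, locB
Pop
s1_1 , 120124 090090
s1_2 , 120120 000090
Pop
s2_1 , 124124 092090
"""


@pytest.fixture
def genepop_small() -> str:
    return GENEPOP_SMALL


@pytest.fixture
def genepop_3digit() -> str:
    return GENEPOP_3DIGIT
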