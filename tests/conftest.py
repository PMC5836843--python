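import numpy as np
import pytest

import hamfold as hf


@pytest.fixture(scope="session")
def toy():
    return hf.EnergyModel.toy()


@pytest.fixture(scope="session")
def turner():
    return hf.EnergyModel.turner2004()


@pytest.fixture(scope="session")
def both_models(toy, turner):
    return [toy, turner]


#: a 23-nt sequence whose dominant fold is a multiloop nested inside another
#: multiloop; outside contexts where a branch pair has further branches on its
#: flanks are essentially absent from short random sequences, so this shape is
#: kept as a dedicated regression fixture
NESTED_ML = "GGCG" + "GAAAC" + "GAAAC" + "CG" + "GAAAC" + "CC"


def random_instance(L, seed, gc_bias=0.6):
    """(sequence, reference) pair for oracle comparisons."""
    return hf.make_fixture(L, gc_bias=gc_bias, seed=seed)


def enum_table(seq, model, length_cap=24):
    return hf.enumerate_structures(seq, model, length_cap=length_cap)


def all_noncrossing_sets(L, min_hairpin=3):
    """Every non-crossing pair set on 1..L with any (i, j), j - i > min_hairpin.

    Independent enumerator for decoding oracles (ignores sequence content).
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def enum(i, j):
        if j - i < min_hairpin + 1:
            return (frozenset(),)
        out = list(enum(i + 1, j))
        for l in range(i + min_hairpin + 1, j + 1):
            rights = enum(l + 1, j) if l < j else (frozenset(),)
            for left in enum(i + 1, l - 1):
                base = left | {(i, l)}
                out.extend(base | r for r in rights)
        return tuple(out)

    return enum(1, L)
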