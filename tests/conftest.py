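import numpy as np
import pytest

from rangexp.genotypes import GenotypeMatrix, LocusTable, PopulationMap


def make_gm(calls, chrom=None, pos=None, sample_ids=None, ref=None, alt=None):
    """Build a GenotypeMatrix from a (samples x loci) list/array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    chrom = np.array(chrom if chrom is not None else ["chr1"] * L, dtype=object)
    pos = np.array(pos if pos is not None else np.arange(1, L + 1) * 100, dtype=np.int64)
    ref = np.array(ref if ref is not None else ["A"] * L, dtype=object)
    alt = np.array(alt if alt is not None else ["G"] * L, dtype=object)
    ids = sample_ids or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(ids, LocusTable(chrom, pos, ref, alt), calls)


@pytest.fixture
def two_pop_gm():
    """Ten diploids in two populations, eight polymorphic loci."""
    rng = np.random.default_rng(17)
    calls = rng.integers(0, 3, size=(10, 8)).astype(np.int8)
    gm = make_gm(calls)
    pm = PopulationMap({f"s{i}": ("P1" if i < 5 else "P2") for i in range(10)})
    return gm, pm
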