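import numpy as np
import pytest

from fursealpop.genotypes import GenotypeMatrix, LocusInfo, PopulationMap
from fursealpop.synth import SynthConfig, generate_study


def make_matrix(calls, individuals=None, loci=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    individuals = individuals or [f"ind{i}" for i in range(n)]
    loci = loci or [LocusInfo(f"L{j}", "1", j + 1, ("A", "G")) for j in range(L)]
    return GenotypeMatrix(individuals, loci, calls)


def two_pop_map(g, split=None):
    """First `split` individuals -> colony A, rest -> colony B."""
    split = split if split is not None else g.n_individuals // 2
    colony_of = {ind: ("A" if i < split else "B") for i, ind in enumerate(g.individuals)}
    return PopulationMap(colony_of, {"A": "west", "B": "east"},
                         {"A": (-41.0, 172.0), "B": (-46.0, 169.0)})


@pytest.fixture(scope="session")
def small_study():
    """Default eight-colony synthetic study at a modest locus count."""
    return generate_study(SynthConfig(n_loci=500, seed=11))


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(SynthConfig(n_loci=60, seed=5))
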