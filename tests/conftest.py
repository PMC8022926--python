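import numpy as np
import pytest

import breedsim as bs


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_founders():
    """50 outbred diploids, 2 chromosomes x 100 loci."""
    return bs.quick_haplo(50, 2, 100, seed=11)


@pytest.fixture
def small_sp(small_founders):
    haplo, gmap = small_founders
    sp = bs.SimParams(haplo, gmap, seed=12)
    sp.add_trait_a(40, mean=0.0, var=1.0)
    return sp


@pytest.fixture
def small_pop(small_founders, small_sp):
    haplo, _ = small_founders
    return bs.new_pop(haplo, small_sp)


def make_haplo_from_genotypes(genos, ploidy=2):
    """Single-locus HaploSet from a list of dosages (exact genotype counts)."""
    n = len(genos)
    arr = np.zeros((n, ploidy, 1), dtype=np.uint8)
    for i, g in enumerate(genos):
        arr[i, :g, 0] = 1
    return bs.HaploSet.from_alleles([arr])


def single_locus_map():
    from breedsim.founders import ChromMap, GeneticMap

    return bs.GeneticMap([ChromMap(np.array([0.5]), length=1.0)])
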