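"""Meiosis: gamma-model chiasmata, bivalent/quadrivalent resolution, crosses."""

import numpy as np
import pytest
from scipy import stats

import breedsim as bs
from breedsim.founders import ChromMap, GeneticMap
from breedsim.meiosis import (
    MeiosisParams,
    bivalent_gamete,
    quadrivalent_gamete,
    sample_chiasmata,
    tracts_to_bed,
)


def haldane(d):
    return 0.5 * (1.0 - np.exp(-2.0 * d))


class TestChiasmaProcess:
    def test_zero_length_empty(self, rng):
        assert len(sample_chiasmata(0.0, 1.0, rng)) == 0
        assert len(sample_chiasmata(0.0, 5.0, rng)) == 0

    def test_negative_length_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_chiasmata(-0.1, 1.0, rng)

    def test_rate_two_per_morgan_when_poisson(self, rng):
        counts = [len(sample_chiasmata(1.0, 1.0, rng)) for _ in range(10_000)]
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 2.0) < 3 * se

    def test_interarrivals_exponential_when_poisson(self, rng):
        # renewal-theory oracle: nu=1 interarrivals ~ Exp(rate 2).  Only the
        # first few gaps of a long window are kept: interarrivals straddling
        # the window end are censored, so "all gaps in the window" would be
        # length-biased.
        gaps = []
        while len(gaps) < 3000:
            pts = sample_chiasmata(20.0, 1.0, rng)
            if len(pts) >= 11:
                gaps.extend(np.diff(pts[:11]))
        _, p = stats.kstest(gaps, "expon", args=(0, 0.5))
        assert p > 0.01

    def test_positions_strictly_increasing(self, rng):
        for _ in range(200):
            pts = sample_chiasmata(3.0, 2.6, rng)
            assert np.all(np.diff(pts) > 0)
            assert np.all((pts >= 0) & (pts <= 3.0))

    def test_interference_tightens_interarrivals(self, rng):
        def gap_var(nu):
            gaps = []
            while len(gaps) < 4000:
                gaps.extend(np.diff(sample_chiasmata(10.0, nu, rng)))
            return np.var(gaps)

        assert gap_var(5.0) < gap_var(1.0)


class TestBivalent:
    def test_haldane_map_function(self, rng):
        # two loci 1 Morgan apart; nu=1 recovers Haldane's c
        cm = ChromMap(np.array([0.0, 1.0]), length=1.0)
        h = [np.array([0, 0], np.uint8), np.array([1, 1], np.uint8)]
        n = 10_000
        rec = 0
        for _ in range(n):
            g = bivalent_gamete(h, cm, 1.0, rng).alleles
            rec += int(g[0] != g[1])
        c = haldane(1.0)
        se = np.sqrt(c * (1 - c) / n)
        assert abs(rec / n - c) < 3 * se

    def test_homozygous_parent_transmits_itself(self, rng):
        cm = ChromMap(np.linspace(0, 1, 20), length=1.0)
        h = np.ones(20, np.uint8)
        for _ in range(50):
            g = bivalent_gamete([h, h], cm, 2.6, rng)
            assert np.array_equal(g.alleles, h)

    def test_mendelian_segregation_one_locus(self, rng):
        # selfing Aa: progeny genotypes 1:2:1
        cm = ChromMap(np.array([0.5]), length=1.0)
        h0 = np.array([0], np.uint8)
        h1 = np.array([1], np.uint8)
        n = 10_000
        genos = np.zeros(3, int)
        for _ in range(n):
            a = bivalent_gamete([h0, h1], cm, 2.6, rng).alleles[0]
            b = bivalent_gamete([h0, h1], cm, 2.6, rng).alleles[0]
            genos[a + b] += 1
        _, p = stats.chisquare(genos, n * np.array([0.25, 0.5, 0.25]))
        assert p > 0.01

    def test_tracts_reconstruct_alleles(self, rng):
        cm = ChromMap(np.linspace(0, 2, 40), length=2.0)
        h0 = np.zeros(40, np.uint8)
        h1 = np.ones(40, np.uint8)
        for _ in range(100):
            g = bivalent_gamete([h0, h1], cm, 1.0, rng)
            rebuilt = np.empty(40, np.uint8)
            covered = np.zeros(40, bool)
            for src, s, e in g.tracts:
                assert not covered[s:e].any()  # tracts tile without overlap
                covered[s:e] = True
                rebuilt[s:e] = src
            assert covered.all()
            assert np.array_equal(rebuilt, g.alleles)

    def test_crossover_count_poisson_dispersion(self, rng):
        # nu=1 on a 2-Morgan chromosome: the thinned (per-chromatid)
        # crossover count is Poisson(2)
        from breedsim.meiosis import _thin

        counts = np.array([
            len(_thin(sample_chiasmata(2.0, 1.0, rng), rng))
            for _ in range(10_000)
        ])
        n = len(counts)
        dispersion = counts.var() / counts.mean()
        # index of dispersion ~ 1 + Normal(0, sqrt(2/n)) under Poisson
        assert abs(dispersion - 1.0) < 4 * np.sqrt(2 / n)
        assert abs(counts.mean() - 2.0) < 4 * np.sqrt(2.0 / n)

    def test_length_mismatch_rejected(self, rng):
        cm = ChromMap(np.array([0.0, 1.0]), length=1.0)
        with pytest.raises(ValueError):
            bivalent_gamete([np.zeros(3, np.uint8), np.zeros(3, np.uint8)],
                            cm, 1.0, rng)


class TestQuadrivalent:
    def labeled_haps(self, n_loci):
        return [np.full(n_loci, i, np.uint8) for i in range(4)]

    def test_double_reduction_zero_at_centromere(self, rng):
        cm = ChromMap(np.array([0.5]), length=1.0)  # locus at the centromere
        haps = self.labeled_haps(1)
        for _ in range(2000):
            g = quadrivalent_gamete(haps, cm, 1.0, rng)
            assert g.alleles[0] != g.sibling.alleles[0]

    def test_double_reduction_rises_with_centromere_distance(self, rng):
        cm = ChromMap(np.array([0.5, 0.7, 1.0]), length=1.0)
        haps = self.labeled_haps(3)
        n = 20_000
        dr = np.zeros(3)
        for _ in range(n):
            g = quadrivalent_gamete(haps, cm, 1.0, rng)
            dr += g.alleles == g.sibling.alleles
        dr /= n
        se = np.sqrt(dr * (1 - dr) / n)
        assert dr[0] == 0.0
        assert dr[1] > dr[0]
        assert dr[2] > dr[1] - 3 * (se[1] + se[2])

    def test_three_parent_chromatids_on_long_map(self, rng):
        cm = ChromMap(np.linspace(0, 2, 30), length=2.0)
        haps = self.labeled_haps(30)
        hits = 0
        for _ in range(3000):
            g = quadrivalent_gamete(haps, cm, 1.0, rng)
            if len(set(g.alleles.tolist())) >= 3:
                hits += 1
        assert hits > 0

    def test_wrong_haplotype_count_rejected(self, rng):
        cm = ChromMap(np.array([0.5]), length=1.0)
        with pytest.raises(ValueError):
            quadrivalent_gamete(self.labeled_haps(1)[:3], cm, 1.0, rng)


class TestCross:
    def test_no_new_alleles(self, rng):
        haplo, gmap = bs.quick_haplo(2, 2, 30, seed=31)
        mother = [haplo.alleles(c)[0] for c in range(2)]
        father = [haplo.alleles(c)[1] for c in range(2)]
        params = MeiosisParams(nu=2.6)
        for prog in bs.make_cross(mother, father, 20, gmap, params, rng):
            for c in range(2):
                par = np.vstack([mother[c], father[c]])
                lo = par.min(axis=0)
                hi = par.max(axis=0)
                assert np.all(prog[c] >= lo) and np.all(prog[c] <= hi)

    def test_tetraploid_bivalent_limit_has_disjoint_sources(self, rng):
        # p_quad=0: the two chromatids come from two disjoint bivalent
        # pairs, so they can never share a source chromosome
        cm = ChromMap(np.linspace(0, 1, 10), length=1.0)
        gmap = GeneticMap([cm])
        haps = [np.stack([np.full(10, i, np.uint8) for i in range(4)])]
        params = MeiosisParams(nu=1.0, p_quad=0.0)
        for _ in range(300):
            g = bs.make_gamete(haps, gmap, params, rng)
            s1 = set(g[0][0].tolist())
            s2 = set(g[0][1].tolist())
            assert not (s1 & s2)

    def test_tetraploid_quadrivalent_allows_shared_sources(self, rng):
        cm = ChromMap(np.linspace(0, 2, 10), length=2.0)
        gmap = GeneticMap([cm])
        haps = [np.stack([np.full(10, i, np.uint8) for i in range(4)])]
        params = MeiosisParams(nu=1.0, p_quad=1.0)
        shared = 0
        for _ in range(2000):
            g = bs.make_gamete(haps, gmap, params, rng)
            if set(g[0][0].tolist()) & set(g[0][1].tolist()):
                shared += 1
        assert shared > 0

    def test_full_sib_genome_sharing_half(self, rng):
        # pedigree expectation: two gametes from the same parent share the
        # source haplotype at half their loci on average
        from breedsim.meiosis import _bivalent_sources

        pos = np.linspace(0, 1, 50)
        share = []
        for _ in range(1000):
            s1 = _bivalent_sources(pos, 1.0, 1.0, rng)
            s2 = _bivalent_sources(pos, 1.0, 1.0, rng)
            share.append(np.mean(s1 == s2))
        se = np.std(share) / np.sqrt(len(share))
        assert abs(np.mean(share) - 0.5) < 4 * se

    def test_ploidy_mismatch_rejected(self, rng):
        h2, g2 = bs.quick_haplo(1, 1, 10, ploidy=2, seed=32)
        h4, _ = bs.quick_haplo(1, 1, 10, ploidy=4, seed=33)
        with pytest.raises(ValueError):
            bs.make_cross([h2.alleles(0)[0]], [h4.alleles(0)[0]], 1, g2,
                          MeiosisParams(), rng)

    def test_bed_export(self, rng):
        cm = ChromMap(np.linspace(0, 1, 10), length=1.0)
        g = bivalent_gamete([np.zeros(10, np.uint8), np.ones(10, np.uint8)],
                            cm, 1.0, rng)
        bed = tracts_to_bed(g, "chr7")
        lines = bed.split("\n")
        assert len(lines) == len(g.tracts)
        assert lines[0].startswith("chr7\t0\t")
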