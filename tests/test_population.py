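"""Population operators: phenotyping, selection, mating and propagation."""

import numpy as np
import pytest

import breedsim as bs


class TestNewPop:
    def test_founder_population(self, small_founders):
        haplo, gmap = small_founders
        sp = bs.SimParams(haplo, gmap, seed=1)
        sp.add_trait_a(20)
        pop = bs.new_pop(haplo, sp)
        assert pop.n_ind == 50
        assert pop.pheno is None and pop.ebv is None
        assert np.all(pop.mother == 0) and np.all(pop.father == 0)
        assert len(np.unique(pop.family)) == 50

    def test_empty_haploset_rejected(self, small_founders, small_sp):
        haplo, _ = small_founders
        with pytest.raises(ValueError):
            bs.new_pop(haplo.subset(np.empty(0, int)), small_sp)

    def test_gv_deterministic_for_duplicates(self, small_pop):
        dup = small_pop.subset(np.array([3, 3]))
        assert dup.gv[0, 0] == dup.gv[1, 0]

    def test_out_of_range_qtl_rejected(self, small_founders, small_sp):
        haplo, _ = small_founders
        short, _ = bs.quick_haplo(5, 2, 10, seed=9)
        with pytest.raises(ValueError, match="out of range"):
            bs.Population(short, small_sp, *[np.arange(5)] * 4)


class TestSetPheno:
    def test_h2_one_reproduces_gv(self, small_pop):
        out = bs.set_pheno(small_pop, H2=1.0)
        assert np.allclose(out.pheno, small_pop.gv)

    def test_realized_heritability(self):
        haplo, gmap = bs.quick_haplo(10_000, 2, 150, seed=61)
        sp = bs.SimParams(haplo, gmap, seed=62)
        sp.add_trait_a(150)
        pop = bs.new_pop(haplo, sp)
        ratios = [
            np.var(pop.gv[:, 0]) / np.var(bs.set_pheno(pop, H2=0.4).pheno[:, 0])
            for _ in range(10)
        ]
        assert abs(np.mean(ratios) - 0.4) < 0.02

    def test_reps_scale_error_variance(self, small_sp, small_pop):
        small_sp.set_var_e(var_e=4.0)
        err1, err16 = [], []
        for _ in range(30):
            err1.append(np.var(bs.set_pheno(small_pop).pheno - small_pop.gv))
            err16.append(
                np.var(bs.set_pheno(small_pop, reps=16).pheno - small_pop.gv))
        ratio = np.mean(err16) / np.mean(err1)
        assert abs(ratio - 1 / 16) < 0.02

    def test_gxe_trait_adds_covariate_term(self):
        haplo, gmap = bs.quick_haplo(300, 1, 40, seed=63)
        sp = bs.SimParams(haplo, gmap, seed=64)
        sp.add_trait(bs.TraitSamplingSpec(n_qtl_per_chr=20, trait_type="AG",
                                          var_w=1.0))
        pop = bs.new_pop(haplo, sp)
        # with H2=1 there is no residual error, but the GxE term still
        # varies between phenotyping events
        p1 = bs.set_pheno(pop, H2=1.0).pheno[:, 0]
        p2 = bs.set_pheno(pop, H2=1.0).pheno[:, 0]
        assert not np.allclose(p1, p2)

    def test_invalid_h2_rejected(self, small_pop):
        with pytest.raises(ValueError):
            bs.set_pheno(small_pop, H2=0.0)
        with pytest.raises(ValueError):
            bs.set_pheno(small_pop, var_e=-1.0)

    def test_missing_var_e_raises(self, small_pop):
        with pytest.raises(ValueError, match="error variance"):
            bs.set_pheno(small_pop)


class TestSelection:
    def phenotyped(self, pop, values):
        out = pop.subset(np.arange(pop.n_ind))
        out.pheno = np.asarray(values, float)[:, None]
        return out

    def test_top_two_of_five(self, small_pop):
        pop = self.phenotyped(small_pop.subset(np.arange(5)),
                              [3, 1, 4, 1, 5])
        sel = bs.select_ind(pop, 2, use="pheno")
        assert sorted(sel.pheno[:, 0]) == [4, 5]

    def test_whole_population_in_original_order(self, small_pop):
        pop = self.phenotyped(small_pop, np.arange(50)[::-1])
        sel = bs.select_ind(pop, 50)
        assert np.array_equal(sel.ids, pop.ids)

    def test_single_best(self, small_pop):
        pop = self.phenotyped(small_pop, np.arange(50.0))
        sel = bs.select_ind(pop, 1)
        assert sel.pheno[0, 0] == 49.0

    def test_bottom_selection(self, small_pop):
        pop = self.phenotyped(small_pop, np.arange(50.0))
        sel = bs.select_ind(pop, 3, top=False)
        assert np.allclose(sorted(sel.pheno[:, 0]), [0, 1, 2])

    def test_stable_tie_break(self, small_pop):
        pop = self.phenotyped(small_pop.subset(np.arange(4)), [1, 1, 1, 1])
        sel = bs.select_ind(pop, 2)
        assert np.array_equal(sel.ids, pop.ids[:2])

    def test_validation(self, small_pop):
        with pytest.raises(ValueError):
            bs.select_ind(small_pop, 100, use="gv")
        with pytest.raises(ValueError, match="not set"):
            bs.select_ind(small_pop, 5, use="pheno")
        with pytest.raises(ValueError, match="not set"):
            bs.select_ind(small_pop, 5, use="ebv")

    def test_within_family(self, small_sp):
        haplo, gmap = bs.quick_haplo(40, 1, 30, seed=70)
        sp = bs.SimParams(haplo, gmap, seed=71)
        sp.add_trait_a(10)
        sp.set_var_e(H2=0.5)
        pop = bs.new_pop(haplo, sp)
        f1 = bs.rand_cross(pop, 8, 10)  # 8 families x 10
        f1 = bs.set_pheno(f1)
        sel = bs.select_within_fam(f1, 3, use="pheno")
        assert sel.n_ind == 24
        for fam in np.unique(sel.family):
            members = sel.pheno[sel.family == fam, 0]
            others = f1.pheno[f1.family == fam, 0]
            assert members.min() >= np.sort(others)[-3]

    def test_one_family_equals_select_ind(self, small_pop):
        pop = self.phenotyped(small_pop, np.arange(50.0))
        pop.family = np.ones(50, dtype=np.int64)
        a = bs.select_within_fam(pop, 7, use="pheno")
        b = bs.select_ind(pop, 7, use="pheno")
        assert np.array_equal(a.ids, b.ids)

    def test_short_families_kept_whole(self, small_pop):
        pop = self.phenotyped(small_pop.subset(np.arange(5)),
                              [5, 4, 3, 2, 1])
        pop.family = np.array([1, 1, 1, 2, 2], dtype=np.int64)
        sel = bs.select_within_fam(pop, 3, use="pheno")
        assert sel.n_ind == 5

    def test_index_selection_with_weights(self, small_founders):
        haplo, gmap = small_founders
        sp = bs.SimParams(haplo, gmap, seed=81)
        sp.add_trait_a(10)
        sp.add_trait_a(10)
        pop = bs.new_pop(haplo, sp)
        sel = bs.select_ind(pop, 5, use="gv", weights=[1.0, -1.0])
        idx = np.argsort(-(pop.gv[:, 0] - pop.gv[:, 1]), kind="stable")[:5]
        assert set(sel.ids) == set(pop.ids[np.sort(idx)])

    def test_user_hook(self, small_pop):
        same = bs.user_selection_hook(small_pop, lambda p: list(p.ids))
        assert np.array_equal(same.ids, small_pop.ids)
        rev = bs.user_selection_hook(small_pop, lambda p: list(p.ids[::-1]))
        assert np.array_equal(rev.ids, small_pop.ids[::-1])
        with pytest.raises(ValueError, match="unknown"):
            bs.user_selection_hook(small_pop, lambda p: [999_999])

    def test_seeded_random_hook_reproducible(self, small_pop):
        def hook(p):
            r = np.random.default_rng(5)
            return list(r.choice(p.ids, size=10, replace=False))

        a = bs.user_selection_hook(small_pop, hook)
        b = bs.user_selection_hook(small_pop, hook)
        assert np.array_equal(a.ids, b.ids)

    def test_selection_response_positive(self):
        # truncation selection on phenotype with h2 > 0 raises mean gv
        wins = 0
        for seed in range(20):
            haplo, gmap = bs.quick_haplo(200, 1, 40, seed=900 + seed)
            sp = bs.SimParams(haplo, gmap, seed=seed)
            sp.add_trait_a(20)
            pop = bs.set_pheno(bs.new_pop(haplo, sp), H2=0.5)
            sel = bs.select_ind(pop, 20, use="pheno")
            wins += sel.gv[:, 0].mean() > pop.gv[:, 0].mean()
        assert wins >= 19


class TestMating:
    def test_rand_cross_counts_and_pedigree(self, small_pop):
        f1 = bs.rand_cross(small_pop, 200, 1)
        assert f1.n_ind == 200
        assert len(np.unique(f1.family)) == 200
        assert np.all(f1.mother != f1.father)  # no selfing
        parent_ids = set(small_pop.ids)
        assert set(f1.mother) <= parent_ids and set(f1.father) <= parent_ids

    def test_family_sizes(self, small_pop):
        f1 = bs.rand_cross(small_pop, 10, 3)
        assert f1.n_ind == 30
        _, counts = np.unique(f1.family, return_counts=True)
        assert np.all(counts == 3)

    def test_cross_of_one_rejected(self, small_pop):
        with pytest.raises(ValueError):
            bs.rand_cross(small_pop.subset(np.array([0])), 5)

    def test_make_dh_homozygous(self, small_pop):
        f1 = bs.rand_cross(small_pop, 5, 1)
        dh = bs.make_dh(f1, 4)
        assert dh.n_ind == 20
        assert np.all(dh.haplo.heterozygosity() == 0.0)
        assert np.array_equal(np.unique(dh.family), np.unique(f1.family))

    def test_dh_of_inbred_is_clone(self):
        haplo, gmap = bs.quick_haplo(3, 1, 25, inbred=True, seed=85)
        sp = bs.SimParams(haplo, gmap, seed=86)
        sp.add_trait_a(10)
        pop = bs.new_pop(haplo, sp)
        dh = bs.make_dh(pop, 1)
        assert np.array_equal(dh.haplo.alleles(0), pop.haplo.alleles(0))

    def test_dh_allele_frequency_half_at_het_loci(self):
        haplo, gmap = bs.quick_haplo(1, 1, 30, seed=87)
        sp = bs.SimParams(haplo, gmap, seed=88, nu=1.0)
        pop = bs.new_pop(haplo, sp)
        a = pop.haplo.alleles(0)
        het = a[0, 0, :] != a[0, 1, :]
        dh = bs.make_dh(pop, 2000)
        freq = dh.haplo.allele_freq(0)
        se = np.sqrt(0.25 / 2000)
        assert np.all(np.abs(freq[het] - 0.5) < 5 * se)

    def test_dh_tetraploid_rejected(self):
        haplo, gmap = bs.quick_haplo(4, 1, 20, ploidy=4, seed=89)
        sp = bs.SimParams(haplo, gmap, seed=90)
        sp.add_trait_a(5)
        pop = bs.new_pop(haplo, sp)
        with pytest.raises(ValueError, match="diploid"):
            bs.make_dh(pop, 2)

    def test_clone_preserves_gv(self, small_pop):
        clones = bs.clone_pop(small_pop, 2)
        assert clones.n_ind == 100
        assert np.allclose(clones.gv, np.repeat(small_pop.gv, 2, axis=0))
        assert np.array_equal(clones.mother, np.repeat(small_pop.ids, 2))

    def test_repeated_selfing_halves_heterozygosity(self):
        # 2000 Aa lineages selfed 6 times: het ~ (1/2)^6
        arr = np.zeros((2000, 2, 2), np.uint8)
        arr[:, 0, :] = 1
        haplo = bs.HaploSet.from_alleles([arr])
        from breedsim.founders import ChromMap

        gmap = bs.GeneticMap([ChromMap(np.array([0.2, 0.8]), length=1.0)])
        sp = bs.SimParams(haplo, gmap, seed=91, nu=1.0)
        pop = bs.new_pop(haplo, sp)
        for _ in range(6):
            pop = bs.self_pop(pop, 1)
        het = np.mean(pop.haplo.alleles(0)[:, 0, 0]
                      != pop.haplo.alleles(0)[:, 1, 0])
        expect = 0.5 ** 6
        se = np.sqrt(expect * (1 - expect) / 2000)
        assert abs(het - expect) < 4 * se

    def test_open_pollination_limits(self, small_pop):
        selfed = bs.open_pollinate(small_pop, 2, self_rate=1.0)
        assert np.all(selfed.mother == selfed.father)
        crossed = bs.open_pollinate(small_pop, 2, self_rate=0.0)
        assert np.all(crossed.mother != crossed.father)
        with pytest.raises(ValueError):
            bs.open_pollinate(small_pop, 1, self_rate=1.5)

    def test_cross_plan(self, small_pop):
        m, f = small_pop.ids[0], small_pop.ids[1]
        prog = bs.make_cross_plan(small_pop, [(m, f, 5)])
        assert prog.n_ind == 5
        assert np.all(prog.mother == m) and np.all(prog.father == f)
        dup = bs.make_cross_plan(small_pop, [(m, f, 2), (m, f, 3)])
        assert dup.n_ind == 5
        assert len(np.unique(dup.family)) == 2
        empty = bs.make_cross_plan(small_pop, [])
        assert empty.n_ind == 0
        with pytest.raises(ValueError, match="unknown"):
            bs.make_cross_plan(small_pop, [(999_999, f, 1)])

    def test_progeny_alleles_from_parents(self, small_pop):
        f1 = bs.rand_cross(small_pop, 20, 2)
        lut = {int(i): k for k, i in enumerate(small_pop.ids)}
        for c in range(small_pop.haplo.n_chr):
            par = small_pop.haplo.alleles(c)
            kid = f1.haplo.alleles(c)
            for k in range(f1.n_ind):
                mi, fi = lut[int(f1.mother[k])], lut[int(f1.father[k])]
                assert np.all(np.isin(kid[k, 0], par[mi, :, :].T))
                lo = par[[mi, fi]].min(axis=(0, 1))
                hi = par[[mi, fi]].max(axis=(0, 1))
                assert np.all(kid[k].min(axis=0) >= lo)
                assert np.all(kid[k].max(axis=0) <= hi)

    def test_pedigree_closure(self, small_pop):
        f1 = bs.rand_cross(small_pop, 10, 2)
        dh = bs.make_dh(f1, 3)
        known = set(small_pop.ids) | set(f1.ids)
        assert set(dh.mother) <= set(f1.ids)
        assert (set(f1.mother) | set(f1.father)) <= set(small_pop.ids)
        assert set(dh.ids).isdisjoint(known)

    def test_reproducible_given_seed(self, small_founders):
        haplo, gmap = small_founders

        def run(seed):
            sp = bs.SimParams(haplo, gmap, seed=seed)
            sp.add_trait_a(10)
            pop = bs.new_pop(haplo, sp)
            f1 = bs.rand_cross(pop, 10, 2)
            return bs.set_pheno(f1, H2=0.5).pheno

        assert np.array_equal(run(5), run(5))
        assert not np.array_equal(run(5), run(6))


class TestExport:
    def test_pop_table_and_pedigree(self, small_pop, tmp_path):
        out = bs.set_pheno(small_pop, H2=0.5)
        df = bs.pop_to_df(out)
        assert list(df.columns)[:4] == ["id", "mother", "father", "family"]
        assert "gv1" in df and "pheno1" in df
        ped = tmp_path / "ped.txt"
        bs.write_pedigree([small_pop], str(ped))
        assert len(ped.read_text().splitlines()) == 51
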