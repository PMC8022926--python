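"""Population container and breeding-program operators.

A :class:`Population` couples a pedigree (ids, parents, family lineages)
with phased haplotypes, true genetic values per trait, and -- once set --
phenotypes and estimated breeding values.  The module-level functions are
the verbs of a breeding program: phenotyping (:func:`set_pheno`), selection
(:func:`select_ind`, :func:`select_within_fam`, :func:`user_selection_hook`)
and mating/propagation (:func:`rand_cross`, :func:`make_dh`,
:func:`self_pop`, :func:`clone_pop`, :func:`open_pollinate`,
:func:`make_cross_plan`).  Global simulation state -- ploidy, recombination
model, traits with their founder variance snapshots, stored error variances,
id/family counters and the RNG -- lives in :class:`SimParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import varcomp as _varcomp
from .founders import GeneticMap, HaploSet
from .meiosis import MeiosisParams, _bivalent_sources, _quadrivalent_sources
from .traits import Trait, TraitSamplingSpec, genetic_value, gxe_deviation, \
    sample_trait

log = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "PhenoSpec",
    "Population",
    "new_pop",
    "set_pheno",
    "select_ind",
    "select_within_fam",
    "user_selection_hook",
    "rand_cross",
    "make_dh",
    "self_pop",
    "clone_pop",
    "open_pollinate",
    "make_cross_plan",
    "pop_to_df",
    "write_pedigree",
]


# ---------------------------------------------------------------------------
# global simulation state
# ---------------------------------------------------------------------------

class SimParams:
    """Global simulation parameters and state.

    Holds the founder haplotypes and genetic map, the meiosis model
    (interference ``nu``, quadrivalent probability ``p_quad``), the trait
    architectures with their founder variance-component snapshots, stored
    error variances, and the id/family counters plus the seeded RNG that
    make every operator reproducible.
    """

    def __init__(self, founder_haplo: HaploSet, gmap: GeneticMap,
                 seed: Optional[int | np.random.Generator] = None,
                 nu: float = 2.6, p_quad: float = 0.0,
                 use_sex_maps: bool = False):
        if founder_haplo.n_loci != gmap.n_loci:
            raise ValueError("haplotypes and map disagree on locus counts")
        self.founder_haplo = founder_haplo
        self.gmap = gmap
        self.ploidy = founder_haplo.ploidy
        self.meiosis = MeiosisParams(nu=nu, p_quad=p_quad,
                                     use_sex_maps=use_sex_maps)
        self.rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        self.traits: list[Trait] = []
        self.var_e: list[Optional[float]] = []
        self.founder_varcomps: list[_varcomp.VarComps] = []
        self._next_id = 1
        self._next_family = 1
        self.n_created = 0

    # -- traits ------------------------------------------------------------

    def add_trait(self, spec: TraitSamplingSpec) -> Trait:
        trait = sample_trait(spec, self.founder_haplo, self.rng,
                             ploidy=self.ploidy)
        self.traits.append(trait)
        self.var_e.append(None)
        self.founder_varcomps.append(
            _varcomp.decompose(self.founder_haplo, trait))
        return trait

    def add_trait_a(self, n_qtl_per_chr: int, mean: float = 0.0,
                    var: float = 1.0) -> Trait:
        """Convenience: one purely additive trait scaled to (mean, var)."""
        return self.add_trait(TraitSamplingSpec(
            n_qtl_per_chr=n_qtl_per_chr, trait_type="A", mean=mean, var=var))

    def refresh_snapshot(self, trait_index: int = 0) -> None:
        """Recompute the founder variance snapshot (after rescaling a trait)."""
        self.founder_varcomps[trait_index] = _varcomp.decompose(
            self.founder_haplo, self.traits[trait_index])

    def set_var_e(self, H2: Optional[float] = None,
                  var_e: Optional[float] = None,
                  trait: Optional[int] = None) -> None:
        """Store error variances, either directly or derived from a target
        broad-sense heritability in the founder population:
        ``var_e = V_G_founder * (1 - H2) / H2``."""
        idx = range(len(self.traits)) if trait is None else [trait]
        for t in idx:
            self.var_e[t] = self._var_e_from(H2, var_e, t)

    def _var_e_from(self, H2: Optional[float], var_e: Optional[float],
                    t: int) -> float:
        if (H2 is None) == (var_e is None):
            raise ValueError("give exactly one of H2 or var_e")
        if var_e is not None:
            if var_e < 0:
                raise ValueError("var_e must be non-negative")
            return float(var_e)
        if not 0.0 < H2 <= 1.0:
            raise ValueError("H2 must lie in (0, 1]")
        v_g = self.founder_varcomps[t].V_G
        return float(v_g * (1.0 - H2) / H2)

    # -- counters ----------------------------------------------------------

    def _new_ids(self, n: int) -> np.ndarray:
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.n_created += n
        return ids

    def _new_families(self, n: int) -> np.ndarray:
        fam = np.arange(self._next_family, self._next_family + n,
                        dtype=np.int64)
        self._next_family += n
        return fam


@dataclass
class PhenoSpec:
    """Phenotyping specification: a target broad-sense heritability in the
    founders OR an error variance, plus the number of replicate evaluations
    (locations).  Replicates average the error, giving variance var_e/reps."""

    H2: Optional[float] = None
    var_e: Optional[float] = None
    reps: int = 1

    def __post_init__(self) -> None:
        if self.H2 is not None and not 0.0 < self.H2 <= 1.0:
            raise ValueError("H2 must lie in (0, 1]")
        if self.var_e is not None and self.var_e < 0:
            raise ValueError("var_e must be non-negative")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------

class Population:
    """A cohort of individuals with pedigree, haplotypes and trait values."""

    def __init__(self, haplo: HaploSet, sp: SimParams, ids: np.ndarray,
                 mother: np.ndarray, father: np.ndarray, family: np.ndarray,
                 sex: Optional[np.ndarray] = None,
                 gv: Optional[np.ndarray] = None):
        self.haplo = haplo
        self.sp = sp
        self.ids = np.asarray(ids, dtype=np.int64)
        self.mother = np.asarray(mother, dtype=np.int64)
        self.father = np.asarray(father, dtype=np.int64)
        self.family = np.asarray(family, dtype=np.int64)
        self.sex = sex
        n = haplo.n_ind
        if not (len(self.ids) == len(self.mother) == len(self.father)
                == len(self.family) == n):
            raise ValueError("pedigree arrays must match the cohort size")
        self.gv = self._compute_gv() if gv is None else gv
        self.pheno: Optional[np.ndarray] = None
        self.ebv: Optional[np.ndarray] = None

    def _compute_gv(self) -> np.ndarray:
        n_t = len(self.sp.traits)
        gv = np.empty((self.haplo.n_ind, n_t))
        for t, trait in enumerate(self.sp.traits):
            if np.any(trait.qtl_idx >= np.asarray(self.haplo.n_loci)[trait.qtl_chr]):
                raise ValueError("trait QTL addresses are out of range for "
                                 "this haplotype set")
            gv[:, t] = genetic_value(
                trait, self.haplo, w=0.0 if trait.g is not None else None)
        return gv

    @property
    def n_ind(self) -> int:
        return self.haplo.n_ind

    def __len__(self) -> int:
        return self.n_ind

    def subset(self, idx: np.ndarray) -> "Population":
        idx = np.asarray(idx)
        pop = Population(
            self.haplo.subset(idx), self.sp, self.ids[idx], self.mother[idx],
            self.father[idx], self.family[idx],
            sex=None if self.sex is None else self.sex[idx],
            gv=self.gv[idx],
        )
        if self.pheno is not None:
            pop.pheno = self.pheno[idx]
        if self.ebv is not None:
            pop.ebv = self.ebv[idx]
        return pop

    def index_of_ids(self, ids: Sequence[int]) -> np.ndarray:
        lut = {int(i): k for k, i in enumerate(self.ids)}
        missing = [int(i) for i in ids if int(i) not in lut]
        if missing:
            raise ValueError(f"unknown individual ids: {missing[:20]}")
        return np.array([lut[int(i)] for i in ids], dtype=np.int64)


def new_pop(haplo: HaploSet, sp: SimParams) -> Population:
    """Wrap founder haplotypes into a population; genetic values are
    computed for all traits, phenotypes and EBVs are unset.  Each founder
    starts its own family lineage."""
    if haplo.n_ind == 0:
        raise ValueError("cannot build a population from an empty "
                         "haplotype set")
    n = haplo.n_ind
    ids = sp._new_ids(n)
    zeros = np.zeros(n, dtype=np.int64)  # founder sentinel parent id 0
    return Population(haplo, sp, ids, zeros, zeros, sp._new_families(n))


# ---------------------------------------------------------------------------
# phenotyping
# ---------------------------------------------------------------------------

def set_pheno(pop: Population, spec: Optional[PhenoSpec] = None, *,
              H2: Optional[float] = None, var_e: Optional[float] = None,
              reps: Optional[int] = None,
              rng: Optional[np.random.Generator] = None) -> Population:
    """Phenotype a population: ``pheno = gv + GxE + e``.

    The error variance is, per trait: ``var_e`` if given here; else derived
    from ``H2`` against the *founder* total genetic variance; else the value
    stored in SimParams (``set_var_e``).  ``e`` is N(0, var_e/reps),
    independent per individual and per phenotyping event -- ``reps``
    replicate locations average the error.  G-type traits add
    ``w * sum g_i (x_i - ploidy/2)`` with one fresh environmental covariate
    ``w ~ N(0, var_w)`` per phenotyping event, shared across reps.
    """
    sp = pop.sp
    if spec is not None:
        H2 = spec.H2 if H2 is None else H2
        var_e = spec.var_e if var_e is None else var_e
        reps = spec.reps if reps is None else reps
    reps = 1 if reps is None else int(reps)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if H2 is not None and not 0.0 < H2 <= 1.0:
        raise ValueError("H2 must lie in (0, 1]")
    if var_e is not None and var_e < 0:
        raise ValueError("var_e must be non-negative")
    rng = sp.rng if rng is None else rng
    out = pop.subset(np.arange(pop.n_ind))
    n = pop.n_ind
    pheno = np.empty_like(pop.gv)
    for t, trait in enumerate(sp.traits):
        if H2 is not None or var_e is not None:
            ve = sp._var_e_from(H2, var_e, t)
        else:
            if sp.var_e[t] is None:
                raise ValueError(
                    "no error variance available: pass H2/var_e or store one "
                    "with SimParams.set_var_e"
                )
            ve = sp.var_e[t]
        col = pop.gv[:, t].copy()
        if trait.g is not None:
            w = rng.normal(0.0, np.sqrt(trait.var_w))
            col += w * gxe_deviation(trait, pop)
        col += rng.normal(0.0, np.sqrt(ve / reps), size=n)
        pheno[:, t] = col
    out.pheno = pheno
    return out


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _criterion(pop: Population, use: str, trait: int,
               weights: Optional[np.ndarray]) -> np.ndarray:
    mats = {"pheno": pop.pheno, "gv": pop.gv, "ebv": pop.ebv}
    if use not in mats:
        raise ValueError(f"unknown selection criterion {use!r}")
    M = mats[use]
    if M is None:
        raise ValueError(f"criterion {use!r} is not set for this population")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != M.shape[1]:
            raise ValueError("index weights must have one entry per trait")
        return M @ weights
    return M[:, trait]


def select_ind(pop: Population, n: int, use: str = "pheno", top: bool = True,
               trait: int = 0,
               weights: Optional[np.ndarray] = None) -> Population:
    """The ``n`` individuals with the largest (``top``) or smallest
    criterion; ties break by original population order; output keeps the
    original order.  ``weights`` turns the criterion into a multi-trait
    index."""
    if not 1 <= n <= pop.n_ind:
        raise ValueError(f"n must be in [1, {pop.n_ind}]")
    crit = _criterion(pop, use, trait, weights)
    order = np.argsort(-crit if top else crit, kind="stable")
    chosen = np.sort(order[:n])
    return pop.subset(chosen)


def select_within_fam(pop: Population, n_per_fam: int, use: str = "pheno",
                      top: bool = True, trait: int = 0,
                      weights: Optional[np.ndarray] = None) -> Population:
    """Top ``n_per_fam`` individuals per family; families smaller than
    ``n_per_fam`` are returned whole (logged)."""
    if n_per_fam < 1:
        raise ValueError("n_per_fam must be >= 1")
    crit = _criterion(pop, use, trait, weights)
    keep = []
    for fam in np.unique(pop.family):
        members = np.flatnonzero(pop.family == fam)
        if len(members) < n_per_fam:
            log.info("family %d has only %d members (< %d): kept whole",
                     fam, len(members), n_per_fam)
            keep.append(members)
            continue
        sub = crit[members]
        order = np.argsort(-sub if top else sub, kind="stable")
        keep.append(np.sort(members[order[:n_per_fam]]))
    return pop.subset(np.sort(np.concatenate(keep)))


def user_selection_hook(pop: Population,
                        criterion: Callable[[Population], Sequence[int]]
                        ) -> Population:
    """Select with a user-supplied callable mapping the population to a list
    of chosen individual ids (order preserved)."""
    ids = list(criterion(pop))
    return pop.subset(pop.index_of_ids(ids))


# ---------------------------------------------------------------------------
# gene-drop engine
# ---------------------------------------------------------------------------

def _tetra_gamete_rows(par: np.ndarray, cm, params: MeiosisParams,
                       rng: np.random.Generator, positions: np.ndarray,
                       length: float) -> np.ndarray:
    """Two gamete chromatids (2, L) from one tetraploid meiosis."""
    if rng.random() < params.p_quad:
        perm = rng.permutation(4)
        src_a, src_b = _quadrivalent_sources(
            positions, length, cm.centromere, params.nu, rng)
        idx = np.arange(par.shape[1])
        return np.stack([par[perm[src_a], idx], par[perm[src_b], idx]])
    perm = rng.permutation(4)
    s1 = _bivalent_sources(positions, length, params.nu, rng)
    s2 = _bivalent_sources(positions, length, params.nu, rng)
    g1 = np.where(s1 == 0, par[perm[0]], par[perm[1]])
    g2 = np.where(s2 == 0, par[perm[2]], par[perm[3]])
    return np.stack([g1, g2])


def _gene_drop(pop: Population, mothers: np.ndarray, fathers: np.ndarray,
               rng: np.random.Generator, doubled: bool = False) -> HaploSet:
    """Drop genes through meiosis for a batch of (mother, father) pairs.

    ``doubled=True`` produces doubled haploids: a single maternal gamete per
    offspring, duplicated into a fully homozygous diploid.
    """
    sp = pop.sp
    params = sp.meiosis
    ploidy = pop.haplo.ploidy
    n_prog = len(mothers)
    chrom_out = []
    for c, cm in enumerate(sp.gmap):
        par = pop.haplo.alleles(c)
        L = cm.n_loci
        if params.use_sex_maps:
            pos_f = cm.positions_for("female")
            pos_m = cm.positions_for("male")
            len_f = cm.length
            len_m = float(pos_m[-1]) if cm.male_positions is not None \
                else cm.length
        else:
            pos_f = pos_m = cm.positions
            len_f = len_m = cm.length
        buf = np.empty((n_prog, ploidy, L), dtype=np.uint8)
        if doubled:
            for k in range(n_prog):
                mh = par[mothers[k]]
                src = _bivalent_sources(pos_f, len_f, params.nu, rng)
                g = np.where(src == 0, mh[0], mh[1])
                buf[k, 0] = g
                buf[k, 1] = g
        elif ploidy == 2:
            for k in range(n_prog):
                mh = par[mothers[k]]
                src = _bivalent_sources(pos_f, len_f, params.nu, rng)
                buf[k, 0] = np.where(src == 0, mh[0], mh[1])
                fh = par[fathers[k]]
                src = _bivalent_sources(pos_m, len_m, params.nu, rng)
                buf[k, 1] = np.where(src == 0, fh[0], fh[1])
        else:
            for k in range(n_prog):
                buf[k, :2] = _tetra_gamete_rows(par[mothers[k]], cm, params,
                                                rng, pos_f, len_f)
                buf[k, 2:] = _tetra_gamete_rows(par[fathers[k]], cm, params,
                                                rng, pos_m, len_m)
        chrom_out.append(buf)
    return HaploSet.from_alleles(chrom_out)


def _progeny_pop(pop: Population, mothers: np.ndarray, fathers: np.ndarray,
                 family: np.ndarray, rng: np.random.Generator,
                 doubled: bool = False) -> Population:
    haplo = _gene_drop(pop, mothers, fathers, rng, doubled=doubled)
    sp = pop.sp
    ids = sp._new_ids(len(mothers))
    return Population(haplo, sp, ids, pop.ids[mothers], pop.ids[fathers],
                      family)


# ---------------------------------------------------------------------------
# mating and propagation
# ---------------------------------------------------------------------------

def rand_cross(pop: Population, n_crosses: int, n_progeny_per_cross: int = 1,
               rng: Optional[np.random.Generator] = None) -> Population:
    """``n_crosses`` random biparental crosses (no selfing; pairs drawn
    without replacement within a pair, parents may repeat across crosses),
    each producing ``n_progeny_per_cross`` offspring.  Each cross founds a
    new family.  With sexes recorded, mothers are drawn from females and
    fathers from males."""
    if pop.n_ind < 2:
        raise ValueError("need at least two individuals to cross")
    rng = pop.sp.rng if rng is None else rng
    if pop.sex is not None:
        females = np.flatnonzero(pop.sex == "F")
        males = np.flatnonzero(pop.sex == "M")
        if len(females) == 0 or len(males) == 0:
            raise ValueError("both sexes must be present to cross")
        mothers = females[rng.integers(len(females), size=n_crosses)]
        fathers = males[rng.integers(len(males), size=n_crosses)]
    else:
        # uniform pair without replacement within a pair, vectorized:
        # father drawn uniformly among the n-1 indices distinct from mother
        mothers = rng.integers(pop.n_ind, size=n_crosses)
        fathers = rng.integers(pop.n_ind - 1, size=n_crosses)
        fathers = np.where(fathers >= mothers, fathers + 1, fathers)
    fam = pop.sp._new_families(n_crosses)
    mothers = np.repeat(mothers, n_progeny_per_cross)
    fathers = np.repeat(fathers, n_progeny_per_cross)
    family = np.repeat(fam, n_progeny_per_cross)
    return _progeny_pop(pop, mothers, fathers, family, rng)


def make_dh(pop: Population, n_dh: int,
            rng: Optional[np.random.Generator] = None) -> Population:
    """``n_dh`` doubled-haploid lines per individual: each line is one
    meiotic gamete doubled into a fully homozygous individual.  Family is
    inherited.  Defined for diploids only."""
    if pop.haplo.ploidy != 2:
        raise ValueError("doubled haploids are defined here for diploids only")
    if n_dh < 1:
        raise ValueError("n_dh must be >= 1")
    rng = pop.sp.rng if rng is None else rng
    parents = np.repeat(np.arange(pop.n_ind), n_dh)
    family = np.repeat(pop.family, n_dh)
    return _progeny_pop(pop, parents, parents, family, rng, doubled=True)


def self_pop(pop: Population, n_progeny: int,
             rng: Optional[np.random.Generator] = None) -> Population:
    """Self-fertilize every individual ``n_progeny`` times (family
    inherited)."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    rng = pop.sp.rng if rng is None else rng
    parents = np.repeat(np.arange(pop.n_ind), n_progeny)
    family = np.repeat(pop.family, n_progeny)
    return _progeny_pop(pop, parents, parents, family, rng)


def clone_pop(pop: Population, n: int = 1) -> Population:
    """Clonal propagation: verbatim haplotype copies, ``n`` per individual,
    with fresh ids and the parent recorded as both mother and father."""
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = np.repeat(np.arange(pop.n_ind), n)
    sp = pop.sp
    out = Population(
        pop.haplo.subset(idx), sp, sp._new_ids(len(idx)), pop.ids[idx],
        pop.ids[idx], pop.family[idx],
        sex=None if pop.sex is None else pop.sex[idx], gv=pop.gv[idx],
    )
    return out


def open_pollinate(pop: Population, n_progeny: int, self_rate: float = 0.0,
                   rng: Optional[np.random.Generator] = None) -> Population:
    """Open pollination: every individual mothers ``n_progeny`` offspring;
    each offspring is selfed with probability ``self_rate``, otherwise sired
    by a random distinct pollen parent."""
    if not 0.0 <= self_rate <= 1.0:
        raise ValueError("self_rate must lie in [0, 1]")
    if pop.n_ind < 2 and self_rate < 1.0:
        raise ValueError("outcrossing needs at least two individuals")
    rng = pop.sp.rng if rng is None else rng
    mothers = np.repeat(np.arange(pop.n_ind), n_progeny)
    fathers = np.empty_like(mothers)
    for k, m in enumerate(mothers):
        if rng.random() < self_rate:
            fathers[k] = m
        else:
            f = int(rng.integers(pop.n_ind - 1))
            fathers[k] = f if f < m else f + 1
    family = np.repeat(pop.family, n_progeny)
    return _progeny_pop(pop, mothers, fathers, family, rng)


def make_cross_plan(pop: Population,
                    plan: Sequence[tuple[int, int, int]],
                    rng: Optional[np.random.Generator] = None) -> Population:
    """Execute a user-supplied mating plan: rows of (mother id, father id,
    n progeny).  Each plan row founds a family; duplicated rows concatenate."""
    rng = pop.sp.rng if rng is None else rng
    mothers_l, fathers_l, fam_l = [], [], []
    for mid, fid, n in plan:
        if n < 0:
            raise ValueError("progeny count must be non-negative")
        m = pop.index_of_ids([mid])[0]
        f = pop.index_of_ids([fid])[0]
        fam = pop.sp._new_families(1)[0]
        mothers_l.extend([m] * n)
        fathers_l.extend([f] * n)
        fam_l.extend([fam] * n)
    if not mothers_l:
        empty = pop.haplo.subset(np.empty(0, dtype=np.int64))
        z = np.empty(0, dtype=np.int64)
        return Population(empty, pop.sp, z, z, z, z,
                          gv=np.empty((0, len(pop.sp.traits))))
    return _progeny_pop(pop, np.asarray(mothers_l), np.asarray(fathers_l),
                        np.asarray(fam_l), rng)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def pop_to_df(pop: Population) -> pd.DataFrame:
    """Tabular view: id, pedigree, family and per-trait value columns."""
    out = pd.DataFrame({
        "id": pop.ids, "mother": pop.mother, "father": pop.father,
        "family": pop.family,
    })
    for t in range(pop.gv.shape[1]):
        out[f"gv{t + 1}"] = pop.gv[:, t]
        if pop.pheno is not None:
            out[f"pheno{t + 1}"] = pop.pheno[:, t]
        if pop.ebv is not None:
            out[f"ebv{t + 1}"] = pop.ebv[:, t]
    return out


def write_pedigree(pops: Sequence[Population], path: str) -> None:
    """Three-column pedigree (id, mother, father) for a list of populations."""
    rows = []
    for pop in pops:
        for i in range(pop.n_ind):
            rows.append((pop.ids[i], pop.mother[i], pop.father[i]))
    pd.DataFrame(rows, columns=["id", "mother", "father"]).to_csv(
        path, sep="\t", index=False)
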