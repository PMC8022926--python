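"""ADEG trait architectures.

A trait is built from four kinds of biological effects at its QTL --
Additive, Dominance, additive-by-additive Epistasis between discrete pairs
of loci, and Genotype-by-environment (additive effects proportional to a
single environmental covariate).  The letters of the effects present name
the trait type: A, AD, AE, AG, ADE, ADG, AEG, ADEG.

The genetic value of an individual with QTL dosages ``x`` (0..ploidy) is

    gv = intercept
       + sum_i a_i (x_i - ploidy/2)
       + sum_i d_i h(x_i)
       + sum_pairs e_p (x_i - ploidy/2)(x_j - ploidy/2)
       + w * sum_i g_i (x_i - ploidy/2)

with ``h(x) = x (ploidy - x)``: for diploids the heterozygote indicator, for
autotetraploids the number of heterozygous chromosome pairs among the six
(digenic dominance), symmetric with h(0) = h(ploidy) = 0.  ``w`` is the
environmental covariate, drawn per phenotyping event as N(0, var_w).

Raw effects are sampled from an initial distribution (standard normal, or
gamma magnitudes with random signs for additive effects), dominance effects
as ``d_i = delta_i |a_i|`` with the dominance degree ``delta_i`` drawn from
N(mean_dd, var_dd), and then *scaled* so that the founder population has
exactly the requested mean and variance (total genetic or additive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Trait",
    "TraitSamplingSpec",
    "sample_trait",
    "sample_correlated_traits",
    "scale_to_target",
    "genetic_value",
    "trait_to_json",
    "trait_from_json",
]

TRAIT_TYPES = ("A", "AD", "AE", "AG", "ADE", "ADG", "AEG", "ADEG")


@dataclass
class Trait:
    """One realized ADEG trait architecture."""

    qtl_chr: np.ndarray
    qtl_idx: np.ndarray
    a: np.ndarray
    ploidy: int = 2
    d: Optional[np.ndarray] = None
    epi_pairs: Optional[np.ndarray] = None  # (k, 2) indices into the QTL arrays
    epi_eff: Optional[np.ndarray] = None
    g: Optional[np.ndarray] = None
    var_w: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.qtl_chr = np.asarray(self.qtl_chr, dtype=np.int64)
        self.qtl_idx = np.asarray(self.qtl_idx, dtype=np.int64)
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.a)
        if len(self.qtl_chr) != n or len(self.qtl_idx) != n:
            raise ValueError("QTL address and effect lengths differ")
        if self.d is not None:
            self.d = np.asarray(self.d, dtype=float)
            if len(self.d) != n:
                raise ValueError("dominance effect length differs from QTL count")
        if self.epi_pairs is not None:
            self.epi_pairs = np.asarray(self.epi_pairs, dtype=np.int64).reshape(-1, 2)
            self.epi_eff = np.asarray(self.epi_eff, dtype=float)
            if len(self.epi_eff) != len(self.epi_pairs):
                raise ValueError("epistatic pair and effect counts differ")
            flat = self.epi_pairs.ravel()
            if len(np.unique(flat)) != len(flat):
                raise ValueError("epistatic pairs must be disjoint")
        if self.g is not None:
            self.g = np.asarray(self.g, dtype=float)
            if len(self.g) != n:
                raise ValueError("GxE effect length differs from QTL count")

    @property
    def n_qtl(self) -> int:
        return len(self.a)

    @property
    def type_tag(self) -> str:
        tag = "A"
        if self.d is not None:
            tag += "D"
        if self.epi_pairs is not None and len(self.epi_pairs) > 0:
            tag += "E"
        if self.g is not None:
            tag += "G"
        return tag

    def copy(self) -> "Trait":
        return Trait(
            qtl_chr=self.qtl_chr.copy(), qtl_idx=self.qtl_idx.copy(),
            a=self.a.copy(), ploidy=self.ploidy,
            d=None if self.d is None else self.d.copy(),
            epi_pairs=None if self.epi_pairs is None else self.epi_pairs.copy(),
            epi_eff=None if self.epi_eff is None else self.epi_eff.copy(),
            g=None if self.g is None else self.g.copy(),
            var_w=self.var_w, intercept=self.intercept,
        )


@dataclass
class TraitSamplingSpec:
    """How to sample a trait architecture.

    trait_type selects which effect families are populated.  ``var`` is the
    target founder variance, either total genetic ("total") or additive
    ("additive", measured by the variance decomposition).  Additive effects
    come from a standard normal or from a gamma distribution with the given
    shape and a random sign.  mean_dd/var_dd parameterize the dominance
    degree, rel_aa and rel_gxe the raw epistatic and GxE effect magnitudes
    relative to the raw additive ones, and var_w the environmental
    covariate's variance.
    """

    n_qtl_per_chr: int
    trait_type: str = "A"
    mean: float = 0.0
    var: float = 1.0
    var_selector: str = "total"
    dist: str = "normal"
    gamma_shape: float = 0.4
    mean_dd: float = 0.0
    var_dd: float = 0.0
    rel_aa: float = 1.0
    rel_gxe: float = 1.0
    var_w: float = 1.0

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"unknown trait type {self.trait_type!r}")
        if self.n_qtl_per_chr < 1:
            raise ValueError("n_qtl_per_chr must be >= 1")
        if self.var < 0 or self.var_dd < 0 or self.var_w < 0:
            raise ValueError("variances must be non-negative")
        if self.var_selector not in ("total", "additive"):
            raise ValueError("var_selector must be 'total' or 'additive'")
        if self.dist not in ("normal", "gamma"):
            raise ValueError("dist must be 'normal' or 'gamma'")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _raw_additive(spec: TraitSamplingSpec, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    if spec.dist == "gamma":
        mag = rng.gamma(spec.gamma_shape, 1.0, size=n)
        sign = rng.integers(0, 2, size=n) * 2 - 1
        return mag * sign
    return rng.standard_normal(n)


def _sample_qtl(spec: TraitSamplingSpec, haplo, rng: np.random.Generator):
    chr_l, idx_l = [], []
    for c in range(haplo.n_chr):
        L = haplo.n_loci[c]
        if spec.n_qtl_per_chr > L:
            raise ValueError(
                f"chromosome {c + 1} has {L} loci but {spec.n_qtl_per_chr} "
                "QTL were requested"
            )
        picked = np.sort(rng.choice(L, size=spec.n_qtl_per_chr, replace=False))
        chr_l.append(np.full(spec.n_qtl_per_chr, c, dtype=np.int64))
        idx_l.append(picked)
    return np.concatenate(chr_l), np.concatenate(idx_l)


def _assemble(spec: TraitSamplingSpec, qtl_chr, qtl_idx, raw_a,
              ploidy: int, rng: np.random.Generator) -> Trait:
    n = len(raw_a)
    d = epi_pairs = epi_eff = g = None
    if "D" in spec.trait_type:
        delta = spec.mean_dd + np.sqrt(spec.var_dd) * rng.standard_normal(n)
        d = delta * np.abs(raw_a)
    if "E" in spec.trait_type:
        perm = rng.permutation(n)
        n_pairs = n // 2
        if n % 2:
            log.info("odd QTL count %d: last QTL carries no epistatic effect", n)
        epi_pairs = perm[: 2 * n_pairs].reshape(n_pairs, 2)
        epi_eff = _raw_additive(spec, n_pairs, rng) * spec.rel_aa
    if "G" in spec.trait_type:
        g = _raw_additive(spec, n, rng) * spec.rel_gxe
    return Trait(qtl_chr=qtl_chr, qtl_idx=qtl_idx, a=raw_a, ploidy=ploidy,
                 d=d, epi_pairs=epi_pairs, epi_eff=epi_eff, g=g,
                 var_w=spec.var_w)


def sample_trait(spec: TraitSamplingSpec, haplo, rng: np.random.Generator,
                 ploidy: Optional[int] = None, scale: bool = True) -> Trait:
    """Sample a trait on founder haplotypes and scale it to the requested
    founder mean and variance.

    QTL are drawn uniformly without replacement per chromosome.  With an odd
    QTL count and epistasis, the last unpaired QTL carries no epistatic
    effect (logged).
    """
    ploidy = haplo.ploidy if ploidy is None else ploidy
    qtl_chr, qtl_idx = _sample_qtl(spec, haplo, rng)
    raw_a = _raw_additive(spec, len(qtl_chr), rng)
    trait = _assemble(spec, qtl_chr, qtl_idx, raw_a, ploidy, rng)
    if scale:
        trait = scale_to_target(trait, haplo, spec.mean, spec.var,
                                spec.var_selector)
    return trait


def sample_correlated_traits(spec: TraitSamplingSpec, n_traits: int,
                             corr: np.ndarray, haplo,
                             rng: np.random.Generator,
                             ploidy: Optional[int] = None) -> list[Trait]:
    """Sample pleiotropic traits of the same type with correlated additive
    effects (a matrix square root of ``corr`` applied to i.i.d. draws).

    All traits share the same QTL.  Only the normal initial distribution is
    supported for correlated draws.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (n_traits, n_traits):
        raise ValueError("correlation matrix shape does not match n_traits")
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("corr must be symmetric with unit diagonal")
    if spec.dist != "normal":
        raise ValueError("correlated traits require the normal initial "
                         "distribution")
    ploidy = haplo.ploidy if ploidy is None else ploidy
    qtl_chr, qtl_idx = _sample_qtl(spec, haplo, rng)
    n = len(qtl_chr)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_traits))
    raw = rng.standard_normal((n, n_traits)) @ chol.T
    traits = []
    for t in range(n_traits):
        tr = _assemble(spec, qtl_chr, qtl_idx, raw[:, t].copy(), ploidy, rng)
        traits.append(scale_to_target(tr, haplo, spec.mean, spec.var,
                                      spec.var_selector))
    return traits


# ---------------------------------------------------------------------------
# scaling and evaluation
# ---------------------------------------------------------------------------

def _dosages(pop_or_haplo, trait: Trait) -> np.ndarray:
    haplo = getattr(pop_or_haplo, "haplo", pop_or_haplo)
    return haplo.dosages_at(trait.qtl_chr, trait.qtl_idx).astype(float)


def _gv_from_haplo(trait: Trait, haplo, w: Optional[float]) -> np.ndarray:
    """Chromosome-chunked genetic values, avoiding the full dosage matrix."""
    half = trait.ploidy / 2.0
    gv = np.full(haplo.n_ind, float(trait.intercept))
    for c in np.unique(trait.qtl_chr):
        sel = trait.qtl_chr == c
        X = haplo.alleles(int(c))[:, :, trait.qtl_idx[sel]] \
            .sum(axis=1, dtype=np.int64).astype(float)
        Xc = X - half
        gv += Xc @ trait.a[sel]
        if trait.d is not None:
            gv += (X * (trait.ploidy - X)) @ trait.d[sel]
        if trait.g is not None and w is not None:
            gv += w * (Xc @ trait.g[sel])
    if trait.g is not None and w is None:
        raise ValueError("a G-type trait needs the environmental covariate w")
    if trait.epi_pairs is not None and len(trait.epi_pairs) > 0:
        i = trait.epi_pairs[:, 0]
        j = trait.epi_pairs[:, 1]
        pair_loci = np.concatenate([i, j])
        Xp = haplo.dosages_at(trait.qtl_chr[pair_loci],
                              trait.qtl_idx[pair_loci]).astype(float) - half
        k = len(i)
        gv += (Xp[:, :k] * Xp[:, k:]) @ trait.epi_eff
    return gv


def genetic_value(trait: Trait, genotypes, w: Optional[float] = None
                  ) -> np.ndarray:
    """Genetic values for a dosage matrix, HaploSet, or Population.

    ``w`` must be supplied for G-type traits (and only then contributes);
    the stored genetic value of a population is the environment-free part.
    """
    if hasattr(genotypes, "dosages_at") or hasattr(genotypes, "haplo"):
        haplo = getattr(genotypes, "haplo", genotypes)
        return _gv_from_haplo(trait, haplo, w)
    X = np.atleast_2d(np.asarray(genotypes, dtype=float))
    half = trait.ploidy / 2.0
    Xc = X - half
    gv = trait.intercept + Xc @ trait.a
    if trait.d is not None:
        gv = gv + (X * (trait.ploidy - X)) @ trait.d
    if trait.epi_pairs is not None and len(trait.epi_pairs) > 0:
        i = trait.epi_pairs[:, 0]
        j = trait.epi_pairs[:, 1]
        gv = gv + (Xc[:, i] * Xc[:, j]) @ trait.epi_eff
    if trait.g is not None:
        if w is None:
            raise ValueError("a G-type trait needs the environmental "
                             "covariate w")
        gv = gv + w * (Xc @ trait.g)
    return gv


def gxe_deviation(trait: Trait, genotypes) -> np.ndarray:
    """The per-individual GxE slope sum (multiplied by w at phenotyping)."""
    if trait.g is None:
        raise ValueError("trait has no GxE effects")
    if isinstance(genotypes, np.ndarray):
        return (np.atleast_2d(genotypes.astype(float)) - trait.ploidy / 2.0) \
            @ trait.g
    haplo = getattr(genotypes, "haplo", genotypes)
    out = np.zeros(haplo.n_ind)
    half = trait.ploidy / 2.0
    for c in np.unique(trait.qtl_chr):
        sel = trait.qtl_chr == c
        X = haplo.alleles(int(c))[:, :, trait.qtl_idx[sel]] \
            .sum(axis=1, dtype=np.int64).astype(float)
        out += (X - half) @ trait.g[sel]
    return out


def scale_to_target(trait: Trait, founder, mu: float, var: float,
                    selector: str = "total") -> Trait:
    """Scale all effects and set the intercept so the founder population has
    exactly mean ``mu`` and variance ``var``.

    ``selector='total'`` targets the total genetic variance;
    ``'additive'`` targets the additive component from the variance
    decomposition.  All effects are multiplied by
    ``sqrt(var / observed)``; because every term of the genetic value is
    linear in its effect vector, the scaling is exact (and idempotent) to
    floating-point precision.
    """
    out = trait.copy()
    if var == 0.0:
        out.a = np.zeros_like(out.a)
        if out.d is not None:
            out.d = np.zeros_like(out.d)
        if out.epi_eff is not None:
            out.epi_eff = np.zeros_like(out.epi_eff)
        if out.g is not None:
            out.g = np.zeros_like(out.g)
        out.intercept = float(mu)
        return out
    if selector == "total":
        gv = genetic_value(out, founder, w=None if out.g is None else 0.0)
        observed = float(np.var(gv))
    elif selector == "additive":
        from .varcomp import decompose

        observed = decompose(founder, out).V_A
    else:
        raise ValueError("selector must be 'total' or 'additive'")
    if observed <= 0.0:
        raise ValueError(
            "observed founder variance is zero (monomorphic QTL draw); "
            "cannot scale to a positive target variance"
        )
    c = float(np.sqrt(var / observed))
    out.a = out.a * c
    if out.d is not None:
        out.d = out.d * c
    if out.epi_eff is not None:
        out.epi_eff = out.epi_eff * c
    if out.g is not None:
        out.g = out.g * c
    gv = genetic_value(out, founder, w=None if out.g is None else 0.0)
    out.intercept = out.intercept + (mu - float(np.mean(gv)))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def trait_to_json(trait: Trait) -> str:
    def arr(x):
        return None if x is None else np.asarray(x).tolist()

    return json.dumps({
        "qtl_chr": arr(trait.qtl_chr), "qtl_idx": arr(trait.qtl_idx),
        "a": arr(trait.a), "ploidy": trait.ploidy, "d": arr(trait.d),
        "epi_pairs": arr(trait.epi_pairs), "epi_eff": arr(trait.epi_eff),
        "g": arr(trait.g), "var_w": trait.var_w,
        "intercept": trait.intercept, "type_tag": trait.type_tag,
    }, indent=1)


def trait_from_json(text: str) -> Trait:
    obj = json.loads(text)
    def arr(x):
        return None if x is None else np.asarray(x)

    return Trait(
        qtl_chr=np.asarray(obj["qtl_chr"]), qtl_idx=np.asarray(obj["qtl_idx"]),
        a=np.asarray(obj["a"]), ploidy=int(obj["ploidy"]), d=arr(obj["d"]),
        epi_pairs=arr(obj["epi_pairs"]), epi_eff=arr(obj["epi_eff"]),
        g=arr(obj["g"]), var_w=float(obj["var_w"]),
        intercept=float(obj["intercept"]),
    )
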