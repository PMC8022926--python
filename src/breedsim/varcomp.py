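"""Genetic variance decomposition valid under arbitrary population structure.

For each QTL the average effect ``alpha`` is the least-squares regression
slope of the locus's own genotypic value on allele dosage, computed with the
observed genotype frequencies -- no Hardy-Weinberg or linkage-equilibrium
assumption.  Breeding values are ``sum_l alpha_l (x_l - mean(x_l))`` and the
additive variance is their empirical variance, so covariances between loci
(linkage disequilibrium) are included automatically.  The additive variance
is further partitioned exactly as

    V_A = genic_A + cov_HWE + cov_LD

where ``genic_A = sum_l ploidy p_l q_l alpha_l^2`` is the additive variance
expected at observed allele frequencies under Hardy-Weinberg and linkage
equilibrium, ``cov_HWE = sum_l (var(x_l) - ploidy p_l q_l) alpha_l^2``
captures departures from Hardy-Weinberg genotype proportions, and
``cov_LD = V_A - sum_l var(x_l) alpha_l^2`` the between-locus dosage
covariances.

Dominance deviations are the residuals of the per-locus regressions and the
additive-by-additive deviations the residuals of per-pair regressions of the
epistatic term on the two dosages (their fitted linear parts are credited to
the average effects, so epistasis contributes to V_A the way average-effect
theory prescribes).  All variances are population variances (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VarComps", "decompose", "founder_snapshot"]


@dataclass
class VarComps:
    mu: float
    V_A: float
    V_D: float
    V_AA: float
    V_G: float
    genic_A: float
    cov_HWE: float
    cov_LD: float

    def to_row(self) -> dict:
        return {
            "mu": self.mu, "V_A": self.V_A, "V_D": self.V_D,
            "V_AA": self.V_AA, "V_G": self.V_G, "genic_A": self.genic_A,
            "cov_HWE": self.cov_HWE, "cov_LD": self.cov_LD,
        }


def _dosage_matrix(pop, trait) -> np.ndarray:
    """Accept a Population or a HaploSet."""
    haplo = getattr(pop, "haplo", pop)
    return haplo.dosages_at(trait.qtl_chr, trait.qtl_idx).astype(float)


def decompose(pop, trait) -> VarComps:
    """Decompose the genetic variance of ``trait`` in ``pop``.

    ``pop`` may be a Population or a bare HaploSet.  A monomorphic trait
    (all genetic values equal) yields all-zero components.
    """
    X = _dosage_matrix(pop, trait)
    n, m = X.shape
    if n == 0:
        raise ValueError("population is empty")
    ploidy = trait.ploidy
    half = ploidy / 2.0

    xbar = X.mean(axis=0)
    varx = X.var(axis=0)

    a = np.asarray(trait.a, dtype=float)
    d = trait.d if trait.d is not None else None

    # per-locus genotypic values: additive (+ dominance) terms
    V = a * (X - half)
    if d is not None:
        V = V + np.asarray(d, dtype=float) * (X * (ploidy - X))

    with np.errstate(invalid="ignore", divide="ignore"):
        cov_vx = ((V - V.mean(axis=0)) * (X - xbar)).mean(axis=0)
        alpha = np.where(varx > 0, cov_vx / np.where(varx > 0, varx, 1.0), 0.0)

    if d is None:
        # a purely additive per-locus value is its own regression fit
        dom_dev = np.zeros(n)
    else:
        fitted = V.mean(axis=0) + alpha * (X - xbar)
        dom_dev = (V - fitted).sum(axis=1)

    gv = trait.intercept + V.sum(axis=1)

    # epistatic pairs: regress each pair's term on the two dosages; the
    # linear parts augment the average effects, the residual is the AA
    # deviation
    aa_dev = np.zeros(n)
    if trait.epi_pairs is not None and len(trait.epi_pairs) > 0:
        for (i, j), e in zip(trait.epi_pairs, trait.epi_eff):
            t = e * (X[:, i] - half) * (X[:, j] - half)
            gv = gv + t
            D = np.column_stack([np.ones(n), X[:, i], X[:, j]])
            beta, *_ = np.linalg.lstsq(D, t, rcond=None)
            alpha[i] += beta[1]
            alpha[j] += beta[2]
            aa_dev += t - D @ beta

    bv = (X - xbar) @ alpha
    V_A = float(bv.var())
    V_D = float(dom_dev.var())
    V_AA = float(aa_dev.var())
    V_G = float(gv.var())

    p = xbar / ploidy
    q = 1.0 - p
    genic = float(np.sum(ploidy * p * q * alpha ** 2))
    sum_locus = float(np.sum(varx * alpha ** 2))
    cov_HWE = sum_locus - genic
    cov_LD = V_A - sum_locus
    return VarComps(
        mu=float(gv.mean()), V_A=V_A, V_D=V_D, V_AA=V_AA, V_G=V_G,
        genic_A=genic, cov_HWE=cov_HWE, cov_LD=cov_LD,
    )


def founder_snapshot(pop, trait, sim_params=None, trait_index: int = 0
                     ) -> VarComps:
    """Decompose and cache the founder variance components.

    When ``sim_params`` is given, the result is stored in its
    ``founder_varcomps`` slot for ``trait_index`` (where trait scaling and
    the H2-to-error-variance conversion read it).  Returns the fresh
    decomposition either way; calling it again simply recomputes, so a
    rescaled trait is re-snapshotted by re-invoking it.
    """
    vc = decompose(pop, trait)
    if sim_params is not None:
        slots = sim_params.founder_varcomps
        while len(slots) <= trait_index:
            slots.append(None)
        slots[trait_index] = vc
    return vc
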