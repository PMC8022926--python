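"""Meiosis under the gamma model of crossover interference.

Chiasmata on the four-strand bundle form a stationary gamma renewal process
with shape ``nu`` and rate ``2*nu`` per Morgan, so the chiasma rate is 2 per
Morgan and -- after each chiasma is inherited by a given chromatid with
probability 1/2 (no chromatid interference) -- the crossover rate is 1 per
Morgan.  ``nu = 1`` gives a Poisson process (no interference); ``nu > 1``
spaces crossovers more evenly.  No obligate chiasma is enforced: at
``nu = 1`` the chiasma count on an L-Morgan chromosome is Poisson(2L) and a
gamete carries zero crossovers with probability ``exp(-L)``.

Diploids resolve each homologue pair as a bivalent.  Autotetraploids pair
each homologue group as a quadrivalent with probability ``p_quad``, else as
two random bivalents.  A quadrivalent is modeled as a cross-type
configuration: one exchange point splits the chromosome into two regions
with different pairing partners, chiasmata are sampled per pairing arm, and
chromatids are resolved from two sampled centromeres outward toward the
telomeres.  This produces chromatids carrying segments of up to three
parental chromosomes and, at loci separated from the centromere by a
crossover, double reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .founders import ChromMap, GeneticMap

__all__ = [
    "MeiosisParams",
    "GameteChrom",
    "Gamete",
    "sample_chiasmata",
    "bivalent_gamete",
    "quadrivalent_gamete",
    "make_gamete",
    "make_cross",
    "tracts_to_bed",
]


@dataclass
class MeiosisParams:
    """Recombination model parameters.

    nu: gamma interference shape; 1 = no interference. The default 2.6 is a
        value commonly fitted to experimental crossover data.
    p_quad: probability a tetraploid homologue group pairs as a quadrivalent.
    use_sex_maps: use the male map for paternal gametes when available.
    """

    nu: float = 2.6
    p_quad: float = 0.0
    use_sex_maps: bool = False

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("interference parameter nu must be > 0")
        if not 0.0 <= self.p_quad <= 1.0:
            raise ValueError("p_quad must lie in [0, 1]")


@dataclass
class GameteChrom:
    """One gamete chromosome: alleles plus the crossover-tract record.

    Tracts are (source haplotype index, start locus, end locus) half-open
    locus intervals that tile the chromosome exactly once; the allele at
    each locus equals the source haplotype's allele there.
    """

    alleles: np.ndarray
    tracts: list[tuple[int, int, int]]
    sibling: Optional["GameteChrom"] = None


@dataclass
class Gamete:
    """One gamete: a GameteChrom per chromosome (2 per chromosome if from a
    tetraploid parent, stored as consecutive entries in ``chromatids``)."""

    chromosomes: list[list[GameteChrom]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# chiasma process
# ---------------------------------------------------------------------------

def sample_chiasmata(map_len_morgans: float, nu: float,
                     rng: np.random.Generator,
                     origin: float = 0.0) -> np.ndarray:
    """Chiasma positions on ``[origin, origin + map_len]``.

    Stationary gamma renewal process with shape ``nu`` and rate ``2*nu``:
    the first event is placed at ``U * T`` where ``T`` is a length-biased
    interarrival (Gamma(nu+1, rate 2*nu)), which is the forward recurrence
    time of the equilibrium process; subsequent interarrivals are
    Gamma(nu, rate 2*nu).
    """
    if map_len_morgans < 0:
        raise ValueError("map length must be non-negative")
    if nu <= 0:
        raise ValueError("nu must be > 0")
    scale = 1.0 / (2.0 * nu)
    pts = []
    x = rng.uniform() * rng.gamma(nu + 1.0, scale)
    while x <= map_len_morgans:
        pts.append(x)
        x += rng.gamma(nu, scale)
    return np.asarray(pts) + origin


def _thin(chiasmata: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Each chiasma involves the sampled chromatid with probability 1/2."""
    if len(chiasmata) == 0:
        return chiasmata
    return chiasmata[rng.random(len(chiasmata)) < 0.5]


def _sources_to_tracts(src: np.ndarray) -> list[tuple[int, int, int]]:
    n = len(src)
    if n == 0:
        return []
    breaks = np.flatnonzero(np.diff(src)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [n]])
    return [(int(src[s]), int(s), int(e)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# bivalent resolution
# ---------------------------------------------------------------------------

def _bivalent_sources(positions: np.ndarray, map_len: float, nu: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Source-haplotype index (0/1) per locus for one bivalent gamete."""
    xo = _thin(sample_chiasmata(map_len, nu, rng), rng)
    start = int(rng.integers(2))
    if len(xo) == 0:
        return np.full(len(positions), start, dtype=np.int64)
    # a crossover at position q switches all loci with map position >= q
    return (start + np.searchsorted(xo, positions, side="right")) % 2


def bivalent_gamete(pair_of_haplotypes: Sequence[np.ndarray],
                    chrom_map: ChromMap, nu: float,
                    rng: np.random.Generator) -> GameteChrom:
    """Resolve one bivalent: a single recombinant chromatid from two homologues."""
    h0, h1 = pair_of_haplotypes
    h0 = np.asarray(h0)
    h1 = np.asarray(h1)
    if h0.shape != h1.shape or len(h0) != chrom_map.n_loci:
        raise ValueError("haplotype length does not match the chromosome map")
    src = _bivalent_sources(chrom_map.positions, chrom_map.length, nu, rng)
    alleles = np.where(src == 0, h0, h1)
    return GameteChrom(alleles, _sources_to_tracts(src))


# ---------------------------------------------------------------------------
# quadrivalent (cross-type) resolution
# ---------------------------------------------------------------------------

def _quadrivalent_sources(positions: np.ndarray, map_len: float,
                          centromere: float, nu: float,
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Source-chromosome index (0..3) per locus for the two chromatids of one
    tetraploid gamete from a cross-type quadrivalent.

    One exchange point is placed uniformly on the map.  Left of it the
    pairing arms are (0,1) and (2,3); right of it (0,2) and (1,3), with the
    four homologues randomly assigned to these roles by the caller's
    shuffling of haplotype order.  Chiasmata are sampled per arm from the
    stationary gamma process.  Two centromeres are drawn without
    replacement and each chromatid is resolved from its centromere outward,
    switching to the pairing partner at each chiasma with probability 1/2.
    """
    e = rng.uniform(0.0, map_len) if map_len > 0 else 0.0
    # chiasmata per pairing arm: (positions, partner-of map)
    arms = []
    if e > 0:
        for pair in ((0, 1), (2, 3)):
            arms.append((sample_chiasmata(e, nu, rng), pair))
    if map_len - e > 0:
        for pair in ((0, 2), (1, 3)):
            arms.append((sample_chiasmata(map_len - e, nu, rng, origin=e), pair))
    # merge into one sorted list
    all_pos = np.concatenate([a[0] for a in arms]) if arms else np.empty(0)
    all_pair = (
        np.concatenate([np.full(len(a[0]), i) for i, a in enumerate(arms)])
        if arms else np.empty(0, dtype=np.int64)
    )
    order = np.argsort(all_pos, kind="stable")
    all_pos = all_pos[order]
    all_pair = all_pair[order].astype(np.int64)
    pair_lut = [a[1] for a in arms]

    cents = rng.choice(4, size=2, replace=False)
    out = []
    for k0 in cents:
        # walk right from the centromere
        right_q, right_chain = [], [int(k0)]
        cur = int(k0)
        for q, pi in zip(all_pos, all_pair):
            if q <= centromere:
                continue
            pa = pair_lut[pi]
            if cur in pa and rng.random() < 0.5:
                cur = pa[0] if cur == pa[1] else pa[1]
                right_q.append(q)
                right_chain.append(cur)
        # walk left from the centromere (descending positions)
        left_q, left_chain = [], [int(k0)]
        cur = int(k0)
        for q, pi in zip(all_pos[::-1], all_pair[::-1]):
            if q > centromere:
                continue
            pa = pair_lut[pi]
            if cur in pa and rng.random() < 0.5:
                cur = pa[0] if cur == pa[1] else pa[1]
                left_q.append(q)
                left_chain.append(cur)
        src = np.empty(len(positions), dtype=np.int64)
        right_mask = positions > centromere
        if right_mask.any():
            idx = np.searchsorted(np.asarray(right_q), positions[right_mask],
                                  side="right")
            src[right_mask] = np.asarray(right_chain)[idx]
        left_mask = ~right_mask
        if left_mask.any():
            # left switches at descending q: locus is past j-th switch iff
            # its position < q_j
            lq = np.asarray(left_q)[::-1]  # ascending
            chain = np.asarray(left_chain)
            cnt = len(lq) - np.searchsorted(lq, positions[left_mask],
                                            side="left")
            src[left_mask] = chain[cnt]
        out.append(src)
    return out[0], out[1]


def quadrivalent_gamete(four_haplotypes: Sequence[np.ndarray],
                        chrom_map: ChromMap, nu: float,
                        rng: np.random.Generator) -> GameteChrom:
    """Resolve one cross-type quadrivalent; returns one chromatid with its
    sibling (the second chromatid of the same gamete) attached."""
    if len(four_haplotypes) != 4:
        raise ValueError("a quadrivalent needs exactly four haplotypes")
    haps = [np.asarray(h) for h in four_haplotypes]
    if any(len(h) != chrom_map.n_loci for h in haps):
        raise ValueError("haplotype length does not match the chromosome map")
    perm = rng.permutation(4)
    src_a, src_b = _quadrivalent_sources(
        chrom_map.positions, chrom_map.length, chrom_map.centromere, nu, rng
    )
    src_a = perm[src_a]
    src_b = perm[src_b]
    stacked = np.stack(haps)
    pos_idx = np.arange(chrom_map.n_loci)
    ga = GameteChrom(stacked[src_a, pos_idx], _sources_to_tracts(src_a))
    gb = GameteChrom(stacked[src_b, pos_idx], _sources_to_tracts(src_b))
    ga.sibling = gb
    gb.sibling = ga
    return ga


# ---------------------------------------------------------------------------
# whole-genome gametes and crosses
# ---------------------------------------------------------------------------

def make_gamete(parent_haps: Sequence[np.ndarray], gmap: GeneticMap,
                params: MeiosisParams, rng: np.random.Generator,
                sex: str = "female") -> list[list[np.ndarray]]:
    """Sample one gamete from a parent.

    parent_haps: per-chromosome arrays of shape (ploidy, n_loci).
    Returns per-chromosome lists of gamete haplotypes (1 for diploid parents,
    2 for tetraploid parents).
    """
    out = []
    for c, cm in enumerate(gmap):
        haps = parent_haps[c]
        ploidy = haps.shape[0]
        positions = cm.positions_for(sex) if params.use_sex_maps else cm.positions
        eff_map = ChromMap(positions, cm.length, cm.centromere) \
            if positions is not cm.positions else cm
        if ploidy == 2:
            out.append([bivalent_gamete(haps, eff_map, params.nu, rng).alleles])
        elif ploidy == 4:
            if rng.random() < params.p_quad:
                ga = quadrivalent_gamete(list(haps), eff_map, params.nu, rng)
                out.append([ga.alleles, ga.sibling.alleles])
            else:
                perm = rng.permutation(4)
                g1 = bivalent_gamete(haps[perm[:2]], eff_map, params.nu, rng)
                g2 = bivalent_gamete(haps[perm[2:]], eff_map, params.nu, rng)
                out.append([g1.alleles, g2.alleles])
        else:
            raise ValueError("only ploidy 2 and 4 are supported")
    return out


def make_cross(mother: Sequence[np.ndarray], father: Sequence[np.ndarray],
               n_progeny: int, gmap: GeneticMap, params: MeiosisParams,
               rng: np.random.Generator) -> list[list[np.ndarray]]:
    """Gene-drop ``n_progeny`` offspring from two parents.

    mother/father: per-chromosome (ploidy, n_loci) arrays sharing the map.
    Returns a list of progeny, each a per-chromosome (ploidy, n_loci) array.
    The maternal gamete uses the female map and the paternal gamete the male
    map when sex-specific maps are enabled.
    """
    if len(mother) != len(father):
        raise ValueError("parents must share the chromosome structure")
    for m, f in zip(mother, father):
        if m.shape != f.shape:
            raise ValueError("parents must have equal ploidy and locus counts")
    progeny = []
    for _ in range(n_progeny):
        gm = make_gamete(mother, gmap, params, rng, sex="female")
        gf = make_gamete(father, gmap, params, rng, sex="male")
        progeny.append([np.stack(gm[c] + gf[c]) for c in range(len(gmap.chromosomes))])
    return progeny


def tracts_to_bed(gamete: GameteChrom, chrom: str = "chr1") -> str:
    """Crossover tracts as BED-like text (chrom, start, end, source), 0-based
    half-open locus coordinates."""
    return "\n".join(
        f"{chrom}\t{s}\t{e}\t{src}" for src, s, e in gamete.tracts
    )
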