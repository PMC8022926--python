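"""Founder haplotype generation.

Founder genomes enter a simulation in one of three ways:

* :func:`run_coalescent` -- a native Markovian coalescent with recombination
  (sequential prune-and-regraft tree transitions along the chromosome) that
  produces whole-chromosome haplotypes whose linkage disequilibrium and
  allele-frequency spectrum follow a neutral constant-size population model;
* :func:`quick_haplo` -- fast random sampling of alleles at frequency 0.5,
  useful for tests and for simulations where founder LD is irrelevant;
* :func:`import_haplotypes` -- phased VCF plus a genetic map in Morgans, so
  output from other coalescent simulators or real phased data can be used.

Haplotypes are stored bit-packed (one bit per allele) in :class:`HaploSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FounderConfig",
    "ChromMap",
    "GeneticMap",
    "HaploSet",
    "run_coalescent",
    "quick_haplo",
    "import_haplotypes",
    "export_haplotypes",
    "write_map",
    "read_map",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class FounderConfig:
    """Parameters of the neutral constant-size founder model.

    The defaults correspond to a generic neutral population: effective size
    ``Ne`` of 100 diploids, 10^8 bp chromosomes, mutation rate 2.5e-8 and
    recombination rate 1e-8 per base per generation (so each chromosome has
    an expected genetic length of 1 Morgan).
    """

    n_ind: int
    n_chr: int
    seg_sites: int
    Ne: float = 100.0
    bp: float = 1e8
    mut_rate: float = 2.5e-8
    rec_rate: float = 1e-8
    ploidy: int = 2
    inbred: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_ind < 1:
            raise ValueError("n_ind must be >= 1")
        if self.n_chr < 1:
            raise ValueError("n_chr must be >= 1")
        if self.seg_sites < 1:
            raise ValueError("seg_sites must be >= 1")
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.bp <= 0:
            raise ValueError("chromosome length bp must be positive")
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.mut_rate < 0 or self.rec_rate < 0:
            raise ValueError("rates must be non-negative")


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class ChromMap:
    """Genetic map of one chromosome.

    positions: locus positions in Morgans, non-decreasing, within [0, length].
    length: total map length in Morgans (crossovers are sampled on [0, length]).
    centromere: centromere position in Morgans (defaults to the midpoint).
    male_positions: optional second map for paternal meiosis (sex-specific maps).
    """

    positions: np.ndarray
    length: float
    centromere: float = field(default=-1.0)
    male_positions: Optional[np.ndarray] = None
    ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("map positions must be non-decreasing")
        if self.length < 0:
            raise ValueError("map length must be non-negative")
        if self.centromere < 0:
            self.centromere = self.length / 2.0
        if not 0 <= self.centromere <= self.length:
            raise ValueError("centromere must lie within [0, length]")
        if self.male_positions is not None:
            self.male_positions = np.asarray(self.male_positions, dtype=float)
            if self.male_positions.shape != self.positions.shape:
                raise ValueError(
                    "male map must have the same locus count as the female map"
                )

    @property
    def n_loci(self) -> int:
        return len(self.positions)

    def positions_for(self, sex: str = "female") -> np.ndarray:
        if sex == "male" and self.male_positions is not None:
            return self.male_positions
        return self.positions


class GeneticMap:
    """Per-chromosome genetic maps (positions in Morgans)."""

    def __init__(self, chromosomes: Sequence[ChromMap]):
        if len(chromosomes) == 0:
            raise ValueError("a genetic map needs at least one chromosome")
        self.chromosomes = list(chromosomes)

    @property
    def n_chr(self) -> int:
        return len(self.chromosomes)

    @property
    def n_loci(self) -> list[int]:
        return [c.n_loci for c in self.chromosomes]

    def __getitem__(self, c: int) -> ChromMap:
        return self.chromosomes[c]

    def __iter__(self):
        return iter(self.chromosomes)

    def locus_ids(self, c: int) -> np.ndarray:
        cm = self.chromosomes[c]
        if cm.ids is not None:
            return np.asarray(cm.ids)
        return np.array([f"c{c + 1}_l{i + 1}" for i in range(cm.n_loci)])


# ---------------------------------------------------------------------------
# haplotype container
# ---------------------------------------------------------------------------

class HaploSet:
    """Phased biallelic haplotypes for a cohort, bit-packed per chromosome.

    Alleles are addressed as (individual, haplotype 0..ploidy-1, chromosome,
    locus) and take values 0/1.  Storage is one bit per allele
    (``numpy.packbits`` along the locus axis), unpacked on access.
    """

    def __init__(self, packed: list[np.ndarray], n_loci: list[int],
                 n_ind: int, ploidy: int):
        self._packed = packed
        self._n_loci = list(n_loci)
        self.n_ind = int(n_ind)
        self.ploidy = int(ploidy)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_alleles(cls, chrom_alleles: Sequence[np.ndarray]) -> "HaploSet":
        """Build from per-chromosome arrays of shape (n_ind, ploidy, n_loci)."""
        packed, n_loci = [], []
        n_ind = ploidy = None
        for arr in chrom_alleles:
            arr = np.ascontiguousarray(arr, dtype=np.uint8)
            if arr.ndim != 3:
                raise ValueError("each chromosome array must be 3-D")
            if arr.max(initial=0) > 1:
                raise ValueError("alleles must be 0 or 1")
            if n_ind is None:
                n_ind, ploidy = arr.shape[0], arr.shape[1]
            elif arr.shape[:2] != (n_ind, ploidy):
                raise ValueError("inconsistent shapes across chromosomes")
            packed.append(np.packbits(arr, axis=-1))
            n_loci.append(arr.shape[2])
        if n_ind is None:
            raise ValueError("at least one chromosome is required")
        return cls(packed, n_loci, n_ind, ploidy)

    # -- access ------------------------------------------------------------

    @property
    def n_chr(self) -> int:
        return len(self._packed)

    @property
    def n_loci(self) -> list[int]:
        return list(self._n_loci)

    @property
    def total_loci(self) -> int:
        return int(sum(self._n_loci))

    def alleles(self, c: int) -> np.ndarray:
        """Unpacked alleles of one chromosome, shape (n_ind, ploidy, n_loci)."""
        return np.unpackbits(self._packed[c], axis=-1, count=self._n_loci[c])

    def haplotype(self, ind: int, h: int, c: int) -> np.ndarray:
        return np.unpackbits(self._packed[c][ind, h], count=self._n_loci[c])

    def dosages(self) -> np.ndarray:
        """Allele-dosage matrix (n_ind, total loci), summed over haplotypes."""
        return np.concatenate(
            [self.alleles(c).sum(axis=1, dtype=np.int64) for c in range(self.n_chr)],
            axis=1,
        )

    def dosages_at(self, qtl_chr: np.ndarray, qtl_idx: np.ndarray) -> np.ndarray:
        """Dosages at selected loci, shape (n_ind, n_qtl)."""
        qtl_chr = np.asarray(qtl_chr)
        qtl_idx = np.asarray(qtl_idx)
        out = np.empty((self.n_ind, len(qtl_chr)), dtype=np.int64)
        for c in np.unique(qtl_chr):
            sel = qtl_chr == c
            cols = self.alleles(int(c))[:, :, qtl_idx[sel]]
            out[:, sel] = cols.sum(axis=1, dtype=np.int64)
        return out

    def allele_freq(self, c: int) -> np.ndarray:
        return self.alleles(c).mean(axis=(0, 1))

    def heterozygosity(self) -> np.ndarray:
        """Per-individual fraction of loci not fixed within the individual."""
        het = np.zeros(self.n_ind)
        for c in range(self.n_chr):
            a = self.alleles(c)
            het += np.logical_and(a.any(axis=1), ~a.all(axis=1)).sum(axis=1)
        return het / self.total_loci

    # -- manipulation ------------------------------------------------------

    def subset(self, idx: np.ndarray) -> "HaploSet":
        idx = np.asarray(idx)
        packed = [p[idx] for p in self._packed]
        return HaploSet(packed, self._n_loci, len(idx), self.ploidy)

    @classmethod
    def concatenate(cls, sets: Sequence["HaploSet"]) -> "HaploSet":
        first = sets[0]
        for s in sets[1:]:
            if s.n_loci != first.n_loci or s.ploidy != first.ploidy:
                raise ValueError("incompatible haplotype sets")
        packed = [
            np.concatenate([s._packed[c] for s in sets], axis=0)
            for c in range(first.n_chr)
        ]
        return cls(packed, first._n_loci, sum(s.n_ind for s in sets), first.ploidy)

    def equals(self, other: "HaploSet") -> bool:
        return (
            self.n_ind == other.n_ind
            and self.ploidy == other.ploidy
            and self._n_loci == other._n_loci
            and all(np.array_equal(a, b) for a, b in zip(self._packed, other._packed))
        )


# ---------------------------------------------------------------------------
# native Markovian coalescent with recombination
# ---------------------------------------------------------------------------
#
# Time is measured in units of 2*Ne generations, so a pair of lineages
# coalesces at rate 1.  Along the sequence, the local genealogy changes at
# recombination breakpoints: a point is chosen uniformly on the branches, the
# lineage above it is detached and re-coalesces with the remaining tree (the
# detached edge itself remains a valid re-coalescence target, in which case
# the tree is unchanged -- the SMC' "invisible" transition).  Mutations are
# laid down as a Poisson process on total branch length within each
# non-recombining segment.


def _initial_tree(n: int, rng: np.random.Generator):
    """Standard coalescent tree: parent pointers and node times.

    Nodes 0..n-1 are leaves; n..2n-2 internal, in coalescence order.
    """
    nnodes = 2 * n - 1
    parent = np.full(nnodes, -1, dtype=np.int64)
    time = np.zeros(nnodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return parent, time


def _leaves_under(parent: np.ndarray, node: int, n: int) -> np.ndarray:
    """Boolean mask over the n leaves descending from ``node``."""
    nnodes = len(parent)
    children: list[list[int]] = [[] for _ in range(nnodes)]
    for v in range(nnodes):
        p = parent[v]
        if p >= 0:
            children[p].append(v)
    mask = np.zeros(n, dtype=bool)
    stack = [node]
    while stack:
        v = stack.pop()
        if v < n:
            mask[v] = True
        else:
            stack.extend(children[v])
    return mask


def _subtree_nodes(parent: np.ndarray, node: int) -> set[int]:
    nnodes = len(parent)
    children: list[list[int]] = [[] for _ in range(nnodes)]
    for v in range(nnodes):
        p = parent[v]
        if p >= 0:
            children[p].append(v)
    out = set()
    stack = [node]
    while stack:
        v = stack.pop()
        out.add(v)
        stack.extend(children[v])
    return out


def _smc_transition(parent, time, n, rng):
    """One recombination transition of the local tree (in place on copies).

    Returns the new (parent, time); the input arrays are not modified.
    """
    nnodes = len(parent)
    # choose recombination point uniformly on the branches
    is_edge = parent >= 0
    blen = np.where(is_edge, time[parent] - time, 0.0)
    tot = blen.sum()
    v = rng.choice(nnodes, p=blen / tot)
    u = rng.uniform(time[v], time[parent[v]])
    p_old = int(parent[v])
    t_p = time[p_old]
    # prune: remove node p_old, splice its other child through
    sibs = [w for w in range(nnodes) if parent[w] == p_old and w != v]
    s = sibs[0]
    gp = int(parent[p_old])
    sub = _subtree_nodes(parent, v)
    # edges of the pruned tree: every node outside subtree(v), excluding p_old;
    # the sibling's edge now runs to gp (or to infinity if p_old was the root)
    lo, hi, edge_child = [], [], []
    for w in range(nnodes):
        if w in sub or w == p_old:
            continue
        if w == s:
            top = time[gp] if gp >= 0 else math.inf
        else:
            pw = parent[w]
            if pw == p_old:  # cannot happen: p_old binary
                top = t_p
            else:
                top = time[pw] if pw >= 0 else math.inf
        lo.append(time[w])
        hi.append(top)
        edge_child.append(w)
    # ghost edge: the detached lineage's former path up to its old parent
    lo.append(u)
    hi.append(t_p)
    edge_child.append(-1)
    lo = np.array(lo)
    hi = np.array(hi)
    # sweep upward from u for the re-coalescence time
    bounds = np.unique(np.concatenate([lo, hi]))
    bounds = bounds[np.isfinite(bounds)]
    t = u
    while True:
        crossing = (lo <= t) & (hi > t)
        k = int(crossing.sum())
        later = bounds[bounds > t]
        nxt = later[0] if len(later) else math.inf
        if k == 0:  # only possible transiently below next boundary
            t = nxt
            continue
        w_t = rng.exponential(1.0 / k)
        if t + w_t < nxt:
            t_star = t + w_t
            break
        t = nxt
    cand = np.flatnonzero((lo <= t_star) & (hi > t_star))
    pick = int(cand[rng.integers(len(cand))])
    child = edge_child[pick]
    if child == -1:  # re-coalesced with its own former edge: tree unchanged
        return parent, time
    new_parent = parent.copy()
    new_time = time.copy()
    # splice out p_old
    new_parent[s] = gp
    # reuse node index p_old as the new coalescence
    new_time[p_old] = t_star
    gpc = int(parent[child]) if child != s else gp
    new_parent[p_old] = gpc if gpc >= 0 else -1
    new_parent[child] = p_old
    new_parent[v] = p_old
    return new_parent, new_time


def _sim_chromosome(n_hap: int, Ne: float, bp: float, mu: float, r: float,
                    rng: np.random.Generator):
    """Simulate one chromosome; returns (site positions in bp, (n_hap, S) alleles)."""
    parent, time = _initial_tree(n_hap, rng)
    x = 0.0
    positions: list[float] = []
    carriers: list[np.ndarray] = []
    while True:
        is_edge = parent >= 0
        blen = np.where(is_edge, time[parent] - time, 0.0)
        tot = blen.sum()
        rec_rate_bp = tot * 2.0 * Ne * r
        dist = rng.exponential(1.0 / rec_rate_bp) if rec_rate_bp > 0 else math.inf
        seg_end = min(bp, x + dist)
        mut_mean = tot * 2.0 * Ne * mu * (seg_end - x)
        n_mut = rng.poisson(mut_mean) if mut_mean > 0 else 0
        if n_mut:
            branches = rng.choice(len(parent), size=n_mut, p=blen / tot)
            pos = np.sort(rng.uniform(x, seg_end, size=n_mut))
            for b, ppos in zip(branches, pos):
                positions.append(float(ppos))
                carriers.append(_leaves_under(parent, int(b), n_hap))
        if seg_end >= bp:
            break
        x = seg_end
        parent, time = _smc_transition(parent, time, n_hap, rng)
    if not positions:
        return np.empty(0), np.empty((n_hap, 0), dtype=np.uint8)
    order = np.argsort(positions, kind="stable")
    pos = np.asarray(positions)[order]
    geno = np.stack([carriers[i] for i in order], axis=1).astype(np.uint8)
    return pos, geno


def run_coalescent(config: FounderConfig) -> tuple[HaploSet, GeneticMap]:
    """Simulate founder haplotypes under the neutral Markovian coalescent.

    Per chromosome the genealogy is simulated along the sequence (SMC'-style
    transitions), mutations are dropped on branches, and the resulting
    segregating sites are thinned uniformly at random (order preserved) to
    exactly ``config.seg_sites``.  Map positions of retained sites are the
    physical position scaled by the recombination rate (Morgans); the map
    length is ``rec_rate * bp`` per chromosome with the centromere at the
    midpoint.

    With ``inbred=True``, ``n_ind`` haplotypes are simulated and duplicated
    ``ploidy`` times per individual, giving fully homozygous founders.
    """
    rng = np.random.default_rng(config.seed)
    n_hap = config.n_ind if config.inbred else config.n_ind * config.ploidy
    if n_hap < 2:
        raise ValueError("need at least two distinct haplotypes to have "
                         "segregating sites")
    chrom_alleles, chrom_maps = [], []
    for c in range(config.n_chr):
        pos_bp, geno = _sim_chromosome(
            n_hap, config.Ne, config.bp, config.mut_rate, config.rec_rate, rng
        )
        n_sites = geno.shape[1]
        if n_sites < config.seg_sites:
            raise ValueError(
                f"chromosome {c + 1}: only {n_sites} segregating sites were "
                f"produced but {config.seg_sites} were requested "
                f"({config.seg_sites - n_sites} short); increase mut_rate, "
                f"bp, or Ne"
            )
        keep = np.sort(rng.choice(n_sites, size=config.seg_sites, replace=False))
        pos_m = pos_bp[keep] * config.rec_rate
        geno = geno[:, keep]
        if config.inbred:
            arr = np.repeat(geno[:, np.newaxis, :], config.ploidy, axis=1)
        else:
            arr = geno.reshape(config.n_ind, config.ploidy, config.seg_sites)
        chrom_alleles.append(arr)
        chrom_maps.append(ChromMap(pos_m, length=config.rec_rate * config.bp))
    return HaploSet.from_alleles(chrom_alleles), GeneticMap(chrom_maps)


# ---------------------------------------------------------------------------
# random founders
# ---------------------------------------------------------------------------

def quick_haplo(n_ind: int, n_chr: int, seg_sites: int, ploidy: int = 2,
                inbred: bool = False,
                seed: Optional[int | np.random.Generator] = None
                ) -> tuple[HaploSet, GeneticMap]:
    """Random founder haplotypes: i.i.d. alleles at frequency 0.5.

    Loci are equally spaced on a 1-Morgan chromosome.  Columns that come out
    monomorphic are redrawn so every locus segregates in the founder set.
    """
    if min(n_ind, n_chr, seg_sites) < 1:
        raise ValueError("counts must be >= 1")
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_hap = n_ind if inbred else n_ind * ploidy
    if n_hap < 2:
        raise ValueError("need at least two distinct haplotypes for "
                         "segregating loci")
    chrom_alleles, chrom_maps = [], []
    for _ in range(n_chr):
        geno = rng.integers(0, 2, size=(n_hap, seg_sites), dtype=np.uint8)
        for _ in range(64):
            mono = (geno.min(axis=0) == geno.max(axis=0))
            if not mono.any():
                break
            geno[:, mono] = rng.integers(0, 2, size=(n_hap, int(mono.sum())),
                                         dtype=np.uint8)
        else:  # pragma: no cover - astronomically unlikely for n_hap >= 2
            raise RuntimeError("failed to produce segregating loci")
        if inbred:
            arr = np.repeat(geno[:, np.newaxis, :], ploidy, axis=1)
        else:
            arr = geno.reshape(n_ind, ploidy, seg_sites)
        chrom_alleles.append(arr)
        pos = np.linspace(0.0, 1.0, seg_sites) if seg_sites > 1 else np.array([0.5])
        chrom_maps.append(ChromMap(pos, length=1.0))
    return HaploSet.from_alleles(chrom_alleles), GeneticMap(chrom_maps)


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------

MAP_COLUMNS = ["chrom", "id", "pos_morgan"]


def write_map(gmap: GeneticMap, path: str) -> None:
    """Write the genetic map as tab-delimited text (chrom, id, pos_morgan)."""
    rows = []
    for c, cm in enumerate(gmap):
        ids = gmap.locus_ids(c)
        for i in range(cm.n_loci):
            rows.append((f"chr{c + 1}", ids[i], cm.positions[i]))
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"map file is missing required columns: {missing}")
    return df


def export_haplotypes(haplo: HaploSet, gmap: GeneticMap, vcf_path: str,
                      map_path: Optional[str] = None,
                      sample_ids: Optional[Sequence[str]] = None) -> None:
    """Write phased haplotypes as VCF 4.2 (GT with '|') plus a map file.

    VCF POS is the 1-based locus ordinal; the genetic positions in Morgans
    live in the companion map file, keyed by the ID column.
    """
    if sample_ids is None:
        sample_ids = [f"ind{i + 1}" for i in range(haplo.n_ind)]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedsim\n")
        for c in range(haplo.n_chr):
            fh.write(f"##contig=<ID=chr{c + 1},length={haplo.n_loci[c] + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for c in range(haplo.n_chr):
            alle = haplo.alleles(c)
            ids = gmap.locus_ids(c)
            for i in range(haplo.n_loci[c]):
                gts = "\t".join(
                    "|".join(str(int(a)) for a in alle[ind, :, i])
                    for ind in range(haplo.n_ind)
                )
                fh.write(f"chr{c + 1}\t{i + 1}\t{ids[i]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
    if map_path is not None:
        write_map(gmap, map_path)


def import_haplotypes(vcf_path: str, map_path: str, ploidy: int = 2
                      ) -> tuple[HaploSet, GeneticMap]:
    """Load phased haplotypes from a VCF plus a Morgan-scale map file.

    Every VCF site must be biallelic, phased, of the requested ploidy, and
    present in the map file (matched on the ID column).  The import is
    lossless: exporting a haplotype set and importing it back reproduces it
    exactly.
    """
    import pysam

    map_df = read_map(map_path)
    map_pos = dict(zip(map_df["id"].astype(str), map_df["pos_morgan"]))

    vcf = pysam.VariantFile(vcf_path)
    samples = list(vcf.header.samples)
    per_chrom: dict[str, list[tuple[str, np.ndarray]]] = {}
    chrom_order: list[str] = []
    missing_sites: list[str] = []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"site {rec.id or rec.pos} is not biallelic")
        row = np.empty((len(samples), ploidy), dtype=np.uint8)
        for j, s in enumerate(samples):
            sample = rec.samples[s]
            gt = sample["GT"]
            if gt is None or any(a is None for a in gt):
                raise ValueError(f"missing genotype at site {rec.id} sample {s}")
            if len(gt) != ploidy:
                raise ValueError(
                    f"site {rec.id} sample {s}: ploidy {len(gt)} does not "
                    f"match requested ploidy {ploidy}"
                )
            if not sample.phased:
                raise ValueError(
                    f"unphased genotype at site {rec.id} sample {s}; phased "
                    "('|') genotypes are required"
                )
            row[j] = gt
        sid = str(rec.id)
        if sid not in map_pos:
            missing_sites.append(sid)
            continue
        if rec.chrom not in per_chrom:
            per_chrom[rec.chrom] = []
            chrom_order.append(rec.chrom)
        per_chrom[rec.chrom].append((sid, row))
    if missing_sites:
        raise ValueError(
            "map file does not cover these VCF sites: "
            + ", ".join(missing_sites[:20])
            + ("..." if len(missing_sites) > 20 else "")
        )
    if not chrom_order:
        raise ValueError("VCF contains no sites")
    chrom_alleles, chrom_maps = [], []
    for chrom in chrom_order:
        sites = per_chrom[chrom]
        ids = np.array([sid for sid, _ in sites])
        pos = np.array([map_pos[sid] for sid, _ in sites], dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"map positions are not sorted along {chrom}")
        arr = np.stack([row for _, row in sites], axis=2)  # (n_ind, ploidy, L)
        chrom_alleles.append(arr)
        length = float(pos[-1]) if len(pos) else 0.0
        chrom_maps.append(ChromMap(pos, length=max(length, 0.0), ids=ids))
    return HaploSet.from_alleles(chrom_alleles), GeneticMap(chrom_maps)
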