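"""Synthetic livestock cohorts: pedigree simulation and gene dropping.

The generator produces the two coupled inputs the analysis stack expects:
a multi-generation pedigree with (optionally) incomplete parentage
records, and diploid SNP genotypes obtained by dropping founder
haplotypes down the true pedigree with recombination, so that pedigree
autozygosity is realised as observable runs of homozygosity.  The default
map mimics a medium-density ovine chip: 26 autosomes with SNP counts
proportional to chromosome rank, ~40k SNPs in total at ~66 kb spacing
(~2.6 Gb of coverage).

Every stochastic draw flows from the single seed in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import GenotypeDataset, Pedigree, PedigreeRecord, SnpMap

__all__ = [
    "MapSpec",
    "SimConfig",
    "SimOutput",
    "make_even_map",
    "simulate_pedigree",
    "erase_parent_records",
    "gene_drop",
    "simulate_cohort",
]

DEFAULT_TOTAL_SNPS = 40_753  # medium-density autosomal chip after QC
DEFAULT_SPACING_KB = 66.0


@dataclass(frozen=True)
class MapSpec:
    """SNP map geometry.

    ``snps_per_chromosome`` may be an explicit per-chromosome list; by
    default ``total_snps`` markers are split across chromosomes with
    counts proportional to (n_chromosomes + 1 - k), approximating the
    decreasing autosome lengths of a real karyotype.  ``jitter_kb`` > 0
    perturbs the inter-SNP gaps uniformly by up to that amount.
    """

    n_chromosomes: int = 26
    total_snps: int = DEFAULT_TOTAL_SNPS
    snps_per_chromosome: tuple[int, ...] | None = None
    spacing_kb: float = DEFAULT_SPACING_KB
    jitter_kb: float = 0.0

    def counts(self) -> np.ndarray:
        if self.snps_per_chromosome is not None:
            counts = np.asarray(self.snps_per_chromosome, dtype=np.int64)
            if counts.size != self.n_chromosomes:
                raise ValueError("snps_per_chromosome length mismatch")
            return counts
        w = np.arange(self.n_chromosomes, 0, -1, dtype=float)
        w /= w.sum()
        counts = np.maximum(2, np.round(w * self.total_snps).astype(np.int64))
        return counts


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate a small monitored flock: a handful of founders,
    three discrete generations with random mating inside the flock (so
    related matings occur by drift), a final cohort of 46 genotyped
    individuals, founder allele frequencies uniform on [0.05, 0.5] (a
    post-QC-like spectrum) and Haldane (no-interference) recombination at
    1 cM/Mb.
    """

    n_founders: int = 12
    n_generations: int = 3
    offspring_per_generation: int = 46
    mating: str = "random"  # {random, circular, bottleneck}
    n_bottleneck_sires: int = 2
    record_loss: float = 0.0
    map: MapSpec = field(default_factory=MapSpec)
    founder_maf: tuple[float, float] = (0.05, 0.5)
    base_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.offspring_per_generation < 1 or self.n_generations < 1:
            raise ValueError("population sizes must be positive (>= 2 founders)")
        if not 0.0 <= self.record_loss <= 1.0:
            raise ValueError("record_loss must be a probability")
        if self.mating not in ("random", "circular", "bottleneck"):
            raise ValueError(f"unknown mating scheme {self.mating!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def make_even_map(config: SimConfig) -> SnpMap:
    """Build the chip map described by ``config.map``."""
    spec = config.map
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    counts = spec.counts()
    ids, chroms, poss = [], [], []
    spacing_bp = spec.spacing_kb * 1000.0
    for c, n in enumerate(counts, start=1):
        if spec.jitter_kb > 0:
            gaps = spacing_bp + rng.uniform(-spec.jitter_kb, spec.jitter_kb, size=n - 1) * 1000.0
            gaps = np.maximum(1.0, gaps)
            pos = np.concatenate([[1.0], 1.0 + np.cumsum(gaps)])
            pos = np.round(pos).astype(np.int64)
            pos = np.maximum.accumulate(pos + np.arange(n))  # enforce strict increase
        else:
            pos = (1 + np.round(np.arange(n) * spacing_bp)).astype(np.int64)
        ids.extend(f"chr{c}_snp{j + 1}" for j in range(n))
        chroms.extend([c] * int(n))
        poss.extend(pos.tolist())
    return SnpMap.from_arrays(ids, chroms, poss)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Simulate a discrete-generation pedigree (complete parentage).

    Founders form generation 0; each later generation holds
    ``offspring_per_generation`` individuals whose parents are drawn from
    the previous generation according to the mating scheme (``bottleneck``
    funnels all matings through ``n_bottleneck_sires`` sires).  Sexes are
    assigned so both are always present; birth years are
    ``base_year + generation + uniform{0,1,2}`` (overlapping generations).

    Use :func:`erase_parent_records` to impose record loss afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    recs: list[PedigreeRecord] = []

    def make_gen(g: int, n: int) -> list[tuple[str, str]]:
        out = []
        # alternate sexes then shuffle, so neither sex ever goes extinct
        sexes = ["male", "female"] * (n // 2 + 1)
        sexes = sexes[:n]
        rng.shuffle(sexes)
        for i in range(n):
            out.append((f"G{g}I{i + 1}", sexes[i]))
        return out

    gen = make_gen(0, config.n_founders)
    for iid, sex in gen:
        year = config.base_year + int(rng.integers(0, 3))
        recs.append(PedigreeRecord(iid, None, None, sex, year))
    for g in range(1, config.n_generations + 1):
        males = [i for i, s in gen if s == "male"]
        females = [i for i, s in gen if s == "female"]
        if not males or not females:
            raise RuntimeError("a sex went extinct; increase population size")
        if config.mating == "bottleneck":
            males = males[: max(1, config.n_bottleneck_sires)]
        nxt = make_gen(g, config.offspring_per_generation)
        for i, (iid, sex) in enumerate(nxt):
            if config.mating == "circular":
                sire = males[i % len(males)]
                dam = females[i % len(females)]
            else:
                sire = males[int(rng.integers(len(males)))]
                dam = females[int(rng.integers(len(females)))]
            year = config.base_year + g + int(rng.integers(0, 3))
            recs.append(PedigreeRecord(iid, sire, dam, sex, year))
        gen = nxt
    return Pedigree(recs)


def erase_parent_records(
    pedigree: Pedigree, record_loss: float, rng: np.random.Generator
) -> Pedigree:
    """Independently erase each parent link with probability ``record_loss``,
    producing the incomplete 'observed' pedigree real herdbooks resemble."""
    recs = []
    for iid in pedigree.ids:
        r = pedigree.record(iid)
        sire = r.sire_id if (r.sire_id is not None and rng.random() >= record_loss) else None
        dam = r.dam_id if (r.dam_id is not None and rng.random() >= record_loss) else None
        recs.append(PedigreeRecord(iid, sire, dam, r.sex, r.birth_year))
    return Pedigree(recs)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


class _Haplotype:
    """Founder-label mosaic along one chromosome: ``ends[i]`` is the last bp
    (inclusive) of segment i carrying founder-haplotype ``labels[i]``."""

    __slots__ = ("ends", "labels")

    def __init__(self, ends: np.ndarray, labels: np.ndarray):
        self.ends = ends
        self.labels = labels

    @classmethod
    def founder(cls, label: int, chrom_end: int) -> "_Haplotype":
        return cls(np.array([chrom_end], dtype=np.int64), np.array([label], dtype=np.int64))

    def labels_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.ends, positions)
        return self.labels[idx]


def _meiosis(h0: _Haplotype, h1: _Haplotype, chrom_start: int, chrom_end: int,
             rng: np.random.Generator) -> _Haplotype:
    """One gamete: Poisson crossovers at 1 cM/Mb, uniform placement, no
    interference; random starting phase."""
    length_morgan = (chrom_end - chrom_start) / 1e8  # 1 Mb = 1 cM
    n_x = rng.poisson(length_morgan)
    cuts = np.sort(rng.integers(chrom_start, chrom_end, size=n_x)) if n_x else np.empty(0, np.int64)
    phase = int(rng.integers(2))
    ends: list[int] = []
    labels: list[int] = []
    seg_start = chrom_start
    sources = (h0, h1)
    for cut in list(cuts) + [chrom_end]:
        if cut < seg_start:  # duplicate cut position
            phase ^= 1
            continue
        src = sources[phase]
        i = int(np.searchsorted(src.ends, seg_start))
        while i < len(src.ends) and src.ends[i] < cut:
            ends.append(int(src.ends[i]))
            labels.append(int(src.labels[i]))
            i += 1
        ends.append(int(cut))
        labels.append(int(src.labels[min(i, len(src.labels) - 1)]))
        seg_start = cut + 1
        phase ^= 1
    # merge adjacent segments with identical labels
    m_ends, m_labels = [], []
    for e, l in zip(ends, labels):
        if m_labels and m_labels[-1] == l:
            m_ends[-1] = e
        else:
            m_ends.append(e)
            m_labels.append(l)
    return _Haplotype(np.asarray(m_ends, np.int64), np.asarray(m_labels, np.int64))


def _ibd_segments(h0: _Haplotype, h1: _Haplotype, chrom_start: int) -> list[tuple[int, int]]:
    """Maximal intervals where the two haplotypes carry the same founder label."""
    bounds = np.union1d(h0.ends, h1.ends)
    segs: list[tuple[int, int]] = []
    start = chrom_start
    for e in bounds:
        l0 = h0.labels[np.searchsorted(h0.ends, start)]
        l1 = h1.labels[np.searchsorted(h1.ends, start)]
        if l0 == l1:
            if segs and segs[-1][1] == start - 1:
                segs[-1] = (segs[-1][0], int(e))
            else:
                segs.append((start, int(e)))
        start = int(e) + 1
    return segs


@dataclass
class SimOutput:
    """Gene-dropped cohort: observed (possibly record-lossy) pedigree, the
    complete true pedigree, genotypes, and the simulation truth."""

    pedigree: Pedigree
    pedigree_true: Pedigree
    genotypes: GenotypeDataset
    true_ibd_fraction: pd.Series
    true_ibd_segments: pd.DataFrame
    config: SimConfig


def gene_drop(
    pedigree: Pedigree,
    config: SimConfig,
    snp_map: SnpMap | None = None,
    genotype_individuals: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> SimOutput:
    """Drop founder haplotypes down ``pedigree`` with recombination.

    Each founder carries two uniquely labelled haplotypes whose alleles
    are drawn per SNP from the founder MAF distribution.  Every meiosis
    recombines the parent's haplotype pair; genotypes are emitted for
    ``genotype_individuals`` (default: all individuals).  True IBD
    segments (both haplotype labels identical) and the per-individual IBD
    fraction of the map coverage are recorded for every genotyped
    individual.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 3]))
    if snp_map is None:
        snp_map = make_even_map(config)
    ids = pedigree.ids
    if genotype_individuals is None:
        genotype_individuals = list(ids)
    geno_set = set(genotype_individuals)

    chroms = [int(c) for c in snp_map.chromosome_list()]
    chrom_bounds = {}
    chrom_slices = {}
    for c in chroms:
        sl = snp_map.chromosome_slice(c)
        pos = snp_map.positions_bp[sl]
        chrom_bounds[c] = (int(pos[0]), int(pos[-1]))
        chrom_slices[c] = sl

    founders = pedigree.founders()
    n_f = len(founders)
    founder_label = {f: 2 * k for k, f in enumerate(founders)}  # labels 2k, 2k+1

    # founder haplotype alleles: (2 n_f) x n_snps, allele freq per SNP
    p = rng.uniform(config.founder_maf[0], config.founder_maf[1], size=snp_map.n_snps)
    founder_alleles = (rng.random((2 * n_f, snp_map.n_snps)) < p).astype(np.int8)

    # drop haplotypes generation by generation (topological order)
    haps: dict[str, dict[int, tuple[_Haplotype, _Haplotype]]] = {}
    for iid in ids:
        s, d = pedigree.parents(iid)
        haps[iid] = {}
        for c in chroms:
            start, end = chrom_bounds[c]
            if s is None and d is None:
                lab = founder_label[iid]
                haps[iid][c] = (
                    _Haplotype.founder(lab, end),
                    _Haplotype.founder(lab + 1, end),
                )
            elif s is None or d is None:
                raise ValueError(
                    "gene_drop needs a complete pedigree (apply record loss only "
                    f"to the observed copy); {iid!r} has one unknown parent"
                )
            else:
                hs = _meiosis(*haps[s][c], start, end, rng)
                hd = _meiosis(*haps[d][c], start, end, rng)
                haps[iid][c] = (hs, hd)

    # realise genotypes and truth for the requested individuals
    calls = np.empty((len(genotype_individuals), snp_map.n_snps), dtype=np.int8)
    ibd_fraction = {}
    seg_rows = []
    l_auto_bp = sum(e - s + 1 for s, e in chrom_bounds.values())
    for i, iid in enumerate(genotype_individuals):
        ibd_bp = 0
        for c in chroms:
            sl = chrom_slices[c]
            pos = snp_map.positions_bp[sl]
            h0, h1 = haps[iid][c]
            lab0 = h0.labels_at(pos)
            lab1 = h1.labels_at(pos)
            calls[i, sl] = founder_alleles[lab0, np.arange(sl.start, sl.stop)] + \
                founder_alleles[lab1, np.arange(sl.start, sl.stop)]
            for a, b in _ibd_segments(h0, h1, chrom_bounds[c][0]):
                ibd_bp += b - a + 1
                seg_rows.append(
                    {"individual_id": iid, "chromosome": c, "start_bp": a, "end_bp": b,
                     "length_kb": (b - a + 1) / 1000.0}
                )
        ibd_fraction[iid] = ibd_bp / l_auto_bp

    genotypes = GenotypeDataset(snp_map, list(genotype_individuals), calls)
    truth_frac = pd.Series(ibd_fraction, name="true_ibd_fraction")
    truth_segs = pd.DataFrame(
        seg_rows, columns=["individual_id", "chromosome", "start_bp", "end_bp", "length_kb"]
    )
    observed = pedigree
    return SimOutput(observed, pedigree, genotypes, truth_frac, truth_segs, config)


def simulate_cohort(config: SimConfig, genotype_last_generation_only: bool = True) -> SimOutput:
    """Pedigree simulation + gene dropping in one seeded call.

    Genotypes (and truth) are emitted for the last generation only by
    default — the 'genotyped cohort' — while the returned observed
    pedigree has parent links erased with probability ``record_loss``.
    """
    ped_true = simulate_pedigree(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 4]))
    cohort = None
    if genotype_last_generation_only:
        last = f"G{config.n_generations}I"
        cohort = [i for i in ped_true.ids if i.startswith(last)]
    out = gene_drop(ped_true, config, genotype_individuals=cohort)
    observed = erase_parent_records(ped_true, config.record_loss, rng) \
        if config.record_loss > 0 else ped_true
    return SimOutput(observed, ped_true, out.genotypes, out.true_ibd_fraction,
                     out.true_ibd_segments, config)
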