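"""Sliding-window runs-of-homozygosity detection and ROH-based inbreeding.

Detection mirrors the de-facto standard SNP-chip procedure: a window of
``window_snps`` consecutive SNPs is scanned along each chromosome and
called homozygous when it contains at most ``max_het_in_window``
heterozygous and ``max_missing_in_window`` missing calls; a SNP whose
proportion of homozygous overlapping windows exceeds
``window_hit_threshold`` is a candidate run member; maximal candidate
stretches are split at large inter-SNP gaps and filtered on SNP count,
length and SNP density.

Four inbreeding measures are derived from the detected segments: F_ROH_L
(total ROH length over autosomal coverage L_AUTO), F_ROH_N (SNPs in ROH
over total SNP count), and the chromosomal partitions F_ROH_KK (per
chromosome, relative to that chromosome's coverage) and F_ROH_KA (per
chromosome, relative to L_AUTO; sums over chromosomes exactly to F_ROH_L).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeDataset, SnpMap

logger = logging.getLogger(__name__)

__all__ = [
    "RohParams",
    "RohSegment",
    "detect_roh",
    "segments_frame",
    "froh_length",
    "froh_nsnp",
    "froh_chromosomal",
    "rank_chromosomes",
    "compare_inbreeding_measures",
]


@dataclass(frozen=True)
class RohParams:
    """ROH detection parameters.

    Defaults reproduce the standard 50-SNP sliding-window settings for
    medium-density chips: one heterozygous and two missing calls allowed
    per window, at least 1 SNP per 100 kb, gaps above 1 Mb split runs,
    and accepted runs must span >= 100 SNPs and >= 1 Mb.
    """

    window_snps: int = 50
    max_het_in_window: int = 1
    max_missing_in_window: int = 2
    min_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 1000.0
    min_run_snps: int = 100
    min_run_kb: float = 1000.0
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_run_snps < 1:
            raise ValueError("window_snps and min_run_snps must be positive")
        for name in ("max_het_in_window", "max_missing_in_window", "min_density_kb_per_snp",
                     "max_gap_kb", "min_run_kb", "window_hit_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run: 1-based inclusive bp coordinates of its bounding
    SNPs; ``n_snps`` counts the non-missing SNPs inside the run."""

    individual_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


def _candidate_snps(geno: np.ndarray, params: RohParams) -> np.ndarray:
    """Boolean candidate mask for one individual on one chromosome.

    ``geno``: calls (0/1/2/MISSING) at the chromosome's SNPs in map order.
    Windows are truncated when the chromosome has fewer SNPs than
    ``window_snps``.
    """
    n = geno.size
    w = min(params.window_snps, n)
    het = (geno == 1).astype(np.int32)
    mis = (geno == MISSING).astype(np.int32)
    # rolling window sums over w consecutive SNPs
    kern = np.ones(w, dtype=np.int32)
    het_w = np.convolve(het, kern, mode="valid")
    mis_w = np.convolve(mis, kern, mode="valid")
    ok = (het_w <= params.max_het_in_window) & (mis_w <= params.max_missing_in_window)
    # per SNP: fraction of overlapping windows that are homozygous.
    # window j covers SNPs j..j+w-1; SNP i is covered by windows
    # max(0, i-w+1) .. min(i, n-w).
    ok_cum = np.concatenate([[0], np.cumsum(ok)])
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n - w)
    n_ok = ok_cum[hi + 1] - ok_cum[lo]
    n_win = hi - lo + 1
    return n_ok > params.window_hit_threshold * n_win


def _stretch_to_segments(
    iid: str,
    chrom: int,
    pos: np.ndarray,
    geno: np.ndarray,
    cand: np.ndarray,
    params: RohParams,
) -> list[RohSegment]:
    """Cut candidate stretches at big gaps and apply run-level filters."""
    segs: list[RohSegment] = []
    n = pos.size
    i = 0
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and cand[j + 1]:
            j += 1
        # split [i, j] at gaps > max_gap_kb
        cut_points = [i]
        for k in range(i, j):
            if (pos[k + 1] - pos[k]) / 1000.0 > params.max_gap_kb:
                cut_points.append(k + 1)
        cut_points.append(j + 1)
        for a, b in zip(cut_points[:-1], cut_points[1:]):
            b -= 1
            length_kb = (pos[b] - pos[a] + 1) / 1000.0
            n_snps = int(np.sum(geno[a : b + 1] != MISSING))
            if n_snps < params.min_run_snps or length_kb < params.min_run_kb:
                continue
            if n_snps > 0 and length_kb / n_snps > params.min_density_kb_per_snp:
                continue
            segs.append(RohSegment(iid, int(chrom), int(pos[a]), int(pos[b]), n_snps))
        i = j + 1
    return segs


def detect_roh(genotypes: GenotypeDataset, params: RohParams | None = None) -> list[RohSegment]:
    """Detect runs of homozygosity for every individual.

    Returns segments sorted by (individual order, chromosome, start);
    deterministic.  Chromosomes with fewer SNPs than the window size are
    scanned with a truncated window (logged).
    """
    params = params or RohParams()
    m = genotypes.snp_map
    segments: list[RohSegment] = []
    for chrom in m.chromosome_list():
        sl = m.chromosome_slice(int(chrom))
        pos = m.positions_bp[sl]
        if pos.size < params.window_snps:
            logger.info("chromosome %s has %d < %d SNPs; truncated window", chrom, pos.size, params.window_snps)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"SNP map not sorted on chromosome {chrom}")
        block = genotypes.calls[:, sl]
        for i, iid in enumerate(genotypes.individual_ids):
            geno = block[i]
            cand = _candidate_snps(geno, params)
            if cand.any():
                segments.extend(_stretch_to_segments(iid, int(chrom), pos, geno, cand, params))
    order = {iid: k for k, iid in enumerate(genotypes.individual_ids)}
    segments.sort(key=lambda s: (order[s.individual_id], s.chromosome, s.start_bp))
    return segments


def segments_frame(segments: list[RohSegment]) -> pd.DataFrame:
    """Segments as a .hom-style table (id, chr, start, end, kb, nsnp)."""
    return pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "chromosome": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "length_kb": s.length_kb,
                "n_snps": s.n_snps,
            }
            for s in segments
        ],
        columns=["individual_id", "chromosome", "start_bp", "end_bp", "length_kb", "n_snps"],
    )


# ---------------------------------------------------------------------------
# Inbreeding measures
# ---------------------------------------------------------------------------


def froh_length(
    segments: list[RohSegment], snp_map: SnpMap, individual_ids: list[str]
) -> pd.Series:
    """F_ROH_L: total ROH length over autosomal SNP coverage L_AUTO."""
    l_auto = snp_map.l_auto_kb
    if l_auto <= 0:
        raise ValueError("map has no coverage (L_AUTO = 0)")
    tot = pd.Series(0.0, index=pd.Index(individual_ids, name="individual_id"))
    for s in segments:
        tot[s.individual_id] += s.length_kb
    return (tot / l_auto).rename("F_ROH_L")


def froh_nsnp(
    segments: list[RohSegment], snp_map: SnpMap, individual_ids: list[str]
) -> pd.Series:
    """F_ROH_N: number of SNPs inside ROH over the total autosomal SNP count."""
    tot = pd.Series(0, index=pd.Index(individual_ids, name="individual_id"), dtype=float)
    for s in segments:
        tot[s.individual_id] += s.n_snps
    return (tot / snp_map.n_snps).rename("F_ROH_N")


def froh_chromosomal(
    segments: list[RohSegment], snp_map: SnpMap, individual_ids: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-chromosome partitions of ROH inbreeding.

    Returns ``(F_ROH_KK, F_ROH_KA, mean_KK)`` where the frames are
    individuals x chromosomes: F_ROH_KK divides each chromosome's ROH
    length by that chromosome's coverage, F_ROH_KA divides it by L_AUTO
    (so row sums of F_ROH_KA equal F_ROH_L exactly), and ``mean_KK`` is
    the unweighted mean of F_ROH_KK over all autosomes per individual.
    """
    chroms = [int(c) for c in snp_map.chromosome_list()]
    cov = np.array([snp_map.coverage_kb(c) for c in chroms])
    l_auto = snp_map.l_auto_kb
    idx = pd.Index(individual_ids, name="individual_id")
    lengths = pd.DataFrame(0.0, index=idx, columns=chroms)
    for s in segments:
        lengths.loc[s.individual_id, s.chromosome] += s.length_kb
    with np.errstate(divide="ignore", invalid="ignore"):
        kk = lengths / cov
    kk = kk.fillna(0.0)
    ka = lengths / l_auto
    mean_kk = kk.mean(axis=1).rename("mean_F_ROH_KK")
    return kk, ka, mean_kk


def rank_chromosomes(kk: pd.DataFrame, ka: pd.DataFrame) -> pd.DataFrame:
    """Rank chromosomes by population-mean inbreeding burden.

    Ranks separately under F_ROH_KA and F_ROH_KK (ties broken by ascending
    chromosome number) and reports, for the F_ROH_KA ranking, the
    cumulative percentage of total inbreeding carried by the top-ranked
    chromosomes.
    """
    mean_ka = ka.mean(axis=0)
    mean_kk = kk.mean(axis=0)
    order_ka = sorted(mean_ka.index, key=lambda c: (-mean_ka[c], c))
    order_kk = sorted(mean_kk.index, key=lambda c: (-mean_kk[c], c))
    total = mean_ka.sum()
    cum = []
    run = 0.0
    for c in order_ka:
        run += mean_ka[c]
        cum.append(100.0 * run / total if total > 0 else 0.0)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order_ka) + 1),
            "chromosome_by_KA": order_ka,
            "mean_F_ROH_KA": [mean_ka[c] for c in order_ka],
            "cumulative_pct_KA": cum,
            "chromosome_by_KK": order_kk,
            "mean_F_ROH_KK": [mean_kk[c] for c in order_kk],
        }
    )


def compare_inbreeding_measures(table: pd.DataFrame, baseline: str = "F_PED") -> dict:
    """Pairwise Pearson correlations and regressions on the baseline measure.

    ``table``: individuals x measures (e.g. F_PED, F_ROH_L, F_ROH_N,
    mean_F_ROH_KK).  Returns the full correlation matrix and, for every
    non-baseline column, the OLS slope/intercept of that measure on the
    baseline.  Zero-variance columns yield NaN correlations and a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 individuals")
    zero_var = [c for c in table.columns if np.isclose(table[c].std(ddof=0), 0.0)]
    if zero_var:
        warnings.warn(f"zero variance in columns {zero_var}; correlations undefined")
    corr = table.corr(method="pearson")
    regressions = {}
    if baseline in table.columns and baseline not in zero_var:
        x = table[baseline].to_numpy(float)
        for c in table.columns:
            if c == baseline:
                continue
            slope, intercept, r, p, se = stats.linregress(x, table[c].to_numpy(float))
            regressions[c] = {"slope": slope, "intercept": intercept, "r": r, "p": p}
    return {"correlations": corr, "regressions": regressions}
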