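"""Recent effective population size from the decay of linkage disequilibrium.

Pairwise composite r² between intra-chromosomal SNPs is binned by physical
distance; each bin's mean distance maps to a recombination rate c (linear
1 cM/Mb by default, Haldane optional), which dates the bin to
t = 1/(2c) generations ago, and the bin's sample-size-adjusted mean r²
yields the effective size at that time:

    N(t) = (1 / (4 c)) * (1 / E[r²_adj] - alpha)

with alpha a correction for mutation (1 by default, i.e. none).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = ["LdBin", "NeTrajectory", "pairwise_r2", "map_distance_to_c", "estimate_ne_trajectory"]


@dataclass(frozen=True)
class LdBin:
    dist_lo_kb: float
    dist_hi_kb: float
    mean_dist_kb: float
    c: float  # Morgans
    t: float  # generations ago
    mean_r2_adj: float
    n_pairs: int
    ne: float
    valid: bool


@dataclass
class NeTrajectory:
    """Ordered (most recent first is NOT guaranteed; bins ascend in
    distance, so ``t`` descends) list of LD bins with provenance."""

    bins: list[LdBin]
    params: dict

    def valid_bins(self) -> list[LdBin]:
        return [b for b in self.bins if b.valid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t": b.t,
                    "Ne": b.ne,
                    "c": b.c,
                    "mean_dist_kb": b.mean_dist_kb,
                    "mean_r2_adj": b.mean_r2_adj,
                    "n_pairs": b.n_pairs,
                    "valid": b.valid,
                }
                for b in self.bins
            ]
        )


def pairwise_r2(
    genotypes: GenotypeDataset,
    max_distance_kb: float = 10_000.0,
    min_maf: float = 0.0,
) -> pd.DataFrame:
    """Composite r² for all intra-chromosomal SNP pairs within a distance cap.

    r² is the squared Pearson correlation of unphased genotype dosages
    over pairwise-complete individuals.  SNPs failing ``min_maf`` and
    pairs where either SNP is monomorphic among the shared individuals
    are skipped.  Returns a frame (distance_kb, r2, n).
    """
    m = genotypes.snp_map
    calls = genotypes.calls
    obs = (calls != MISSING)
    x = np.where(obs, calls, 0).astype(np.float64)
    xsq = x * x
    mask = obs.astype(np.float64)

    # MAF filter up front
    n_obs = mask.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = x.sum(axis=0) / (2 * n_obs)
    maf = np.minimum(freq, 1 - freq)
    usable = np.nan_to_num(maf, nan=-1) >= min_maf

    out_d, out_r2, out_n = [], [], []
    n_skipped = 0
    for chrom in m.chromosome_list():
        sl = m.chromosome_slice(int(chrom))
        pos = m.positions_bp[sl].astype(np.float64)
        use = usable[sl]
        X, X2, Mk = x[:, sl], xsq[:, sl], mask[:, sl]
        n_snp = pos.size
        # vectorise over pair offset: columns j and j+k
        for k in range(1, n_snp):
            d = (pos[k:] - pos[:-k]) / 1000.0
            sel = (d <= max_distance_kb) & use[:-k] & use[k:]
            if not sel.any():
                if np.all((pos[k:] - pos[:-k]) / 1000.0 > max_distance_kb):
                    break
                continue
            a_idx = np.flatnonzero(sel)
            b_idx = a_idx + k
            A, B = X[:, a_idx], X[:, b_idx]
            MA, MB = Mk[:, a_idx], Mk[:, b_idx]
            both = MA * MB
            n = both.sum(axis=0)
            sa = (A * both).sum(axis=0)
            sb = (B * both).sum(axis=0)
            saa = (X2[:, a_idx] * both).sum(axis=0)
            sbb = (X2[:, b_idx] * both).sum(axis=0)
            sab = (A * B * both).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                cov = sab - sa * sb / n
                va = saa - sa * sa / n
                vb = sbb - sb * sb / n
                r2 = (cov * cov) / (va * vb)
            good = (n >= 2) & (va > 0) & (vb > 0)
            n_skipped += int((~good).sum())
            out_d.append(d[sel][good])
            out_r2.append(r2[good])
            out_n.append(n[good])
    if n_skipped:
        logger.info("skipped %d pairs with a monomorphic member", n_skipped)
    if not out_d:
        return pd.DataFrame(columns=["distance_kb", "r2", "n"])
    return pd.DataFrame(
        {
            "distance_kb": np.concatenate(out_d),
            "r2": np.concatenate(out_r2),
            "n": np.concatenate(out_n).astype(int),
        }
    )


def map_distance_to_c(d_kb, mapping: str = "linear") -> np.ndarray | float:
    """Physical distance (kb) to recombination rate c in Morgans.

    ``linear``: 1 Mb = 1 cM, i.e. c = d_kb * 1e-5, capped at 0.5 (so the
    10 Mb pair cap corresponds to t = 1/(2c) = 5 generations).
    ``haldane``: c = 0.5 (1 - exp(-2 d_M)) with d_M the linear map length
    in Morgans.
    """
    d = np.asarray(d_kb, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    d_morgan = d * 1e-5
    if mapping == "linear":
        c = np.minimum(d_morgan, 0.5)
    elif mapping == "haldane":
        c = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return float(c) if np.isscalar(d_kb) else c


def estimate_ne_trajectory(
    pairs: pd.DataFrame,
    n_individuals: int,
    bins: int = 30,
    alpha: float = 1.0,
    max_distance_kb: float = 10_000.0,
    mapping: str = "linear",
    sample_size_correction: bool = True,
    haploid_n: bool = True,
    min_pairs_per_bin: int = 50,
) -> NeTrajectory:
    """Effective-size trajectory from binned LD decay.

    Pairs are binned into ``bins`` equal-width distance bins over
    (0, max_distance_kb]; each bin's mean r² is adjusted for chromosome
    sample size (r² - 1/n with n = 2 x individuals by default, or 1/
    individuals with ``haploid_n=False``) and converted to an Ne estimate
    via the recombination rate of the bin's mean distance.  Bins with too
    few pairs are dropped; bins whose adjusted r² implies a non-positive
    Ne are kept but flagged invalid.
    """
    if pairs.empty:
        raise ValueError("no SNP pairs supplied")
    n = 2 * n_individuals if haploid_n else n_individuals
    edges = np.linspace(0.0, max_distance_kb, bins + 1)
    which = np.digitize(pairs["distance_kb"], edges[1:-1], right=True)
    out: list[LdBin] = []
    for b in range(bins):
        sub = pairs[which == b]
        if len(sub) < min_pairs_per_bin:
            if len(sub):
                warnings.warn(f"bin {b} has {len(sub)} < {min_pairs_per_bin} pairs; dropped")
            continue
        mean_d = float(sub["distance_kb"].mean())
        r2 = float(sub["r2"].mean())
        r2_adj = r2 - 1.0 / n if sample_size_correction else r2
        c = float(map_distance_to_c(mean_d, mapping))
        t = 1.0 / (2.0 * c)
        valid = r2_adj > 0 and (1.0 / r2_adj - alpha) > 0
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha) if valid else float("nan")
        out.append(
            LdBin(float(edges[b]), float(edges[b + 1]), mean_d, c, t, r2_adj, len(sub), ne, valid)
        )
    params = {
        "bins": bins,
        "alpha": alpha,
        "max_distance_kb": max_distance_kb,
        "mapping": mapping,
        "sample_size_correction": sample_size_correction,
        "n_individuals": n_individuals,
        "min_pairs_per_bin": min_pairs_per_bin,
    }
    return NeTrajectory(out, params)
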