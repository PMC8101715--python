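"""Genotype quality control and heterozygosity summaries.

QC applies, in order: individual call rate, SNP call rate, minor allele
frequency, and an exact two-sided Hardy-Weinberg test on genotype counts.
LD pruning removes SNPs whose genotype is too predictable from its window
neighbours (variance-inflation-factor rule, the ``--indep`` procedure).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "QcParams",
    "QcReport",
    "HetSummary",
    "hwe_exact_test",
    "allele_frequencies",
    "qc_filter",
    "ld_prune",
    "heterozygosity",
]


@dataclass(frozen=True)
class QcParams:
    """QC thresholds; call-rate and MAF thresholds are inclusive (a SNP at
    exactly the threshold is kept), the HWE p-value floor is exclusive
    (p <= floor removed)."""

    min_call_rate_snp: float = 0.90
    min_call_rate_ind: float = 0.90
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-4
    prune_window: int = 50
    prune_step: int = 5
    prune_vif: float = 2.0

    def __post_init__(self) -> None:
        for name in ("min_call_rate_snp", "min_call_rate_ind", "min_maf"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0 <= self.hwe_p_floor <= 1:
            raise ValueError("hwe_p_floor must be in [0,1]")


@dataclass
class QcReport:
    n_individuals_removed_call_rate: int
    n_snps_removed_call_rate: int
    n_snps_removed_maf: int
    n_snps_removed_hwe: int
    removed_individuals: list[str]
    removed_snps: dict[str, list[str]]


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int, mid_p: bool = False) -> float:
    """Exact two-sided Hardy-Weinberg p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the
    observed table (the standard SNP exact test).  ``mid_p`` counts the
    observed table with half weight.
    """
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het  # rare allele count
    # P(n_het | n, n_rare) up to a constant, built by recurrence to avoid
    # overflow; heterozygote count has the parity of n_rare.
    het_values = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    probs = {}
    h = het_values[0]
    probs[h] = 1.0
    for h2 in het_values[1:]:
        h = h2 - 2
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # P(h+2)/P(h) = 4 * rare_hom * common_hom / ((h+2)*(h+1))
        probs[h2] = probs[h] * 4.0 * rare_hom * common_hom / ((h + 2) * (h + 1))
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    tol = p_obs * (1 + 1e-12)
    p = sum(v / total for v in probs.values() if v / total <= tol)
    if mid_p:
        p -= 0.5 * p_obs
    return min(1.0, p)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def allele_frequencies(genotypes: GenotypeDataset) -> np.ndarray:
    """Frequency of the counted allele per SNP, over non-missing calls."""
    calls = genotypes.calls
    obs = calls != MISSING
    n = obs.sum(axis=0)
    s = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = s / (2.0 * n)
    return np.where(n > 0, p, np.nan)


def qc_filter(
    genotypes: GenotypeDataset, params: QcParams | None = None
) -> tuple[GenotypeDataset, QcReport]:
    """Apply call-rate, MAF and HWE filters; returns the filtered dataset
    and a report of removals per step."""
    params = params or QcParams()
    ds = genotypes

    ind_cr = 1.0 - ds.missing_rate_per_individual()
    keep_ind = ind_cr >= params.min_call_rate_ind
    removed_ind = [i for i, k in zip(ds.individual_ids, keep_ind) if not k]
    if not keep_ind.all():
        ds = ds.subset(individuals=keep_ind)

    snp_cr = 1.0 - ds.missing_rate_per_snp()
    keep_cr = snp_cr >= params.min_call_rate_snp
    removed_cr = list(ds.snp_map.snp_ids[~keep_cr])
    if not keep_cr.all():
        ds = ds.subset(snps=keep_cr)

    p = allele_frequencies(ds)
    maf = np.minimum(p, 1.0 - p)
    keep_maf = np.nan_to_num(maf, nan=-1.0) >= params.min_maf
    removed_maf = list(ds.snp_map.snp_ids[~keep_maf])
    if not keep_maf.all():
        ds = ds.subset(snps=keep_maf)

    pvals = np.empty(ds.n_snps)
    for j in range(ds.n_snps):
        col = ds.calls[:, j]
        pvals[j] = hwe_exact_test(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
    keep_hwe = pvals > params.hwe_p_floor
    removed_hwe = list(ds.snp_map.snp_ids[~keep_hwe])
    if not keep_hwe.all():
        ds = ds.subset(snps=keep_hwe)

    if ds.n_snps == 0 or ds.n_individuals == 0:
        raise ValueError("dataset empty after QC filtering")
    report = QcReport(
        len(removed_ind), len(removed_cr), len(removed_maf), len(removed_hwe),
        removed_ind,
        {"call_rate": removed_cr, "maf": removed_maf, "hwe": removed_hwe},
    )
    return ds, report


# ---------------------------------------------------------------------------
# LD pruning (VIF)
# ---------------------------------------------------------------------------


def _window_vifs(x: np.ndarray) -> np.ndarray:
    """VIF of each column of the standardised genotype block ``x``.

    VIF_i = 1/(1 - R_i^2) with R_i^2 from regressing column i on the other
    columns; computed from the diagonal of the inverse correlation matrix.
    Returns inf where the correlation matrix is singular.
    """
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    try:
        inv = np.linalg.inv(r)
        return np.diag(inv).copy()
    except np.linalg.LinAlgError:
        return np.full(r.shape[0], np.inf)


def ld_prune(
    genotypes: GenotypeDataset,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> list[str]:
    """VIF-based LD pruning; returns the kept SNP ids.

    Slides a window of ``window`` SNPs by ``step`` within each chromosome;
    in each window, while some SNP's variance inflation factor exceeds
    ``vif_threshold``, the SNP with the largest VIF is removed (ties and
    singular windows drop the later SNP).  Monomorphic SNPs within the
    window are ignored by the regression but never removed here.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    m = genotypes.snp_map
    calls = genotypes.calls.astype(float)
    calls[genotypes.calls == MISSING] = np.nan
    # mean-impute missing for the regression only
    col_mean = np.nanmean(calls, axis=0)
    inds = np.where(np.isnan(calls))
    calls[inds] = np.take(col_mean, inds[1])

    removed = np.zeros(m.n_snps, dtype=bool)
    for chrom in m.chromosome_list():
        sl = m.chromosome_slice(int(chrom))
        lo, hi = sl.start, sl.stop
        start = lo
        while start < hi:
            idx = np.arange(start, min(start + window, hi))
            active = idx[~removed[idx]]
            # exclude zero-variance columns from the VIF computation
            variable = active[np.std(calls[:, active], axis=0) > 0]
            while variable.size >= 2:
                vifs = _window_vifs(calls[:, variable])
                worst = np.nanmax(vifs)
                if not (worst > vif_threshold) and np.isfinite(worst):
                    break
                if not np.isfinite(worst):
                    # singular: drop the later SNP among the maximal ones
                    drop_pos = variable[np.isinf(vifs) | np.isnan(vifs)][-1]
                    logger.info("singular window on chr %s; dropping SNP %s",
                                chrom, m.snp_ids[drop_pos])
                else:
                    cand = variable[np.isclose(vifs, worst)]
                    drop_pos = cand[-1]
                removed[drop_pos] = True
                variable = variable[variable != drop_pos]
            start += step
            if start + window > hi and idx[-1] == hi - 1:
                break
    return [m.snp_ids[j] for j in range(m.n_snps) if not removed[j]]


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------


@dataclass
class HetSummary:
    ho_per_individual: pd.Series
    mean_ho: float
    he: float
    he_uncorrected: float


def heterozygosity(genotypes: GenotypeDataset, corrected: bool = True) -> HetSummary:
    """Observed and expected heterozygosity.

    H_o(i) is the heterozygous fraction of individual i's non-missing
    autosomal calls.  H_e is the mean over SNPs of 2p(1-p), with the
    small-sample correction 2n/(2n-1) applied by default (n = non-missing
    individuals at the SNP); both variants are reported.
    """
    calls = genotypes.calls
    obs = calls != MISSING
    het = calls == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = het.sum(axis=1) / obs.sum(axis=1)
    ho_series = pd.Series(ho, index=pd.Index(genotypes.individual_ids, name="individual_id"),
                          name="H_o")

    p = allele_frequencies(genotypes)
    n = obs.sum(axis=0)
    poly = ~np.isnan(p) & (n > 0)
    if not poly.any():
        raise ValueError("no genotyped SNPs")
    he_raw = 2.0 * p[poly] * (1.0 - p[poly])
    if np.all(he_raw == 0):
        warnings.warn("all SNPs monomorphic; H_e = 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = 2.0 * n[poly] / (2.0 * n[poly] - 1.0)
    he_corr = float(np.mean(he_raw * np.where(n[poly] > 0, corr, 1.0)))
    he_unc = float(np.mean(he_raw))
    he = he_corr if corrected else he_unc
    return HetSummary(ho_series, float(np.nanmean(ho)), he, he_unc)
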