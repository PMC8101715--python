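"""End-to-end diversity analysis: simulate/load -> QC -> pedigree metrics ->
ROH inbreeding -> measure comparison -> LD-based Ne, with TSV reports and a
reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import Pedigree, read_pedigree, read_plink_bed, read_plink_text
from .ldne import estimate_ne_trajectory, pairwise_r2
from .pedigree import (
    complete_generation_equivalent,
    inbreeding_meuwissen_luo,
    ne_from_regression,
    pedigree_metrics,
)
from .popgen_stats import QcParams, heterozygosity, qc_filter
from .roh import (
    RohParams,
    compare_inbreeding_measures,
    detect_roh,
    froh_chromosomal,
    froh_length,
    froh_nsnp,
    rank_chromosomes,
    segments_frame,
)
from .synthdata import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and stage parameters for one pipeline run.

    Either ``sim`` (a :class:`SimConfig`) or all of
    ``pedigree_path``/``genotype_prefix`` must be given.  ``seed``
    overrides ``sim.seed`` when set.
    """

    out_dir: str = "herdgen_run"
    seed: int | None = None
    sim: SimConfig | None = None
    pedigree_path: str | None = None
    genotype_prefix: str | None = None  # PLINK prefix (.bed/.bim/.fam or .ped/.map)
    qc: QcParams = field(default_factory=QcParams)
    roh: RohParams = field(default_factory=RohParams)
    reference_years: tuple[int, int] | None = None
    completeness_depth: int = 10
    ldne_max_distance_kb: float = 10_000.0
    ldne_bins: int = 30
    ldne_alpha: float = 1.0
    ldne_min_pairs: int = 50


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        sim = config.sim
        if config.seed is not None:
            from dataclasses import replace

            sim = replace(sim, seed=config.seed)
        out = simulate_cohort(sim)
        return out.pedigree, out.genotypes
    if not (config.pedigree_path and config.genotype_prefix):
        raise ValueError("config needs either a SimConfig or input paths")
    pedigree = read_pedigree(config.pedigree_path)
    prefix = Path(config.genotype_prefix)
    if prefix.with_suffix(".bed").exists():
        genotypes = read_plink_bed(
            prefix.with_suffix(".bed"), prefix.with_suffix(".bim"), prefix.with_suffix(".fam")
        )
    else:
        genotypes = read_plink_text(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    return pedigree, genotypes


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; writes six TSV reports plus ``manifest.json`` into
    ``config.out_dir`` and returns the results in memory.

    Raises if any internal consistency check fails (chromosomal partition
    identity, Ne closed form).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pedigree, genotypes_raw = _load_inputs(config)

    # --- QC ---------------------------------------------------------------
    genotypes, qc_report = qc_filter(genotypes_raw, config.qc)
    het = heterozygosity(genotypes)

    # --- pedigree metrics -------------------------------------------------
    ped = pedigree_metrics(pedigree, config.reference_years, config.completeness_depth)
    gi = ped["generation_intervals"]
    gi_table = gi.pathways.copy()
    gi_table.loc["overall"] = {
        "n": gi.overall_n,
        "mean": gi.overall_mean if gi.overall_mean is not None else math.nan,
        "sd": gi.overall_sd if gi.overall_sd is not None else math.nan,
    }
    gi_table.to_csv(out_dir / "generation_intervals.tsv", sep="\t")

    sub = ped["subpopulation"] or {}
    summary_rows = [
        {"scope": "whole", "n": len(pedigree), "mean_F": ped["mean_F"],
         "mean_F_inbred": ped["mean_F_inbred"], "n_inbred": ped["n_inbred"],
         "mean_CGE": ped["mean_CGE"], "delta_F": ped["delta_F"], "Ne": ped["Ne"],
         "f_e": ped["f_e"], "f_a": ped["f_a"],
         "fa_over_fe": ped["f_a"] / ped["f_e"] if ped["f_e"] else math.nan},
    ]
    if sub:
        summary_rows.append(
            {"scope": "subpopulation", "n": sub.get("n"), "mean_F": sub.get("mean_F"),
             "mean_F_inbred": math.nan, "n_inbred": math.nan,
             "mean_CGE": sub.get("mean_CGE"), "delta_F": sub.get("delta_F"),
             "Ne": sub.get("Ne"), "f_e": sub.get("f_e"), "f_a": sub.get("f_a"),
             "fa_over_fe": (sub["f_a"] / sub["f_e"])
             if sub.get("f_e") and sub.get("f_a") else math.nan}
        )
    ped_summary = pd.DataFrame(summary_rows)
    ped_summary.to_csv(out_dir / "pedigree_summary.tsv", sep="\t", index=False)

    # --- ROH --------------------------------------------------------------
    segments = detect_roh(genotypes, config.roh)
    seg_table = segments_frame(segments)
    seg_table.to_csv(out_dir / "roh_segments.tsv", sep="\t", index=False)
    ids = genotypes.individual_ids
    fl = froh_length(segments, genotypes.snp_map, ids)
    fn = froh_nsnp(segments, genotypes.snp_map, ids)
    kk, ka, mean_kk = froh_chromosomal(segments, genotypes.snp_map, ids)

    # invariant self-check: chromosomal partition identity
    if not np.allclose(ka.sum(axis=1).to_numpy(), fl.to_numpy(), rtol=0, atol=1e-12):
        raise AssertionError("partition identity violated: sum_k F_ROH_KA != F_ROH_L")

    froh_table = pd.DataFrame({"F_ROH_L": fl, "F_ROH_N": fn, "mean_F_ROH_KK": mean_kk})
    F = inbreeding_meuwissen_luo(pedigree)
    cge = complete_generation_equivalent(pedigree)
    in_ped = [i for i in ids if i in pedigree]
    froh_table["F_PED"] = pd.Series({i: F[i] for i in in_ped})
    froh_table.to_csv(out_dir / "roh_inbreeding.tsv", sep="\t")

    ranking = rank_chromosomes(kk, ka)
    ranking.to_csv(out_dir / "chromosome_ranking.tsv", sep="\t", index=False)

    # --- measure comparison ----------------------------------------------
    comparison = None
    if len(in_ped) >= 3:
        cmp_table = froh_table.loc[in_ped, ["F_PED", "F_ROH_L", "F_ROH_N", "mean_F_ROH_KK"]]
        comparison = compare_inbreeding_measures(cmp_table)
        comparison["correlations"].to_csv(out_dir / "inbreeding_correlations.tsv", sep="\t")
    else:
        pd.DataFrame().to_csv(out_dir / "inbreeding_correlations.tsv", sep="\t")

    # ROH-based Ne: |slope| of F_ROH_L on CGE, whole-population formula
    ne_roh = None
    if len(in_ped) >= 3:
        cge_v = np.array([cge[i] for i in in_ped])
        if not np.allclose(cge_v, cge_v[0]):
            dF_roh, ne_roh_val = ne_from_regression(
                froh_table.loc[in_ped, "F_ROH_L"].to_numpy(), cge_v, absolute_slope=True
            )
            ne_roh = {"delta_F": dF_roh, "Ne_ROH": ne_roh_val}
            if math.isfinite(ne_roh_val) and not math.isclose(ne_roh_val, 1 / (2 * dF_roh)):
                raise AssertionError("Ne closed form violated")

    # --- LD Ne ------------------------------------------------------------
    pairs = pairwise_r2(genotypes, config.ldne_max_distance_kb, min_maf=config.qc.min_maf)
    trajectory = estimate_ne_trajectory(
        pairs, genotypes.n_individuals, bins=config.ldne_bins, alpha=config.ldne_alpha,
        max_distance_kb=config.ldne_max_distance_kb, min_pairs_per_bin=config.ldne_min_pairs,
    )
    trajectory.to_frame().to_csv(out_dir / "ne_trajectory.tsv", sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    cfg_json = json.dumps(asdict(config), default=str, sort_keys=True)
    manifest = {
        "herdgen_version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_individuals": genotypes.n_individuals,
        "n_snps": genotypes.n_snps,
        "n_pedigree_records": len(pedigree),
        "n_roh_segments": len(segments),
        "mean_H_o": het.mean_ho,
        "H_e": het.he,
        "Ne_ROH": ne_roh,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "pedigree": pedigree,
        "genotypes": genotypes,
        "qc_report": qc_report,
        "het": het,
        "pedigree_metrics": ped,
        "segments": segments,
        "froh_table": froh_table,
        "ranking": ranking,
        "comparison": comparison,
        "ne_roh": ne_roh,
        "trajectory": trajectory,
        "manifest": manifest,
    }
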