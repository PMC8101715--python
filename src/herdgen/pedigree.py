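"""Pedigree-based diversity and demography parameters.

Implements the classic pedigree toolkit for livestock monitoring
populations: the Meuwissen & Luo inbreeding algorithm, complete generation
equivalents (CGE), MacCluer-style pedigree completeness, generation
intervals along the four gametic pathways, realised inbreeding rate and
effective population size from the regression of F on CGE, and the
probability-of-gene-origin parameters f_e (effective number of founders)
and f_a (effective number of ancestors, Boichard's marginal-contribution
greedy algorithm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Pedigree

__all__ = [
    "inbreeding_meuwissen_luo",
    "complete_generation_equivalent",
    "completeness_index",
    "generation_intervals",
    "GenerationIntervals",
    "ne_from_regression",
    "effective_number_of_founders",
    "effective_number_of_ancestors",
    "pedigree_metrics",
]


# ---------------------------------------------------------------------------
# Inbreeding (Meuwissen & Luo)
# ---------------------------------------------------------------------------


def inbreeding_meuwissen_luo(pedigree: Pedigree) -> dict[str, float]:
    """Per-individual inbreeding coefficients F.

    Uses the ancestor-tracing algorithm of Meuwissen & Luo: for animal *i*
    with both parents known, 1 + F_i equals the sum over the ancestors *j*
    of the mid-parent of L_j^2 * D_j, where L_j is the expected genetic
    contribution of *j* to the mid-parent genome and
    D_j = 1/2 - (F_sire(j) + F_dam(j))/4 is the within-family Mendelian
    sampling variance.  Individuals with an unknown parent get F = 0.
    """
    order = pedigree.ids  # parents before offspring
    index = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for k, iid in enumerate(order):
        s, d = pedigree.parents(iid)
        if s is not None:
            sire[k] = index[s]
        if d is not None:
            dam[k] = index[d]

    F = np.zeros(n)
    # D_j depends only on j's parents' F, which are computed before j is
    # ever visited as an ancestor (topological order).
    for k in range(n):
        s, d = sire[k], dam[k]
        if s < 0 or d < 0:
            F[k] = 0.0
            continue
        # accumulate contributions L to the (virtual) offspring of s x d
        L: dict[int, float] = {s: 0.5, d: 0.5}
        # process ancestors youngest-first so each node is expanded once
        import heapq

        heap = [-s, -d]
        heapq.heapify(heap)
        seen = set(heap)
        total = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            fs = F[sire[j]] if sire[j] >= 0 else 0.0
            fd = F[dam[j]] if dam[j] >= 0 else 0.0
            known = int(sire[j] >= 0) + int(dam[j] >= 0)
            # Mendelian sampling variance; unknown parents contribute as
            # unrelated non-inbred founders
            dj = 0.5 - 0.25 * (fs + fd) if known == 2 else (0.75 - 0.25 * fs - 0.25 * fd if known == 1 else 1.0)
            total += lj * lj * dj
            for p in (sire[j], dam[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + lj / 2.0
                    if -p not in seen:
                        heapq.heappush(heap, -p)
                        seen.add(-p)
            seen.discard(-j)
        # total = a(s,d)/?  -- total equals 0.5*(1+F_offspring)*2?  No:
        # sum L^2 D over ancestors of the offspring (with L[off]=1) gives
        # 1+F_off; here we dropped the offspring term D_off = 0.5-0.25(Fs+Fd):
        F[k] = total + (0.5 - 0.25 * (F[s] + F[d])) - 1.0
    return {iid: float(F[index[iid]]) for iid in order}


# ---------------------------------------------------------------------------
# CGE and completeness
# ---------------------------------------------------------------------------


def complete_generation_equivalent(pedigree: Pedigree) -> dict[str, float]:
    """Complete generation equivalents: sum of (1/2)^g over known ancestors.

    Each known ancestor slot at parental generation g contributes (1/2)^g,
    so CGE = 1 for an individual with both parents known and nothing
    deeper, and CGE = g for g fully known generations.
    """
    cge: dict[str, float] = {}
    for iid in pedigree.ids:  # parents first
        s, d = pedigree.parents(iid)
        v = 0.0
        for p in (s, d):
            if p is not None:
                v += 0.5 * (1.0 + cge[p])
        cge[iid] = v
    return cge


def _known_slots(pedigree: Pedigree, depth: int) -> dict[str, np.ndarray]:
    """Per individual, number of known ancestor slots at generations 1..depth."""
    counts: dict[str, np.ndarray] = {}
    for iid in pedigree.ids:
        s, d = pedigree.parents(iid)
        vec = np.zeros(depth, dtype=np.int64)
        for p in (s, d):
            if p is not None:
                vec[0] += 1
                if depth > 1:
                    vec[1:] += counts[p][: depth - 1]
        counts[iid] = vec
    return counts


def completeness_index(pedigree: Pedigree, depth: int) -> pd.DataFrame:
    """MacCluer-style pedigree completeness.

    Returns a frame with, per individual, the proportion of the 2^d
    ancestor slots known at each parental generation d = 1..depth, plus a
    summary ``index``: the harmonic mean of the paternal- and maternal-line
    completeness, each line's completeness being the mean known proportion
    over generations 1..depth within that line (zero if either line is
    unrecorded).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counts = _known_slots(pedigree, depth)
    denom = 2.0 ** np.arange(1, depth + 1)
    line_denom = 2.0 ** np.arange(0, depth)  # slots within one parental line
    rows = []
    for iid in pedigree.ids:
        prop = counts[iid] / denom
        s, d = pedigree.parents(iid)

        def line_completeness(p):
            if p is None:
                return 0.0
            vec = np.zeros(depth, dtype=np.int64)
            vec[0] = 1
            if depth > 1:
                vec[1:] = counts[p][: depth - 1]
            return float(np.mean(vec / line_denom))

        c_pat = line_completeness(s)
        c_mat = line_completeness(d)
        idx = 0.0 if c_pat == 0.0 or c_mat == 0.0 else 2.0 * c_pat * c_mat / (c_pat + c_mat)
        row = {"individual_id": iid, "index": idx}
        for g in range(depth):
            row[f"gen{g + 1}"] = prop[g]
        rows.append(row)
    return pd.DataFrame(rows).set_index("individual_id")


# ---------------------------------------------------------------------------
# Generation intervals
# ---------------------------------------------------------------------------


@dataclass
class GenerationIntervals:
    """Mean parental age (years) at birth of offspring kept for reproduction,
    by gametic pathway, plus the overall mean L."""

    pathways: pd.DataFrame  # rows L_ss/L_sd/L_ds/L_dd: n, mean, sd
    overall_n: int
    overall_mean: float | None
    overall_sd: float | None
    n_missing_birth_year: int = 0


_PATHWAY = {("male", "male"): "L_ss", ("male", "female"): "L_sd",
            ("female", "male"): "L_ds", ("female", "female"): "L_dd"}


def generation_intervals(pedigree: Pedigree) -> GenerationIntervals:
    """Generation intervals along the four gametic pathways.

    Only parent-offspring pairs where the offspring itself has recorded
    progeny contribute ("kept for reproduction"); pairs lacking a birth
    year on either side are dropped and counted.
    """
    n_off = pedigree.offspring_counts()
    obs: dict[str, list[float]] = {k: [] for k in _PATHWAY.values()}
    n_missing = 0
    for iid in pedigree.ids:
        if n_off[iid] == 0:
            continue  # offspring not kept for reproduction
        rec = pedigree.record(iid)
        if rec.sex not in ("male", "female"):
            continue
        for p in pedigree.parents(iid):
            if p is None:
                continue
            prec = pedigree.record(p)
            if prec.sex not in ("male", "female"):
                continue
            if rec.birth_year is None or prec.birth_year is None:
                n_missing += 1
                continue
            obs[_PATHWAY[(prec.sex, rec.sex)]].append(float(rec.birth_year - prec.birth_year))
    rows = []
    allv: list[float] = []
    for k in ("L_ss", "L_sd", "L_ds", "L_dd"):
        v = obs[k]
        allv.extend(v)
        rows.append(
            {
                "pathway": k,
                "n": len(v),
                "mean": float(np.mean(v)) if v else math.nan,
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else math.nan,
            }
        )
    frame = pd.DataFrame(rows).set_index("pathway")
    if allv:
        mean = float(np.mean(allv))
        sd = float(np.std(allv, ddof=1)) if len(allv) > 1 else math.nan
    else:
        warnings.warn("no qualifying parent-offspring pairs; generation interval undefined")
        mean = sd = None
    return GenerationIntervals(frame, len(allv), mean, sd, n_missing)


# ---------------------------------------------------------------------------
# Inbreeding rate and Ne from the regression of F on CGE
# ---------------------------------------------------------------------------


def ne_from_regression(
    F: np.ndarray,
    cge: np.ndarray,
    mode: str = "whole",
    absolute_slope: bool = False,
) -> tuple[float, float]:
    """Rate of inbreeding and effective population size from F ~ CGE.

    The OLS slope *b* of individual inbreeding on complete generation
    equivalents estimates the per-generation rate of inbreeding.  In
    ``whole`` mode ΔF = b; in ``subpopulation`` mode ΔF = b / (1 - (F_t - b))
    with F_t the subpopulation mean F.  Ne = 1 / (2 ΔF).

    ``absolute_slope`` takes |b| (used for ROH-based Ne to avoid negative
    effective sizes).

    Returns (delta_F, Ne); Ne is ``inf`` (with a warning) when ΔF <= 0.
    """
    F = np.asarray(F, dtype=float)
    cge = np.asarray(cge, dtype=float)
    if F.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.allclose(cge, cge[0]):
        raise ValueError("CGE values are all equal; slope undefined")
    # OLS with intercept
    b = float(np.polyfit(cge, F, 1)[0])
    if absolute_slope:
        b = abs(b)
    if mode == "whole":
        delta_f = b
    elif mode == "subpopulation":
        f_t = float(np.mean(F))
        delta_f = b / (1.0 - (f_t - b))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if delta_f <= 0:
        warnings.warn("non-positive inbreeding rate; Ne reported as infinite")
        return delta_f, math.inf
    return delta_f, 1.0 / (2.0 * delta_f)


# ---------------------------------------------------------------------------
# Probability of gene origin: f_e and f_a
# ---------------------------------------------------------------------------


def _gene_flow(
    pedigree: Pedigree,
    reference: list[str],
    absorb: set[str] | None = None,
) -> dict[str, float]:
    """Expected fraction of reference-set genes passing through each individual.

    Weight 1/|ref| starts at each reference individual and flows half to
    each known parent; the flow stops at individuals in ``absorb`` and at
    unknown-parent slots (absorbed by the individual itself, i.e. treated
    as a founder for that fraction).  Returns the total weight arriving at
    every individual (each individual's own reference weight included).
    """
    absorb = absorb or set()
    arrive = {iid: 0.0 for iid in pedigree.ids}
    w0 = 1.0 / len(reference)
    for iid in reference:
        arrive[iid] += w0
    for iid in reversed(pedigree.ids):  # offspring before parents
        w = arrive[iid]
        if w == 0.0 or iid in absorb:
            continue
        s, d = pedigree.parents(iid)
        for p in (s, d):
            if p is not None:
                arrive[p] += w / 2.0
    return arrive


def effective_number_of_founders(
    pedigree: Pedigree, reference: list[str] | set[str]
) -> tuple[float, dict[str, float]]:
    """f_e = 1 / sum(q_k^2) with q_k the expected founder contributions.

    q_k is the probability that a gene sampled at random in the reference
    set originates from founder k; individuals with partially unknown
    parents act as founders for the unknown fraction of their genome.
    """
    reference = sorted(reference)
    for iid in reference:
        if iid not in pedigree:
            raise KeyError(f"reference individual {iid!r} not in pedigree")
    arrive = _gene_flow(pedigree, reference)
    q: dict[str, float] = {}
    for iid in pedigree.ids:
        s, d = pedigree.parents(iid)
        n_unknown = (s is None) + (d is None)
        if n_unknown and arrive[iid] > 0:
            q[iid] = arrive[iid] * n_unknown / 2.0
    total = sum(q.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise AssertionError(f"founder contributions sum to {total}, not 1")
    fe = 1.0 / sum(v * v for v in q.values())
    return fe, q


def effective_number_of_ancestors(
    pedigree: Pedigree,
    reference: list[str] | set[str],
    tol: float = 1e-9,
    max_ancestors: int | None = None,
) -> tuple[float, dict[str, float], list[str]]:
    """f_a = 1 / sum(q_j^2) over greedily chosen ancestors (Boichard).

    Rounds: compute each candidate's expected contribution to the
    reference set with gene flow absorbed at already-chosen ancestors
    (so contribution routed through a chosen ancestor is not re-counted),
    pick the ancestor with the largest marginal contribution, and repeat
    until the residual unexplained contribution falls below ``tol``.
    """
    reference = sorted(reference)
    for iid in reference:
        if iid not in pedigree:
            raise KeyError(f"reference individual {iid!r} not in pedigree")
    chosen: list[str] = []
    q: dict[str, float] = {}
    explained = 0.0
    limit = max_ancestors or len(pedigree)
    while len(chosen) < limit:
        if explained >= 1.0 - tol:
            break
        absorb = set(chosen)
        arrive = _gene_flow(pedigree, reference, absorb=absorb)
        # probability that a gene of each individual's own genome escapes
        # the chosen set when traced upward (parents first in pedigree order)
        escape: dict[str, float] = {}
        for iid in pedigree.ids:
            e = 0.0
            for p in pedigree.parents(iid):
                if p is None:
                    e += 0.5  # founder slot: unexplained
                elif p not in absorb:
                    e += 0.5 * escape[p]
            escape[iid] = e
        # marginal contribution: genes reaching the candidate that no chosen
        # ancestor would otherwise explain; ties broken by pedigree order
        best, best_w = None, tol
        for iid in pedigree.ids:
            if iid in q:
                continue
            w = arrive[iid] * escape[iid]
            if w > best_w + 1e-15:
                best, best_w = iid, w
        if best is None:
            break
        q[best] = best_w
        chosen.append(best)
        explained += best_w
    fa = 1.0 / sum(v * v for v in q.values())
    return fa, q, chosen


# ---------------------------------------------------------------------------
# Combined per-population summary
# ---------------------------------------------------------------------------


def pedigree_metrics(
    pedigree: Pedigree,
    reference_years: tuple[int, int] | None = None,
    depth: int = 15,
) -> dict:
    """One-stop pedigree characterisation.

    Computes per-individual F and CGE, completeness, generation intervals,
    ΔF/Ne for the whole pedigree and (if ``reference_years`` is given) for
    the birth-year-window subpopulation, and f_e/f_a for both reference
    sets.  Returns a dict of results; subpopulation entries are ``None``
    when the window selects fewer than 3 individuals.
    """
    F = inbreeding_meuwissen_luo(pedigree)
    cge = complete_generation_equivalent(pedigree)
    ids = pedigree.ids
    Fv = np.array([F[i] for i in ids])
    Cv = np.array([cge[i] for i in ids])
    out: dict = {
        "F": F,
        "CGE": cge,
        "mean_F": float(Fv.mean()),
        "mean_F_inbred": float(Fv[Fv > 0].mean()) if (Fv > 0).any() else 0.0,
        "n_inbred": int((Fv > 0).sum()),
        "mean_CGE": float(Cv.mean()),
        "completeness": completeness_index(pedigree, depth),
        "generation_intervals": generation_intervals(pedigree),
    }
    try:
        dF, ne = ne_from_regression(Fv, Cv, mode="whole")
        out["delta_F"], out["Ne"] = dF, ne
    except ValueError:
        out["delta_F"] = out["Ne"] = None
    fe, _ = effective_number_of_founders(pedigree, ids)
    fa, _, _ = effective_number_of_ancestors(pedigree, ids)
    out["f_e"], out["f_a"] = fe, fa

    out["subpopulation"] = None
    if reference_years is not None:
        lo, hi = reference_years
        ref = [
            i
            for i in ids
            if pedigree.record(i).birth_year is not None and lo <= pedigree.record(i).birth_year <= hi
        ]
        sub: dict = {"reference_ids": ref, "n": len(ref)}
        if len(ref) >= 3:
            Fs = np.array([F[i] for i in ref])
            Cs = np.array([cge[i] for i in ref])
            sub["mean_F"] = float(Fs.mean())
            sub["mean_CGE"] = float(Cs.mean())
            try:
                dF, ne = ne_from_regression(Fs, Cs, mode="subpopulation")
                sub["delta_F"], sub["Ne"] = dF, ne
            except ValueError:
                sub["delta_F"] = sub["Ne"] = None
            fe, _ = effective_number_of_founders(pedigree, ref)
            fa, _, _ = effective_number_of_ancestors(pedigree, ref)
            sub["f_e"], sub["f_a"] = fe, fa
        out["subpopulation"] = sub
    return out
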