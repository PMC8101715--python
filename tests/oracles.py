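"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles (path counting,
exhaustive enumeration, naive scanning, Monte-Carlo) without sharing code
with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------------------
# Wright's path-counting inbreeding coefficient
# ---------------------------------------------------------------------------


def wright_inbreeding(parents: dict[str, tuple[str | None, str | None]]) -> dict[str, float]:
    """F for every individual by enumerating ancestral loops (Wright).

    ``parents[i] = (sire, dam)`` with ``None`` for unknown.
    F_i = sum over common ancestors A of sire and dam, over pairs of
    ascending paths meeting only at A, of (1/2)^(n1+n2+1) (1+F_A).
    """

    def paths_up(x: str) -> list[list[str]]:
        # all ascending paths from x (inclusive) to each of its ancestors
        out = [[x]]
        for p in parents.get(x, (None, None)):
            if p is not None:
                out.extend([[x] + path for path in paths_up(p)])
        return out

    memo: dict[str, float] = {}

    def F(i: str) -> float:
        if i in memo:
            return memo[i]
        memo[i] = 0.0  # guard (pedigree is acyclic; value fixed below)
        s, d = parents.get(i, (None, None))
        if s is None or d is None:
            memo[i] = 0.0
            return 0.0
        total = 0.0
        for p1 in paths_up(s):
            for p2 in paths_up(d):
                if p1[-1] != p2[-1]:
                    continue  # must end at the same ancestor
                # meet only at the terminal common ancestor
                if set(p1[:-1]) & set(p2):
                    continue
                if set(p2[:-1]) & set(p1):
                    continue
                a = p1[-1]
                n1, n2 = len(p1) - 1, len(p2) - 1
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + F(a))
        memo[i] = total
        return total

    return {i: F(i) for i in parents}


# ---------------------------------------------------------------------------
# CGE by exhaustive ancestor-slot walk
# ---------------------------------------------------------------------------


def cge_by_walk(parents: dict[str, tuple[str | None, str | None]], iid: str) -> float:
    def walk(x: str, g: int) -> float:
        tot = 0.0
        for p in parents.get(x, (None, None)):
            if p is not None:
                tot += 0.5 ** g + walk(p, g + 1)
        return tot

    return walk(iid, 1)


# ---------------------------------------------------------------------------
# Naive quadratic ROH scanner (same rules, direct loops)
# ---------------------------------------------------------------------------


def naive_roh_scan(geno, pos, window_snps=50, max_het=1, max_missing=2,
                   min_density_kb=100.0, max_gap_kb=1000.0, min_run_snps=100,
                   min_run_kb=1000.0, hit_threshold=0.05):
    """Return (start_bp, end_bp, n_snps) tuples; geno uses -1 for missing."""
    geno = list(geno)
    pos = list(pos)
    n = len(pos)
    w = min(window_snps, n)
    nwin = n - w + 1
    ok = []
    for j in range(nwin):
        win = geno[j:j + w]
        ok.append(sum(1 for g in win if g == 1) <= max_het
                  and sum(1 for g in win if g == -1) <= max_missing)
    cand = []
    for i in range(n):
        wins = [j for j in range(nwin) if j <= i <= j + w - 1]
        hits = sum(1 for j in wins if ok[j])
        cand.append(hits > hit_threshold * len(wins))
    segs = []
    i = 0
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and cand[j + 1]:
            j += 1
        parts = []
        start = i
        for k in range(i, j):
            if (pos[k + 1] - pos[k]) / 1000.0 > max_gap_kb:
                parts.append((start, k))
                start = k + 1
        parts.append((start, j))
        for a, b in parts:
            length_kb = (pos[b] - pos[a] + 1) / 1000.0
            nsnp = sum(1 for g in geno[a:b + 1] if g != -1)
            if nsnp < min_run_snps or length_kb < min_run_kb:
                continue
            if nsnp and length_kb / nsnp > min_density_kb:
                continue
            segs.append((pos[a], pos[b], nsnp))
        i = j + 1
    return segs


# ---------------------------------------------------------------------------
# Exact HWE by full enumeration with rational arithmetic
# ---------------------------------------------------------------------------


def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact HWE p-value summed over the full support with exact
    fractions (Levene/Haldane conditional distribution)."""
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    na = 2 * n_hom1 + n_het  # allele-1 count
    nb = 2 * n - na

    def prob(h: int) -> Fraction:
        if (na - h) % 2 or h > min(na, nb) or (na - h) < 0 or (nb - h) < 0:
            return Fraction(0)
        aa = (na - h) // 2
        bb = (nb - h) // 2
        return Fraction(
            math.factorial(n) * math.factorial(na) * math.factorial(nb) * 2 ** h,
            math.factorial(aa) * math.factorial(h) * math.factorial(bb) * math.factorial(2 * n),
        )

    support = [h for h in range(0, min(na, nb) + 1) if (na - h) % 2 == 0]
    probs = {h: prob(h) for h in support}
    assert sum(probs.values()) == 1
    p_obs = probs[n_het]
    return float(sum(v for v in probs.values() if v <= p_obs))


# ---------------------------------------------------------------------------
# Monte-Carlo gene-drop founder contributions
# ---------------------------------------------------------------------------


def montecarlo_founder_contributions(parents, reference, n_drops=100_000, seed=0):
    """Sample single-gene origins: pick a reference individual uniformly,
    then ascend choosing sire/dam with probability 1/2 each until a missing
    parent slot stops the walk; the stopping individual is the founder of
    record.  Returns (frequencies dict, n_drops)."""
    rng = np.random.default_rng(seed)
    reference = list(reference)
    counts: dict[str, int] = {}
    for _ in range(n_drops):
        x = reference[rng.integers(len(reference))]
        while True:
            p = parents.get(x, (None, None))[int(rng.integers(2))]
            if p is None:
                break
            x = p
        counts[x] = counts.get(x, 0) + 1
    return {k: v / n_drops for k, v in counts.items()}, n_drops
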