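# herdgen

Genetic-diversity analysis for small, monitored livestock populations from
the two data sources a breed society actually has: the herdbook pedigree
and a medium-density SNP chip.

Small flock-book breeds (the motivating case is a monitored mutton sheep
population genotyped on a ~50k ovine chip) need routine answers to a
handful of questions: how inbred is the population, how fast is inbreeding
accumulating, how many founders and ancestors effectively contributed, and
what is the recent effective population size?  `herdgen` implements the
standard toolkit for all of them, plus a recombination-aware gene-dropping
simulator so the whole stack can be exercised and validated without any
confidential herdbook data.

## What it computes

**Pedigree side** (`herdgen.pedigree`)

- Inbreeding coefficients *F* by the Meuwissen–Luo ancestor-tracing
  algorithm (verified against Wright's path-counting on random pedigrees).
- Pedigree quality: complete generation equivalents
  (CGE = Σ (1/2)^g over known ancestors) and MacCluer-style per-generation
  completeness.
- Generation intervals *L* along the four gametic pathways
  (L_ss, L_sd, L_ds, L_dd), counting only offspring that themselves
  reproduce.
- Rate of inbreeding from the OLS regression of *F* on CGE:
  ΔF = b (whole population) or ΔF = b / (1 − (F̄ − b)) (recent
  subpopulation), and N_e = 1/(2ΔF).
- Probability-of-gene-origin parameters: effective number of founders
  f_e = 1/Σq_k² and effective number of ancestors f_a = 1/Σq_j² (greedy
  marginal contributions, Boichard-style); f_a/f_e < 1 signals a
  bottleneck.

**Genomic side** (`herdgen.roh`, `herdgen.popgen_stats`, `herdgen.ldne`)

- QC: individual/SNP call rate, MAF, exact Hardy–Weinberg test, and
  VIF-based LD pruning (the `--indep` procedure).
- Sliding-window ROH detection (50-SNP window, ≤1 heterozygote, ≤2 missing,
  ≥1 SNP/100 kb, gaps ≤1 Mb split runs; runs ≥100 SNPs and ≥1 Mb), checked
  against a naive quadratic scanner.
- Four ROH inbreeding measures per individual:

      F_ROH_L  = Σ L_ROH / L_AUTO          F_ROH_N  = ROH_SNP / N_SNP
      F_ROH_KK = Σ L_ROH_K / L_AUTO_K      F_ROH_KA = Σ L_ROH_K / L_AUTO

  with the partition identity Σ_k F_ROH_KA = F_ROH_L holding exactly,
  chromosome rankings by inbreeding burden, and correlation/regression
  comparison of all measures against F_PED.
- Observed/expected heterozygosity and the LD-decay effective-size
  trajectory N(t) = (4c)⁻¹ (E[r²_adj|c]⁻¹ − α) at t = (2c)⁻¹ generations
  ago, with the 10 Mb pair-distance cap dating the most recent estimate to
  t = 5.

**Simulator** (`herdgen.synthdata`) — multi-generation pedigrees with
configurable mating schemes and record loss, plus gene dropping of founder
haplotypes with Haldane recombination on a 26-autosome, ~40k-SNP evenly
spaced map, so pedigree autozygosity is realised as detectable ROH and
every estimator can be tested against simulation truth.

## Worked example

```python
import numpy as np
from scipy import stats
from herdgen import (SimConfig, simulate_cohort, detect_roh,
                     froh_length, froh_nsnp, inbreeding_meuwissen_luo)

out = simulate_cohort(SimConfig(seed=1))       # 46 individuals, 40,753 SNPs
segs = detect_roh(out.genotypes)
ids = out.genotypes.individual_ids
fl = froh_length(segs, out.genotypes.snp_map, ids)
fn = froh_nsnp(segs, out.genotypes.snp_map, ids)
F = inbreeding_meuwissen_luo(out.pedigree_true)
fped = np.array([F[i] for i in ids])

print(len(segs), round(fl.mean(), 4))
print(round(stats.pearsonr(fl, fn).statistic, 4))
print(round(stats.pearsonr(fped, fl).statistic, 4))
```

prints

```
252 0.0421
1.0
0.8807
```

i.e. 252 ROH across the cohort, mean genomic inbreeding F_ROH_L = 4.2%, a
near-perfect correlation between the length-based and SNP-count-based
measures (a direct consequence of even SNP spacing), and a correlation of
0.88 between pedigree and genomic inbreeding on this three-generation
fully recorded pedigree.

The same analyses are available from the shell:

```bash
herdgen simulate --seed 3 --out-prefix sim/cohort
herdgen qc --bfile sim/cohort --out sim/clean
herdgen roh --bfile sim/clean --out sim/roh.tsv
herdgen ldne --bfile sim/clean --max-dist-mb 10 --out sim/ne.tsv
herdgen ped-metrics --pedigree sim/cohort.pedigree.csv --depth 10 --out sim/ped.tsv
herdgen run --config run.yaml        # full pipeline + manifest.json
```

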