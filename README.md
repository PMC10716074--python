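# rrsim

Stochastic simulation of **reciprocal recurrent selection (RRS)** for hybrid
rice breeding, comparing phenotypic testcross selection with genomic
prediction of single-cross hybrid performance.

## Who this is for

Breeding-program designers and quantitative geneticists who want to ask,
before committing a decade of field seasons: *how much faster does a
two-pool hybrid program improve if all candidate single crosses are
predicted in silico instead of testcrossed to a handful of testers — and
how much genetic variance does each strategy burn?*

## The model

Two heterotic pools A and B of fully inbred rice lines are improved for the
value of their inter-pool F1 hybrids. A quantitative trait (e.g. grain
yield) is controlled by 360 QTN on 12 chromosomes. QTN *i* has an additive
effect *a_i* ~ Gamma(1, 1) with random sign and a dominance effect
*d_i* = |*a_i*| · δ_i with dominance degree δ_i ~ N(0.22, 0.26), so roughly
a third of loci show opposite-direction dominance and ~6% overdominance.
The genetic value of a genotype is

    G = Σ_i a_i x_i + Σ_i d_i h_i ,   x ∈ {−1, 0, +1},  h = 1 if heterozygous,

with effects rescaled once so that the 3,000-line founder panel has
genetic variance 1 and mean 0, and an environmental variance
V_E = (1 − H²)/H² with H² = 0.53. Founders come from a Wright–Fisher
population simulated with recombination so that linkage disequilibrium
decays with map distance.

Five breeding schemes share one base population (the best 384 founders, all
73,536 pairwise crosses, top hybrids founding each pool) and a three-cycle
burn-in, then run for 20 cycles at three program sizes
(L = 64/128/192 lines per pool, P = 10/20/30 recycled parents):

| scheme        | evaluation                                   | selection        |
|---------------|----------------------------------------------|------------------|
| `TRAD_RRS`    | testcross to 3 static testers (HO = 6L)      | phenotype        |
| `DRIFT_RRS`   | same mechanics                               | uniform random   |
| `TRAD_RRS_UP` | testcross, testers replaced every cycle      | phenotype        |
| `GS_A_RRS`    | all L×L crosses predicted, top HO realized   | additive RR-BLUP |
| `GS_AD_RRS`   | as above                                     | additive + dominance RR-BLUP |

Genomic prediction deduces each hybrid's 996-SNP profile from its inbred
parents and solves the ridge system û = (Z′Z + λI)⁻¹Z′y with
λ = σ²_e/σ²_u estimated by a REML-type profile likelihood; the training
set keeps a sliding window of the last three cycles of phenotyped hybrids.
Per cycle the simulator records mean and best hybrid genetic value,
within-pool additive variance Var(Σ α_i x_i) with α = a + (q − p)d,
selection/prediction accuracy, and the Hudson F_ST between the pools.

## Worked example

```python
import numpy as np
from rrsim import SchemeConfig, run_comparison

cfg = SchemeConfig(n_cycles=5, n_replicates=2, master_seed=7)
rows = run_comparison(cfg, [("TRAD_RRS", "I"), ("GS_A_RRS", "I")])
print(rows.groupby(["scheme", "cycle"]).mean_hybrid_gv.mean().round(2))
```

prints (values in genetic-standard-deviation units of the founder panel;
cycle 0 is the shared post-burn-in state):

```
scheme    cycle
GS_A_RRS  0        4.28
          1        5.60
          2        5.99
          3        6.40
          4        6.62
          5        6.93
TRAD_RRS  0        4.28
          1        4.51
          2        4.68
          3        5.00
          4        5.16
          5        5.28
Name: mean_hybrid_gv, dtype: float64
```

Both arms start from the same burn-in mean (+4.28 after base-population and
burn-in selection); after five cycles the genomic arm has gained about
twice as much as phenotypic testcrossing, because it screens all 4,096
candidate crosses in silico instead of 384 testcrosses.

The same runs from a shell, writing tidy CSVs:

```bash
rrsim simulate --scheme gs_a --size I --cycles 5 --reps 2 --seed 7 --out out/
rrsim compare --config examples/compare.yaml --out out/ --plots
```

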