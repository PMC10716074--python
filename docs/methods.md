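# Methods

This note documents the models behind `rrsim`, the defaults and their
units, the choices made where the design was genuinely open, and what the
synthetic data can and cannot say about real breeding programs.

## Founder genome and panel

The genome is 12 chromosomes of 130 cM (≈1,560 cM total, a rice consensus
scale), each carrying 600 segregating biallelic sites at uniform random
map positions; 30 sites per chromosome are causal (QTN, 360 genome-wide)
and 83 form the genotyping panel (SNP, 996 genome-wide), drawn jointly
without replacement so the two sets never overlap. All per-site arrays use
chromosome-major flat indexing; positions are in centimorgans.

The founder panel emulates a germplasm bank of 3,000 fully inbred lines.
A Wright–Fisher population of 200 diploids is initialized with per-site
allele frequencies from Beta(0.5, 0.5) clamped to [0.05, 0.95] (a U-shaped
spectrum with no near-lost alleles), random-mated with recombination for
200 generations to build linkage disequilibrium, and each founder is the
doubled gamete of a random individual — fully homozygous, with the
population's allele frequencies and LD intact. Sites monomorphic after
drift are re-drawn i.i.d. from the frequency spectrum (at most 100
attempts each) so every QTN and SNP segregates; these few columns carry no
LD, which is acceptable for their purpose. A coalescent backend could be
substituted; the downstream contract is only *segregating, LD-decaying,
inbred*.

Limitations worth knowing: LD from this generator is modest (mean r² ≈
0.03 between sites < 1 cM apart in the panel) — real rice diversity panels,
and coalescent simulations with bottleneck histories, show substantially
stronger short-range LD. The SNP panel is also not ascertained on minor
allele frequency, unlike commercial chips, so many panel SNPs are nearly
fixed. Both features depress genomic prediction accuracy relative to a
program genotyped with a real chip; they affect the *relative* standing of
the genomic schemes (see "Known limitations").

## Meiosis

Crossovers follow a Poisson process along the genetic map (expected count
= length in Morgans), uniform positions, no interference, no obligate
chiasma, no mutation. `make_gamete` implements this literally. The
vectorised engine (`gametes_batch`) instead samples an independent switch
indicator per interval between adjacent mapped sites with the Haldane
recombination fraction r = (1 − e^(−2d/100))/2; under no interference this
reproduces exactly the inheritance law of the Poisson process at the
mapped sites, and the two implementations are cross-checked statistically
in the test suite. Inbreeding uses doubled gametes by default (instant
homozygosity; cycle-length differences between schemes are not modeled);
`ssd_k` selfing is available for realism studies.

## Trait model and calibration

Additive effects are Gamma(1, 1) with uniform random sign — "randomly
assigned" is read as a random direction per locus, since a trait with
all-positive effects would be degenerate under bidirectional selection.
Dominance degrees are N(0.22, 0.26) and d = |a|·δ, so the dominance/
additive ratio at each locus survives any common rescaling.

Calibration multiplies all effects by one constant so that the variance of
true genetic values **among the 3,000 inbred founders** is exactly 1
(population variance, ddof 0), sets the intercept so their mean is 0, and
sets V_E = (1 − 0.53)/0.53 ≈ 0.887 from the broad-sense target H² = 0.53.
In a fully inbred panel no dominance deviations are expressed, so genotypic
values are exactly linear in dosage and H² = h² there; the narrow-sense
value in any *hybrid* population is emergent, not enforced. Crossing
inbreds halves the per-locus additive variance (4pq a² → 2pq α²) and
phenotypic selection of the base parents removes more (Bulmer effect), so
the realized narrow-sense heritability in the base single-cross population
comes out near 0.25, not 0.5; both realized heritabilities are computed and
reported by the acceptance script rather than asserted as inputs.
Phenotype errors are Gaussian, i.i.d., redrawn at every phenotyping event
(single-trial evaluation, no permanent environment effect).

## Base population and burn-in

Founders are phenotyped once; the best 384 are crossed in all C(384,2) =
73,536 pairs in silico and the hybrids phenotyped once with the same V_E
(no replicated plots, as no trial design is modeled). Walking the ranked
hybrid list, unseen female-side parents fill pool A and unseen male-side
parents pool B until each has 10; because pair orientation among founders
is arbitrary, an individual is not allowed to found both pools. Each
pool's first three parents — the parents of the best hybrids — are its
testers. Three cycles of traditional RRS at size I (static testers) form
the burn-in; the final 384 testcross hybrids seed the genomic training
set. All scheme arms of a replicate branch from this state.

## Breeding cycles

Every cycle, each pool's P parents are random-mated (uniform pairs, no
selfing) into exactly L one-per-pair doubled-gamete lines. Phenotypic
schemes testcross each line to the three testers of the reciprocal pool
(pool A is the female/CMS side throughout), phenotype the 6L hybrids, and
select: the P best hybrids (uniform random for DRIFT) are traced to their
**line** parents — females to pool A, males to pool B, uniqueness enforced
by continuing down the ranked list. Testers are evaluation aids and are
not themselves recycled; an early implementation that allowed the three
static testers back into the parent sets every cycle kept re-injecting
cycle-zero genetics, which held additive variance flat and suppressed the
response — contradicting the expected variance decay under both drift and
selection. `TRAD_RRS_UP` replaces each pool's testers every cycle with the
parents of that cycle's three best hybrids (the same rule that seeded the
cycle-zero testers); the alternative reading — ranking lines by mean
testcross-progeny performance — is effectively progeny-testing GCA
selection of testers and made tester updating implausibly strong.

Genomic schemes genotype the L lines per pool at the 996 SNPs, deduce all
L × L hybrid profiles from the parents, predict them with RR-BLUP (A or
A+D kernel), realize and phenotype the top HO = 6L by predicted value,
and select parents and the released hybrid by prediction, never phenotype.
Prediction ties (common once the panel is exhausted within pools) are
broken in random order; if the realized set exposes fewer than P unique
parents on a side, the remainder is filled from that pool's lines ranked
by marginal predicted value. The training set follows the
grandparents–parents–offspring rule: the newest HO hybrids enter each
cycle and only the last three cycles are kept.

## RR-BLUP

Phenotypes are centred on the training mean (intercept-only fixed
effects); marker codes are {−1, 0, +1} additive and {0, 1, 0} dominance,
columns uncentred. The additive ridge parameter λ = σ²_e/σ²_u is
estimated by maximizing a REML-type profile likelihood over the
marker-to-residual variance ratio, computed from one eigendecomposition of
Z′Z per fit with n − 1 degrees of freedom; the search is on log-ratio in
[−16, 12] (Brent, bounded). For the A+D model the two ratios come from two
one-kernel profiles (additive on G, dominance on T) — the conventional
pair of separate one-kernel solutions — and the effects then solve the joint
two-block mixed-model equations, which avoids the inconsistency of
separate solutions when G′T ≠ 0 and reduces to them exactly when G′T = 0.
Because every needed statistic is a sum over training hybrids, per-cycle
cross-product blocks are cached and reused as the window slides. Fixing λ
(and λ_d) directly bypasses the profile and is used by the
normal-equation oracle tests. Monomorphic markers are retained with zero
effect; an identically zero kernel raises an error.

## Metrics

* mean/best true genetic value of the realized (HO) hybrids;
* within-pool additive variance: variance over the pool's L lines of
  breeding values Σ α_i x_i with α = a + (q − p)d at the pool's current
  frequencies;
* accuracy on the realized HO set: corr(true, predicted) for genomic
  schemes, corr(true, phenotype) for phenotypic ones, 0 by definition for
  DRIFT. Because the realized set is the top slice of the prediction
  ranking, genomic accuracy is range-restricted — it drops sharply from
  the training-set cycle and hovers low, which is precisely the
  decline-then-plateau pattern expected of this estimator (accuracy over
  the full unselected L × L grid is roughly 0.5 at the first cycle);
* F_ST between the pools' lines at the SNP panel: Hudson estimator,
  ratio-of-sums across loci, loci monomorphic in both pools excluded,
  negative multi-locus estimates clipped to 0 (Weir–Cockerham is available
  as an option). Allele counts use 2n haplotypes; fully inbred lines make
  the two haplotypes of an individual identical, which mildly overstates
  the effective sample size — immaterial at n ≥ 64 lines;
* relative gain between two arms: contrast of replicate-mean values at a
  chosen cycle, (m₁ − m₂)/m₂; the gain-from-cycle-0 contrast
  ((g₁ − g₂)/g₂ on gains) is also available. For the tester-updating
  comparison the two differ a lot: static testers freeze one side of every
  testcross, so roughly half of each cycle's genetic progress is invisible
  in the testcross mean, deflating the denominator of the gain-based
  contrast (~110%) relative to the value-based one (~42%).

Undefined metrics (zero-variance correlations, all-monomorphic F_ST) are
recorded as missing and excluded pairwise from aggregation.

## Study conditions and problem sizes

The full study design is 20 cycles × 100 replicates per arm. The package
runs any replicate count; the shipped experiment scripts and tests use 10
replicates of 20 cycles — enough for the qualitative orderings and
relative gains to stabilize at desk scale — with the five schemes compared
at size I and the size-III contrast arms (TRAD, TRAD_UP, GS_A) added. A
replicate's founder panel, trait, base population and burn-in are shared
across arms (streams: master seed → replicate → stage), so arm contrasts
are paired; arms diverge only through their own selection randomness.

## Numerical and degenerate-input choices

Haplotypes are uint8; dosage sums are explicitly widened before centring.
Selection rankings use stable argsort on continuous keys (ties have
probability zero except in degenerate prediction collapse, handled above).
Population variance (ddof 0) is used for calibration and additive
variance. Calibration rejects a reference whose genetic variance is zero
to machine precision. The VCF export writes positions as round(cM × 10⁴),
bumped minimally to keep per-contig positions strictly increasing.

## Known limitations

* Weak founder LD and an unascertained SNP panel (above) put the genomic
  schemes at a disadvantage a real chip would not face: in this simulator
  `TRAD_RRS_UP` matches or slightly exceeds `GS_A_RRS` in long-run mean
  hybrid value, whereas with stronger marker information genomic
  prediction is expected to lead; the gap between either and static-tester
  `TRAD_RRS` (≈40–55% at cycle 20) is robust.
* No epistasis, single trait, no genotype-by-environment interaction, no
  calendar/cost model, no male-sterility genetics (CMS conversion is a
  role flag).
* Variance components are re-estimated each cycle from selected
  (truncated) training data, which biases marker variance downward; this
  mirrors what a real program would do, but it accelerates the late-cycle
  collapse of prediction accuracy once within-pool panel variance is
  exhausted.
* Passing tests demonstrate internal consistency of the simulator and
  reproduction of the modeled breeding program's qualitative behavior, not forecasts
  for any particular real breeding program.
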