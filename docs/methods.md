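# Methods

## The screen model

`tnscreen` analyses a pooled fitness experiment: a saturating transposon
mutant library enters growth arrest, and each gene's insertion mutants
either persist (neutral), die off (longevity-defective) or resume growth
(positively selected). Sequencing reads report the relative abundance of
viable mutants — an outgrowth step before library preparation means dead
cells never contribute DNA — so a gene whose mutants die falls out of the
read distribution over the post-arrest time course.

The statistical core treats each sample's per-gene log₂ RpK values as
draws from a common null distribution plus outliers. The null is estimated
by fitting a Gaussian to the log₂ RpK histogram rather than by sample
moments, which makes the location/scale estimate track the bulk of the
distribution and resist the very outliers the screen is looking for. A
gene is non-neutral in a sample when it falls outside the two-tailed
α = 0.05 band (|z| > 1.959964) of that fitted Gaussian, and a consensus
requires the same call in both biological replicates — squaring the
per-tail rate, so the nominal per-timepoint consensus false-call rate is
(α/2)² = 6.25×10⁻⁴ under replicate independence.

### Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `head_frac` / `tail_frac` | 0.05 / 0.10 | fraction of gene length | positional trim of gene termini before read totalling; a site exactly at 5% is discarded, exactly at 90% kept |
| `alpha` | 0.05 | — | two-tailed band for per-sample classification |
| `bin_width` | 0.25 | log₂ RpK | histogram resolution for the Gaussian fit; fine enough to resolve σ ≈ 1–2 over thousands of genes |
| `pseudocount_reads` | 0.5 | reads | applied only when a gene's central total is 0, so log₂ RpK stays finite and total depletion classifies as reduced |
| `reduced_window` | {3, 7, 14} | days | timepoints whose reduced consensus admits a gene to the longevity set; day 30 is reported but excluded because takeover mutants dominate late reads |

Trimming is interpreted positionally (drop sites in the terminal 5%/10%
of the gene's length), the standard Tn-seq practice of excluding termini
where insertions often leave function intact; the alternative reading —
trimming the extreme 5%/10% of sites ranked by count — is not implemented.

### Numerical choices

The Gaussian is fitted as A·exp(−(x−μ)²/2σ²) at bin centres with
`scipy.optimize.curve_fit` (xtol/ftol 1e-8), initialised from sample
moments, with σ kept positive by optimising log σ. The first bin is
centred on the observed minimum so that values on a regular grid land at
bin centres; symmetric data therefore give an exactly centred μ. Degenerate
inputs (under 30 finite values, zero spread, fewer than four populated
bins) and optimiser non-convergence raise typed errors carrying
diagnostics — there is no silent fall-back to moments. A gene absent from
one replicate's table at a timepoint is treated as neutral there
(conservative: absence is indistinguishable from upstream filtering), and
the per-sample Gaussian is always fitted to every gene present in that
sample before any exclusion list is applied; exclusions only filter the
final gene set.

## What the synthetic generator emulates

`build_pool`/`simulate_abundances`/`sample_reads` reproduce the population
structure the analysis assumes, at study scale by default: 4,836 genes,
~36 insertion sites per gene (~175,000 mutants), 117/4836 of genes
longevity-defective, sequencing depth 2×10⁶ reads per sample, two
replicates at 0/3/7/14/30 days.

* **Dynamics** are exponential with constant per-phenotype rates —
  a(t) = a(0)·e^(∓rate·t) — the simplest kinetics consistent with
  post-arrest die-off and takeover. Defaults: die-off 0.2/day (≥16-fold
  depletion by day 14), takeover growth 0.3/day (pool dominance by day
  30). The pre-arrest growth phase is not simulated; exclusion lists are
  the mechanism for growth-phase effects.
* **Library structure**: insertion density is constant per bp (site count
  scales with gene length, as in a saturating library) and a gene's
  initial abundance is proportional to its length, split equally over its
  sites, so expected RpK is uniform across genes under the null.
* **Sequencing** is a multinomial draw of the requested depth over viable
  abundance proportions, per (timepoint, replicate). Outgrowth is treated
  as exact proportional amplification — a no-op on proportions.
* **Replicate noise**: before each draw, every gene's abundance is
  perturbed by an independent log-normal factor (default sd 1.0 log₂
  units), emulating biological replicate-culture and outgrowth variation;
  this is what gives the log₂ RpK distribution its realistic σ ≈ 1 spread.
  The factor is drawn per gene, not per site, which keeps the null spread
  homogeneous across genes.
* **RNA-seq**: negative-binomial counts with mean = baseline·fold·library
  scaling and a single dispersion parameter (default 0.05); baselines are
  log-normal around 600. The default truth table plants 257 repressed and
  120 induced genes with final folds log-uniform in [12, 100], fully
  established by the first post-arrest sample (matching the rapid
  transcriptional shutdown of carbon-starved cells).

What the generator does **not** model — and hence what passing tests do
not show about real data: insertion-site bias and local sequence effects,
outgrowth bottlenecks and plating jackpots, PCR duplication, batch effects
between replicates, genes with correlated phenotypes (operons), partial
loss-of-function insertions, and any compositional coupling between genes
beyond the shared multinomial denominator.

## Calibration and known limitations

* **Sparse libraries inflate the consensus null rate.** Positional
  trimming removes a binomially varying fraction of each gene's *fixed*
  site set; the induced per-gene log₂ offset is shared across replicates
  and timepoints. At ~36 sites/gene the offset variance is negligible and
  the observed all-neutral consensus reduced rate matches (α/2)² within
  binomial 99% bounds; at ~10 sites/gene it roughly doubles the nominal
  rate. Screens on sparse libraries should widen α or pool sites before
  trusting the nominal calibration.
* **RPKM composition bias.** When induced and repressed sets are very
  unbalanced, estimating library size from column sums distorts ratios
  (the 180 h library nearly doubles when 120 genes rise ~35-fold); with
  known library scalings the filters recover planted folds ≥ 20 with
  recall and precision ≥ 0.95. Pass explicit `library_sizes` when they
  are known, or supply pre-normalised tables.
* **The day-30 takeover share depends on pool size**: the same 0.3/day
  mutant reaches ~89% of reads in a 2,000-gene pool but ~50–70% at 4,836
  genes, because the neutral background scales with pool size.
* The fitted σ slightly underestimates the sample SD when the underlying
  distribution is a scale mixture (peakier than Gaussian); the effect is
  ~1% at defaults and is covered by the fit-oracle test tolerance.
* Enrichment assumes single-category annotation (a partition);
  multi-label annotations are rejected at load. The census reports only
  fold ratios; the optional Fisher exact test is an extension, off by
  default.

## Problem sizes used in the test suite

Tests run scaled-down but structurally faithful conditions: 500–1,000-gene
pools for unit/property tests, 2,000 genes for planted-recovery and
takeover checks, 4,800 genes × 5 seeds for null calibration, and the
full 4,836-gene screen in the acceptance script — all at the saturating
insertion density (~36 sites/gene) and depth 2×10⁶ where calibration
matters.
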