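# Methods

## The two-phase model of ageing

`smurfdeconv.twophase` implements a demographic model in which every
individual lives through two consecutive phases: a healthy phase with
essentially zero mortality, followed by a terminal frail phase — the
"Smurf" phase, named after the intestinal-permeability dye assay that
identifies it in flies — with a constant force of mortality `h`
(day⁻¹).  Three consequences define the model's signature:

1. the median remaining lifespan after the transition is `ln 2 / h`,
   independent of the age at which the transition happened (the
   exponential phase is memoryless);
2. every death occurs in the Smurf state;
3. population survival is driven entirely by the rising Smurf
   prevalence `p(t)` among live individuals:
   `S(t) = exp(−h ∫₀ᵗ p(u) du)`, which for the linear approximation
   `p(t) = a·t + b` (clipped to [0, 1]) gives
   `S(t) = exp(−h (a t²/2 + b t))`.

The Smurf-transition hazard family is `λ(t) = c·t` by default, with a
constant-hazard mode (`λ = c`).  Under the linear hazard the quasi-steady
prevalence is `p(t) ≈ c·t/h`, i.e. close to linear over mid-life — the
regime the linear approximation targets; the default `c = 0.0015 day⁻²`
with `h = ln 2 / 2.04 day⁻¹` puts the fitted prevalence slope at
≈0.0044/day, inside the 0.0009–0.0055/day range longevity screens
report.  The default `h` is calibrated so the Smurf median remaining
lifespan is 2.04 days.

Simulation draws transition ages by inverse-CDF sampling of the
cumulative hazard (`Λ(t) = c t²/2 ⇒ t = √(2E/c)`, `E ~ Exp(1)`) and
Smurf-phase durations from `Exponential(h)`; a deterministic
two-compartment ODE (`n_NS' = −λ n_NS`, `n_S' = λ n_NS − h n_S`) serves
as the oracle the stochastic cohort is tested against.  Time is in days
throughout; daily observation grids by default.

## The synthetic experiment generator

`smurfdeconv.synth` emulates the study design the analysis assumes: 16
Smurf and 16 age-matched non-Smurf whole-body samples at 20/30/40 days
(5/6/5 per age per state), ~15,364 genes, raw negative-binomial counts:

    E[count_gj] = s_j · μ_g · 2^( βS·S_j + βA·d_j + βI·S_j·d_j ),
    Var = μ (1 + α μ),     d_j = (age_j − 20)/10

with gene classes `smurf_up`/`smurf_down` (~19.6 % of genes, split
54/46 up/down), `age_linear` (~2 %, both states), `old_smurf_interaction`
(a Smurf-only, age-proportional effect), and `null`.  Effect sizes:
`|βS|` has a Gamma body with mean ≈0.7 plus a 5 % tail ≥ 2 log2 units
(the antimicrobial-peptide-like strong responders); `|βA|` and `|βI|`
are Gamma with means 0.6 and 0.8 per decade.  Age-linear genes are 69 %
positive; interaction genes 75 % negative (old-Smurf changes are mostly
downward).

Dispersion grows with age, `α_g(age) = α_g0 (1 + γ (age−20)/20)` with
`γ = 3`, quadrupling between day 20 and 40, which doubles the
high-expression RSD (`RSD² ≈ 1/μ + α`).  Baseline means and dispersions
(`μ ~ LogNormal(log 2500, 1.2)`, `α₀ ~ LogNormal(log 0.002, 0.6)`) are
calibrated so the RSD density peaks sit near 0.04–0.05 at day 20 and
0.07–0.09 at day 40 — the very low noise floor of pooled 8-fly samples —
giving an old/young peak ratio near 1.9.  Size factors are
LogNormal(0, 0.1) so normalization always has real work to do.

Hallmark tags ATH1–ATH6 mark coherent 60-gene subsets: ATH1–2 among
Smurf-upregulated genes (inflammation, stress response), ATH3–4 among
Smurf-downregulated genes (metabolism, protein synthesis), ATH5–6 among
downward interaction genes (cell cycle, gene-expression dysregulation).
Decoy gene sets contain only null genes.  `hours_since_transition` is
metadata-only (collection times are pooled).

What the generator does **not** emulate: pooling-of-8-flies variance
decomposition, batch effects, gene–gene correlation, length/GC bias,
outlier samples, and real dispersion–mean relationships beyond the
`a₀ + a₁/μ` family.  Passing tests therefore show estimator correctness
and calibration under the stated model, not robustness to those
real-data features.

## Differential expression

`smurfdeconv.de` normalizes with median-of-ratios size factors and
fits, per gene, a negative-binomial GLM (log link, size-factor offset)
batched across genes with IRLS.  Dispersion: method-of-moments from a
Poisson pilot fit, a `α(μ) = a₀ + a₁/μ` trend fitted to the central 90 %
of moment estimates, then log-space shrinkage toward the trend with
weight 0.5 — asymmetric: estimates **above** the trend are kept
(shrinking dispersion outliers down inflates test statistics).  The
contrast coefficient's Wald statistic is referred to a t distribution
with residual df; at n = 32 with estimated dispersion the normal
reference is measurably anticonservative in the far tail (BH false
rejections appear on all-null data).  Genes with mean normalized count
< 1 are flagged `tested = False`; BH runs across tested genes only.  No
fold-change shrinkage: log2FC is plain MLE with its standard error.

The concordance variant (`nb_quasi_test`) uses the trended dispersion
only, absorbs per-gene over/under-dispersion into a quasi-dispersion
(Pearson χ²/df, moderated toward its mean with 10 prior df) and refers
the squared statistic to an F distribution.  The two variants share the
data but differ in dispersion handling and reference distribution; call
overlap and log2FC concordance between them are reported by the
acceptance script.

## Preranked gene-set enrichment

`smurfdeconv.enrichment` ranks tested genes by the Wald statistic
(descending, ties broken lexicographically by gene id) and computes the
classic weighted KS running sum: hits advance by `|score|^w / Σ_hits`,
misses retreat by `1/(N−k)`; the ES is the extremum of larger absolute
value, with the positive extremum preferred on exact ties.  The null is
gene-label permutation (random same-size sets of ranked positions);
same-size sets share one null, which also makes runs order-independent
under a seed.  NES divides ES by the mean |null ES| of matching sign;
p-values are sign-stratified tails with a +1 pseudocount (so
`p ≥ 1/(nPerm+1)`), BH-adjusted across sets.  Defaults: `w = 1`,
`nPerm = 15,000`, set sizes 10–600.  On a mixed-signal universe,
null-gene decoy sets are conservative (random same-size sets include
signal genes, widening the null), so decoy-uniformity calibration is
checked on all-null data.

## Deconvolution statistics

All downstream statistics use `log2(normalized + 1)` expression (a
variance-stabilizing transform substitutes for the vst the analyses are
usually run on; the properties tested here are transform-robust).

- **PCA factor association** — components from the centred matrix of
  the 1000 top-variance genes; PC scores associated with Smurfness by
  one-way ANOVA (η² and p) and with age by Pearson correlation.
- **Interaction scan** — per-gene OLS of expression on Smurfness, age
  (decades) and their product; per-coefficient t tests with BH within
  each coefficient family; the age-growing dispersion makes the state
  coefficient mildly conservative and the interaction mildly liberal
  (±2 points around the nominal 5 %), a documented heteroskedasticity
  effect.
- **Age regression (non-Smurfs)** — per-gene regression on age in days;
  a gene passes iff F-test p < 0.05 **and** R² > 0.5; partitioned by
  slope sign; overlap with the Smurf DEG list reported.
- **RSD noise** — per (state, age) group, RSD = sd/mean of normalized
  counts; the distribution's peak is the mode of a Gaussian KDE
  (Silverman bandwidth, 512-point grid on [0, max]; the 0.6 cap is for
  display only); pairwise two-sample KS between age groups within each
  state; old/young peak ratios per state.
- **Fasano–Franceschini test** — 2-D two-sample KS: at every data point
  of the conditioning sample, the largest |quadrant-fraction difference|
  over the four orientations and both boundary closures (at the point
  and its left limit); D averages the two conditioning-sample maxima.
  The double closure makes D = 1 for completely separated clouds and
  collapses D exactly to the 1-D KS distance when one coordinate is
  constant.  An O(n log n) Fenwick-tree sweep (numba) makes the
  permutation p (default 2000 label permutations) affordable against a
  whole-transcriptome background.  Degenerate all-identical input
  returns D with p = 1 and a warning.
- **Correlation map** — per gene, `r_smurf` (point-biserial, Pearson on
  the 0/1 state) and `r_age` (Pearson on age in days); each gene set's
  member cloud is compared with the non-member cloud by the FF test
  (sets with < 10 members dropped), BH across sets.
- **Hallmark attribution** — a hallmark's sets are looked up in three
  enrichment runs (Smurf vs non-Smurf; old vs young Smurf; old vs young
  non-Smurf) at q < 0.05.  Precedence: old-Smurf significance wins
  (an age-modulated signature is `old_smurf` even when the pooled state
  contrast also sees its diluted shift, which it typically does), then
  `smurf_specific`, then `chronological`, else `none`.  The noise facet
  of the heterogeneity hallmark is `chronological` when the old/young
  RSD peak ratio exceeds 1.5 in both states.
- **Mixture projection** — `(1−p)·μ_NS + p·μ_S`: the expectation an
  unlabeled sample actually measures.  A state-only gene in unlabeled
  samples with rising prevalence acquires a spurious age slope
  ∝ βS·dp/dt that disappears when samples are stratified by state —
  the confounding the two-phase decomposition removes.  Note the
  demonstration needs state-shifted genes to be a minority: if every
  gene shifts, median-of-ratios normalization absorbs the mixture
  effect entirely.

## Longevity statistics

Mean lifespan is `Σ day·deaths / Σ deaths` from complete death tables
(no censoring in v1); percent change vs a designated control is rounded
to one decimal.  Survival curves are right-continuous steps.  Smurf
prevalence (`n_smurf/n_alive`) is regressed on age per condition by OLS
(the conventional plain linear fit), with an `n_alive`-weighted mode;
the joint model adds condition dummies and condition × age interactions
(condition categorical), and a significant negative interaction is the
delayed-Smurf-entry readout.  Degenerate zero-residual fits report
p = 1 for a zero slope.

### Power of the interaction test: a known limitation

At the screen's size (150 flies/condition, weekly counts over 60 days)
the interaction test cannot reach 80 % power for a 2× slope difference
anywhere inside the 0.0009–0.0055/day slope range: the ideal
(independent-binomial, optimally weighted) z for the slope difference
is ≈2.4, i.e. ≤ ~65 % power at α = 0.05, and cohort serial correlation
lowers the realized power to ~0.45–0.55.  The machinery itself is fine
(power = 1.0 at n = 5000/condition); the limit is informational.  The
acceptance script reports the measured power; the corresponding
acceptance test is expected to fail and is left in place.  Real screens
detect ~3–5× slope differences, which are comfortably inside reach.

## Problem sizes and numerical choices

The test suite and acceptance script run the full method at these
sizes, chosen as this package's standard desk-scale configuration:
cohorts of 10⁵ individuals for demographic checks and 150/condition for
screen emulation (200 bias replicates, 100 power replicates); the full
15,364 × 32 bundle for recall, concordance, PCA, RSD and hallmark
attribution; 20 × 2000 all-null genes for FDR calibration; 50 seeds ×
4 decoy sets at nPerm = 2000 for GSEA calibration (the production
default stays 15,000).  IRLS runs at most 60 iterations to Δβ < 1e-10
with a 1e-10 ridge on the normal equations; η is clipped to ±30;
dispersions to [1e-8, 10].  All randomness flows through
`numpy.random.default_rng`; the pipeline spawns per-stage seeds from
the master seed via `SeedSequence` in a fixed stage order.

## Known limitations

- Per-gene dispersion estimation is moment-based with a parametric
  trend; no Cox–Reid adjustment, so dispersions are slightly biased at
  small n (the asymmetric shrinkage and t reference compensate at the
  calibration level).
- The OLS interaction scan ignores the mean–variance relation of
  counts; it is a screening tool, not an inferential replacement for
  the NB contrasts.
- Censoring, vial effects and dose–response structure are out of scope
  in the longevity module.
- GMT descriptions are not preserved through the pipeline; enrichment
  is preranked-only (no phenotype permutation).
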