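# smurfdeconv

Deconvolving what ageing does to the transcriptome from what the end of
life does to it.

In *Drosophila*, a blue-dye assay for intestinal permeability splits any
ageing cohort into two subpopulations: healthy "non-Smurf" flies with
near-zero mortality, and "Smurf" flies in a terminal high-mortality
phase with a short, age-independent remaining lifespan (median
≈ 2 days).  Because the Smurf fraction among live flies rises with age,
bulk measurements on unlabeled animals mix the two states in
age-dependent proportions — and transcriptional changes that belong to
the Smurf state get misread as gradual effects of chronological age.

`smurfdeconv` packages the statistics needed to take this apart, for
people who work with two-phase mortality models or age-by-state bulk
RNA-seq designs:

- **`twophase`** — the two-phase demographic model: closed-form
  survival `S(t) = exp(−h(a t²/2 + b t))` under a linear Smurf
  prevalence `p(t) = a t + b`, the mechanistic two-compartment ODE, and
  stochastic cohort simulation (transition hazard `λ(t) = c·t` or
  constant; Smurf mortality `h` constant, so Smurf T50 = ln 2 / h).
- **`synth`** — a generator for the full study design (16 Smurf + 16
  non-Smurf samples at days 20/30/40, ~15k genes) with explicit
  per-gene ground truth: state effects, age effects, old-Smurf
  interaction effects, and a dispersion that quadruples from day 20 to
  40 (transcriptional noise).
- **`de`** — negative-binomial GLM differential expression (Wald test,
  trended + shrunk dispersion, BH FDR) plus an independent
  quasi-likelihood variant for concordance checks.
- **`enrichment`** — preranked GSEA written from first principles:
  weighted KS enrichment score, gene-label permutation null, NES,
  sign-stratified permutation p, BH q, leading edges.
- **`deconvolve`** — the separation statistics: PCA factor
  association, per-gene Smurfness × age interaction models, the
  non-Smurf age regression with F-test/R² filters, RSD
  transcriptional-noise analysis, the per-gene (r_smurf, r_age)
  correlation map tested set-by-set with a Fasano–Franceschini 2-D KS
  test, hallmark (ATH1–6) attribution, and the mixture projection that
  demonstrates the confounding directly.
- **`longevity`** — mean-lifespan summaries, survival curves, and
  Smurf-prevalence regression with a condition × age interaction (the
  delayed-Smurf-entry test).
- **`pipeline` / CLI** — `smurfdeconv {simulate-cohort, simulate-counts,
  de, gsea, deconvolve, longevity, run, validate}` with a YAML config,
  derived per-stage seeds, and a text report.

## Worked example

```python
import numpy as np
from smurfdeconv import synth, de, enrichment, deconvolve, longevity, twophase

# Demography: the Smurf phase is short and memoryless
params = twophase.TwoPhaseParams()           # h = ln2/2.04, lambda(t) = 0.0015 t
cohort = twophase.simulate_cohort(params, n=100_000, horizon=80, seed=1)
ind = cohort.individuals
t50 = (ind.death_age - ind.smurf_entry_age).dropna().median()
print(f"Smurf median remaining lifespan: {t50:.2f} days")

# A synthetic 16+16 experiment with known gene classes
truth = synth.generate_gene_truth(n_genes=6000, seed=11)
expt = synth.simulate_counts(truth, seed=12)
res = de.nb_wald_test(expt.counts, expt.meta, contrast="smurf")
print(f"Smurf vs non-Smurf DEGs (q<0.05): {len(res.significant())}")

sets, hallmark_map = synth.build_genesets(truth, seed=13)
enr = enrichment.gsea(res, sets, n_perm=2000, seed=14)
print(enr.table[["set", "size", "nes", "q", "direction"]].head(4).to_string(index=False))

noise = deconvolve.rsd_analysis(expt.counts, expt.meta)
print(f"RSD peak ratio 40d/20d, non-Smurfs: {noise.peak_ratios[0]:.2f}")
print(f"Percent ML change 72.2 -> 79.8 days: {longevity.percent_change(72.2, 79.8)}%")
```

prints

```
Smurf median remaining lifespan: 2.01 days
Smurf vs non-Smurf DEGs (q<0.05): 1752
     set  size       nes        q direction
ATH1_set    60  1.994771 0.005437        up
ATH2_set    60  2.002527 0.005437        up
ATH3_set    60 -2.086396 0.005437      down
ATH4_set    60 -2.097975 0.005437      down
RSD peak ratio 40d/20d, non-Smurfs: 1.91
Percent ML change 72.2 -> 79.8 days: 10.5%
```

The Smurf median remaining lifespan matches its ln 2/h calibration
(2.04 days); inflammation/stress sets (ATH1–2) come out upregulated and
metabolism/protein-synthesis sets (ATH3–4) downregulated in Smurfs; the
transcriptional-noise peak roughly doubles between day 20 and day 40;
and a 72.2 → 79.8 day mean-lifespan shift is a +10.5 % extension.

An end-to-end run (simulate → DE → GSEA → deconvolve → longevity →
report) is one command:

```bash
smurfdeconv run --outdir run1 --seed 3
cat run1/report.tsv        # DEG counts, hallmark attribution, lifespans
```

On default synthetic data the report attributes hallmarks ATH1–4 to the
Smurf state, ATH5–6 to old Smurfs only, and the rise in
expression heterogeneity to chronological age.

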