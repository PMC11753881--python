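# evquant

Quantitative characterization of bacterial extracellular vesicles (EVs) —
the membrane-bounded particles that Gram-negative bacteria such as the
marine cyanobacterium *Prochlorococcus* release into their environment.
`evquant` is for microbiologists and proteomics analysts who have the
standard measurements of an EV study — electron-microscopy axis
measurements, nanoparticle-tracking (NTA) particle diameters, label-free
protein intensity matrices, and diel (light–dark) time-course
concentrations — and want the downstream numbers: shape scores, size-peak
calls, enriched-protein lists, and phase-resolved net-production statistics.

## What it computes

**Morphometry.** Each vesicle's longer diameter *a* and shorter diameter
*b* give a shape score *e* = 1 − *b*²/*a*² (0 for a sphere, ≥ 0.5 called
elliptical). Population summaries report mean ± s.d. and the elliptical
fraction. The classical form √(1 − *b*²/*a*²) is available behind a flag.

**NTA size distributions.** Per-particle diameters from technical
replicates are binned (1 nm default), scaled so each replicate's density
integrates exactly to its dilution-corrected concentration, averaged with a
t-based 95% confidence band, and peak-called on a smoothed density.
`evs_per_cell` normalizes EV counts to the source culture.

**Proteomic enrichment.** Intensities are converted to per-sample
proportions (each protein as a fraction of its sample's total). Proteins
with ≥ 2 valid values per group are *identified* there; the presence
partition yields shared/unique (Venn) counts. Shared proteins get a
volcano: log₂ of the ratio of group-mean proportions versus a two-sided
equal-variance Student's *t*, with enrichment called at |log₂FC| > 0.58 and
*p* < 0.05. A second path for paired-timepoint designs (DUSK vs DAWN EV
preparations bracketing one night) log-transforms, imputes left-censored
missing values (down-shifted Gaussian, 1.8 s.d. shift, 0.3 s.d. width), and
applies an empirical-Bayes moderated *t*

  t̃_g = (x̄_g2 − x̄_g1) / ( s̃_g · √(1/n₁ + 1/n₂) ),
  s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),

with the prior (d₀, s₀²) estimated by moment matching on log s²_g; it is
cross-checked against the Bioconductor reference implementation in the test
suite.

**Diel production.** From EVs-per-cell ratios at three chronological
sampling points (t₁ just after lights-on, t₂ just after lights-off, t₃
after the next lights-on): light_net = (t₂ − t₁)/t₁ and
dark_net = (t₃ − t₂)/t₂, compared with a paired *t* across biological
replicates, plus a two-sample contrast of dark_net between control and
division-arrested (TBZ-treated) cultures.

**Annotation summaries.** Abundance-weighted COG category proportions
(multi-letter proteins split equally), GO-term percentages over a protein
list, and localization percentages, each with an explicit unannotated
bucket.

**Synthetic data.** Seeded generators for all four input kinds (log-normal
proteomes with planted effects and abundance-dependent dropout, a phased
growth/secretion/uptake diel model, axis-ratio mixtures, Gaussian-mixture
particle sizes) so the whole pipeline runs and is testable without any
instrument data.

## Worked example

Everything is reachable from the `evquant` command. Simulate each input at
a fixed seed and run the matching stage:

```sh
evquant simulate --kind morphometry --seed 11 --out demo/sim
evquant morphometry --input demo/sim/morphometry.tsv --out demo/morph
# n=52 mean_e=0.587 sd=0.306 fraction_elliptical=0.692

evquant simulate --kind nta --seed 11 --out demo/sim
evquant nta --particles demo/sim/particles.tsv \
            --scales demo/sim/particle_scales.tsv --out demo/nta
# peaks: 76.5 nm, 110.5 nm

evquant simulate --kind diel --seed 11 --out demo/sim
evquant diel --input demo/sim/diel.tsv --out demo/diel
# control: light=-0.202 dark=+0.446 p=0.0189
```

Reading the output: of 52 simulated vesicles the mean shape score is 0.587
with 69% above the 0.5 cutoff — a mostly elliptical population. The NTA
stage localizes the two planted size modes (77 and 110 nm) to within half a
bin. The diel stage shows EVs per cell falling ~20% over the light phase
and rising ~45% over the dark phase; the paired test on three simulated
replicates already separates the phases (p ≈ 0.02).

The same operations are available as a library:

```python
from evquant import eccentricity, ProteomeSimConfig, simulate_proteome, dusk_dawn_analysis

eccentricity(200, 100)          # 0.75
cfg = ProteomeSimConfig(n_proteins=777, n_replicates_per_group=4,
                        n_enriched_group1=24, n_enriched_group2=11,
                        log2_effect=2.0, noise_cv=0.05,
                        missing_logit_intercept=-50.0, seed=1)
matrix, truth = simulate_proteome(cfg, group_names=("DUSK", "DAWN"))
res = dusk_dawn_analysis(matrix, seed=1)
res.n_differential              # 35 (24 more enriched in DUSK, 11 in DAWN)
```

Each CLI stage writes its result tables as TSV under `--out` together with
a `run.log` recording the resolved parameters.

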