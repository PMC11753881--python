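# Methods

This note documents the statistical procedures, the synthetic-data model
behind the tests, the numerical choices, and what the test suite does and
does not demonstrate.

## Shape scoring

The per-vesicle score is *e* = 1 − *b*²/*a*² from the longer (*a*) and
shorter (*b*) diameters. This is the *square* of the textbook ellipse
eccentricity; it is the reporting convention in the EV literature this
package follows, and both forms are exposed (`textbook=True` for the
square root). The score is scale-invariant (unit-free) and lies in [0, 1);
the elliptical/spherical cutoff (default 0.5, boundary inclusive) is a
classification convention, not a statistical threshold. Population s.d.
uses the n − 1 denominator; a single measurement reports s.d. 0 with a
degenerate flag rather than NaN.

## NTA size distributions

Each technical replicate's diameters are histogrammed on a common grid
(default 1 nm) and scaled so the replicate's density integrates exactly to
its dilution-corrected concentration — an invariant the tests check
bin-by-bin. The replicate mean gets a per-bin t-interval (95% default),
which collapses onto the mean for a single replicate. Peak calling runs on
a centered moving average (default 5 bins) of the mean density and keeps
local maxima whose prominence is ≥ 10% of the global maximum; peaks are
reported at bin-center resolution, ascending.

Localizing a Gaussian mode to ±1 bin at 1 nm bins is noise-limited: near
the mode the density is flat (the density 2 nm off a mode with 8 nm spread
is only ~3% lower), so the peak position fluctuates by several nm unless
per-bin counts are large. A measured power analysis put ±1 nm recovery of
two modes at 77/110 nm (8 nm spreads, 3 replicates) at ~58% success with
5 000 tracks per replicate and at ~100% with 50 000; the planted-recovery
tests therefore use 50 000 tracks per replicate, which is within the range
a concentration-weighted NTA acquisition accumulates over its video frames.
Larger bin widths or wider smoothing would relax this requirement at the
cost of resolution.

## Proportion normalization and the volcano path

Intensities are divided by their sample's total over detected proteins, so
each sample's detected proportions sum to 1. This makes samples
compositionally comparable but has a known consequence: boosting one set of
proteins in one group deflates every other protein's proportion in that
group. With asymmetric planting (e.g. 217 proteins boosted 4-fold in one
group versus 23 in the other, the default simulation), group totals differ
by ~1.6×, which shifts every null protein's proportion fold change by
~0.7 log₂ units. The simulator therefore plants effects exactly on the
*abundance* scale, and calibration-style checks use balanced planting so
null fold changes center at zero. This compositional behavior is inherent
to the proportion method, not an artifact of the implementation.

Shared proteins (≥ 2 valid values in each group, the default presence
rule) are tested with a two-sided equal-variance Student's *t* on the raw
replicate proportions, unmoderated, matching the few-replicate cell-vs-EV
design this path reproduces. Raw proportions are ratios of (approximately)
log-normal quantities and hence mildly skewed; at n = 3 per group the
nominal 5% test empirically rejects ~5–10% of nulls. The classification
gate (|log₂FC| > 0.58 *and* p < 0.05) keeps false enrichment *calls* near
zero regardless. Proteins whose mean proportion is zero in a group are
excluded as `filtered` rather than given infinite fold changes; exact-tie
zero-variance cases report p = 1 (equal means, `degenerate` flag) or p = 0
(`zero_variance` flag). Ties are detected on exact value equality, not
`var == 0`, because identical inputs can carry ~1e-33 of floating-point
variance. Benjamini–Hochberg FDR is always reported as a column;
classification uses raw p by default (pass `fdr_cutoff` to gate on FDR).
The unpaired test is the default; `paired=True` pairs replicates by column
order.

## Left-censored imputation and the moderated t

The paired-timepoint path (`dusk_dawn_analysis`) log₂-transforms shared
proteins and fills missing cells per sample from
Normal(mean − 1.8·s.d., (0.3·s.d.)²) computed on that sample's observed
values — the down-shifted-Gaussian convention for detection-limit dropout
in label-free MS. Both parameters are exposed; imputed cells are flagged
and the draw is seeded.

The moderated *t* assumes per-protein residual variances s²_g follow a
scaled F distribution around a prior (d₀, s₀²). The prior is estimated by
moment matching on z = log s²_g using digamma/trigamma identities, with
the trigamma inverse solved by Newton iteration; non-positive excess
variance yields d₀ = ∞ (all posterior variances equal s₀²). Posterior
variances s̃² = (d₀s₀² + d·s²)/(d₀ + d) enter the t statistic, whose null
distribution gains d₀ degrees of freedom. Forcing d₀ = 0 reproduces the
ordinary Student's t exactly (tested), and the full estimate matches the
Bioconductor reference implementation to ~1e-14 on a seeded matrix (tested
via Rscript). Under a simulated complete null the p < 0.05 rate stays
within binomial 99% bounds of 0.05 at 1000 proteins, 4 vs 4. Zero-variance
proteins are excluded from prior estimation but still shrunk; an
all-zero-variance matrix is a hard error.

## Diel statistics

The net-production statistic uses EVs-per-cell ratios at three
chronological points: light_net = (t₂ − t₁)/t₁, dark_net = (t₃ − t₂)/t₂.
Both are unit-free and invariant to common rescaling. Sampling points are
matched to requested zeitgeber times within ±0.25 h; intermediate samples
(e.g. ZT 12 and 16) ride along in the series output but do not enter the
statistic. Replicates missing any of the three points are dropped pairwise
with a logged count, and net production is computed per replicate (not
from replicate-averaged ratios). The phase comparison is a two-sided
paired t across replicates; the treatment contrast is a two-sided
two-sample equal-variance t on the chosen phase's net production.
Zero-variance differences report p = 0 (nonzero constant difference) or
p = 1 (identically zero) with a degenerate flag.

## Annotation summaries

COG proportions are abundance-weighted; a protein's abundance is split
equally across its category letters (the alternative full-count mode is
available and documented as inflating the sum above 1). The output
includes an `unannotated` bucket and sums to 1 in the default mode.
GO and localization summaries are percentages over the full protein list;
duplicate ids in a list are rejected. Percentages are kept at full
precision and rounded half-up to whole percent only by the reporting
helper.

## Synthetic-data model

*Proteome*: per-protein base abundance is log-normal (log₂ mean 20,
s.d. 2, a typical label-free intensity range); planted proteins gain the
configured log₂ effect in their group's mean; replicate noise is
multiplicative log-normal with CV 0.1 by default; dropout is Bernoulli
with probability logistic(7.8 − 0.5·log₂ abundance), giving ~13% overall
missingness concentrated in low-abundance proteins. Defaults mirror a
998-protein, 3 + 3 replicate cell-vs-EV design with 217 and 23 planted
effects; the paired-timepoint analyses use 777 proteins, 4 + 4 replicates
and 24/11 planted effects.

*Diel*: deterministic per-phase linear dynamics dC/dt = μC,
dV/dt = sC − uV integrated by explicit Euler (dt = 0.01 h), with phase set
by time modulo 24 h (14 h light : 10 h dark). Default rates
(μ = 0.005/0.07 h⁻¹, s = 0.05/0.35 EVs cell⁻¹ h⁻¹, u = 0.03/0.02 h⁻¹ for
light/dark) place division and most secretion at night, so EVs per cell
fall ~20% in the light and rise ~40% in the dark from a starting ratio of
3. Measurement noise is optional mean-one log-normal per sampled
concentration. The noise level used in tests (CV 0.05) was back-calculated
so the simulated experiments land in the significance regime the real
assays report — a paired contrast at n = 11 typically below p = 10⁻⁴ and a
3-replicate division-arrest contrast around p < 0.05 — rather than from
replicate-level variance data, which the source assays do not provide.
Division arrest is modeled as zero dark-phase growth with dark secretion
reduced to the light-phase rate.

*Morphometry*: the short/long axis ratio is a two-component Gaussian
mixture (means 0.92 and 0.45, s.d. 0.08, 65% elongated), clipped to
(0, 1]; long axes are Gaussian (110 ± 25 nm, floored at 1 nm). These
defaults give 52-vesicle samples with mean e ≈ 0.6 and a majority above
0.5.

*NTA*: diameters are a Gaussian mixture (default 77/110 nm, equal weight,
8 nm spreads) truncated at zero by redraw; per-replicate counts are
Poisson.

All generators draw from one `numpy` Generator seeded per call; identical
configs give bit-identical output, and no global random state is touched.

What the synthetic data does *not* emulate: peptide-to-protein rollup and
shared-peptide ambiguity, correlated (batch) sample effects, heavy-tailed
intensity noise, NTA sizing bias at the small-diameter detection edge,
demographic stochasticity in the diel process, and EV
degradation/aggregation. Passing tests therefore demonstrate the
correctness and calibration of the procedures under their stated
assumptions, not robustness to every artifact of real instrument data.

## Numerical and interface conventions

TSV (tab-separated, UTF-8, header row) is the single table dialect;
missing values are written as empty strings and `""`/`NA`/`NaN` are
accepted on read; floats are written at %.12g so canonical tables
round-trip byte-identically. Reversed morphometry axis pairs are swapped
on read with a warning; nonpositive diameters, duplicate protein ids,
unassigned samples and non-numeric cells are hard errors. "At least two
valid values" is interpreted per group; a flag-free helper for the overall
interpretation was considered and rejected to keep the Venn-unique classes
well defined. Configuration precedence is CLI > YAML file > defaults, and
every CLI stage logs its resolved parameters to `run.log`.

## Known limitations

* The volcano path's t on raw proportions inherits the mild
  anti-conservativeness described above; use the moderated path for
  calibrated inference at small n.
* Peak calling reports bin centers; sub-bin peak interpolation is not
  implemented.
* The diel model has no cell-death or EV-degradation terms, so its
  dark-phase gain is attributable to secretion and division only.
* `presence_partition` and the enrichment paths compare exactly two
  groups; multi-group designs must be analyzed pairwise.
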