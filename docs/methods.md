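# Methods

## Problem and model

`gasam` treats band selection for species discrimination as a wrapper
feature-selection problem. Given a labelled library of leaf emissivity
spectra on a shared wavelength grid (2.5–14 µm), the genetic algorithm
searches over k-element band subsets; the objective is the overall
validation accuracy of a spectral-angle-mapper (SAM) nearest-centroid
classifier restricted to the subset. Separability of the resulting bands
is quantified by the Jeffries–Matusita (J-M) distance between Gaussian
class models and compared with randomly drawn subsets.

Key assumptions:

- **SAM** compares spectral *shape*, not brightness: the angle between a
  spectrum and a class mean is invariant to positive scaling. A corollary
  worth knowing is that band subsets on which two species' spectra are
  proportional (e.g. several bands inside one shared absorption feature
  that differs only in depth) are *not* separable by SAM; discrimination
  requires a shape contrast across the selected bands.
- **J-M** assumes multivariate Gaussian classes. Sample covariances over
  k = 5 bands are estimated from 35 replicates per species (the full
  library, not the training half, to maximise covariance stability) and
  ridge-regularised. Shapiro–Wilk (per species × band) and median-centred
  Levene (per band) checks are reported but never gate the analysis.

## Genetic algorithm

Chromosomes are sorted tuples of k distinct valid band indices.
Per generation: fitness evaluation → elitism (the `elite_count` fittest
copied unchanged) → roulette-wheel parent selection (probability
fitnessᵢ/Σ fitness, uniform fallback if all fitness is zero) →
single-point crossover with probability `pc` → mutation. Design choices
where the procedure is genuinely underdetermined:

- **Crossover on the sorted representation.** "Single point" is only
  well-defined for set-valued solutions once an order is fixed; sorting by
  band index makes cuts spectrally meaningful (low-wavelength vs
  high-wavelength segments recombine).
- **Duplicate repair.** A splice can duplicate a band; each duplicate is
  replaced by a uniformly drawn valid band not already in the child.
- **Mutation is per chromosome** (with probability `pm` exactly one
  uniformly chosen gene is replaced by a fresh valid band), not per gene —
  matching the convention that a single gene of an offspring is altered.
- **Stopping.** `max_generations`, or no strict improvement of the best
  fitness for `plateau_generations = 50` consecutive generations
  (`plateau_epsilon = 0`).
- **Seeding.** One `numpy` generator per run drives everything; the
  repeated-run protocol derives a split seed and a GA seed per run from
  the master seed via `SeedSequence`, so runs are independent and the
  whole protocol reproduces bit-for-bit.

Defaults follow the full-scale protocol (population 1,000, ≤ 500
generations, pc = 1, pm = 0.01, elite 2, 85% fitness threshold). The
shipped study conditions use a *scaled* GA — population 200, ≤ 100
generations — which this package adopts as its standard desk-scale
configuration; with the default fixture, runs converge in ≈ 60
generations and ≈ 1 s.

Winner genes pooled over runs are grouped by 1-D single-linkage
clustering: sorted wavelengths start a new group when the gap to the
previous gene exceeds `gap_um` (default 0.15 µm, configurable — the exact
grouping rule behind published region tables is not standardised). Groups
report count, range, mean, population sd, and a region label (mid infrared
< 6 µm, thermal infrared ≥ 8 µm).

## Synthetic data generator

The generator emulates a laboratory FTIR campaign of 13 broadleaf species
× 35 leaves. Each spectrum is

ε(λ) = baseline(λ) − Σ_f d_f · exp(−(λ−c_f)²/(2 w_f²)) + smooth noise + iid noise,

clipped to [0, 1], with per-leaf depths d_f ~ N(mean depth of the species,
jitter sd). Defaults of the shipped fixture:

- **Grid:** 303 evenly spaced bands over 2.5–14 µm with the 6–8 µm window
  masked (250 valid bands). This is a deliberate desk-scale reduction of a
  ~3,000-band instrument grid (available via `make_grid(3024)`): it keeps
  the GA search meaningful at population 200 while preserving ≈ 0.04 µm
  band spacing, far finer than the 0.1 µm recovery tolerance used in
  tests.
- **Features:** centres 3.44, 5.80, 9.36, 9.87, 11.52 µm (diagnostic
  leaf-surface wavelengths: wax CH₂ stretch, ester carbonyl,
  cellulose/matrix, aromatic), Gaussian width 0.05 µm.
- **Depths:** three levels {0.05, 0.10, 0.15} emissivity units assigned
  per (species, feature) by a fixed ternary code of length 5 with pairwise
  Hamming distance ≥ 3, so every species pair differs in at least three
  features and any three planted features separate all pairs — giving the
  GA a usable gradient and making the five "true" bands well-defined for
  recovery scoring.
- **Noise:** baseline 0.95 with −0.002/µm tilt; depth jitter sd 0.008;
  iid noise sd 0.006; smooth noise sd 0.004 with 0.3 µm correlation scale
  (iid noise convolved with a Gaussian kernel, rescaled to the target sd).
  These values are calibrated, and frozen, such that the SAM on the five
  true bands scores ≈ 98% validation accuracy (comfortably above the 85%
  threshold) while off-feature bands stay at chance (≈ 1/13).

What the generator does **not** emulate: radiative-transfer leaf optics,
cavity effects, wavelength-dependent instrument noise, inter-feature
correlations of real leaf chemistry, or atmospheric effects. Passing tests
on this fixture therefore demonstrate that the search, classifier and
separability machinery behave correctly on data with planted structure —
not that any particular accuracy will be attained on real spectra.

## Numerical choices

- SAM cosine clamped to [−1, 1] before `arccos` (floating-point overshoot
  on near-identical spectra); nearest-angle ties broken alphabetically by
  species code for deterministic fitness.
- Covariance ridge 1e-8·I, escalated ×10 (logged) until Cholesky succeeds;
  log-determinants via `slogdet`.
- Accuracies are percentages reported to two decimals in text output.
- Welch (unequal-variance) two-sample t-test for the GA-vs-random J-M
  comparison — the two chromosome samples are not naturally paired. Raw
  p-values by default; Bonferroni/Benjamini–Hochberg available via
  `adjust_p_values`.
- Emissivity outside [0, 1] is an error on input (it flags corrupted
  data), but clipped (and logged) at synthesis time; masked bands are
  exempt, since real instruments produce out-of-range values in excluded
  windows.
- Odd replicate counts: with 35 leaves and 17 in training, validation is
  trimmed to 17 per species and one leaf is held out unused, keeping both
  halves species-balanced.

## Problem sizes

The test suite and the acceptance script run the 40-run repeat protocol on
the 455-spectrum fixture (≈ 25 s), a 20-run recovery check reusing those
runs, exhaustive-search oracle comparisons on a 12-band instance
(C(12,3) = 220 subsets), and quadrature cross-checks of the Bhattacharyya
coefficient. These sizes are the package's standard desk-scale study
conditions.

## Known limitations

- Fitness-proportional selection on accuracy percentages exerts weak
  pressure when all chromosomes score similarly; the plateau rule and
  elitism, not selection alone, drive convergence late in a run.
- With k fixed and accuracy saturating at 100%, surplus genes drift: a
  winner may carry one or two uninformative bands once four features
  suffice, which is why recovery is scored as "≥ 4 of 5 centres".
- J-M with 5×5 covariances from 35 samples is noisy; the ridge guards
  singularity but small-sample bias remains (a reason the comparison uses
  distributions over chromosomes rather than single values).
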