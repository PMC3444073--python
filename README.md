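# gasam — genetic-algorithm band selection for mid/thermal-IR leaf spectra

Hyperspectral emissivity spectra of plant leaves in the mid and thermal
infrared (2.5–14 µm) carry species-specific absorption features from
leaf-surface chemistry (waxes, cutin, cellulose), but with thousands of
contiguous bands the data are massively redundant. `gasam` implements a
wrapper band selector for this setting: a genetic algorithm (GA) searches
for a small subset of wavelengths that maximises species classification
accuracy, and Jeffries–Matusita (J-M) distances quantify how separable the
species are on the selected bands compared with randomly chosen ones. It
is written for spectroscopists and remote-sensing researchers who want to
identify diagnostic wavebands from labelled leaf spectral libraries — for
example to guide band placement of airborne mid/thermal-IR imagers.

## Method

A candidate solution ("chromosome") is a set of *k* distinct band indices.
Its fitness is the overall validation accuracy of a **spectral angle
mapper (SAM)** nearest-centroid classifier restricted to those bands: a
spectrum *t* is assigned to the species whose mean training spectrum *r*
minimises

θ(t, r) = arccos( ⟨t, r⟩ / (‖t‖ ‖r‖) ),

which is invariant to overall brightness scaling. Evolution uses
fitness-proportional (roulette-wheel) parent selection, single-point
crossover on the sorted band list (with duplicate repair), per-chromosome
single-gene mutation, and elitism, so the best fitness per generation
never decreases. A chromosome-size sweep identifies the smallest *k*
meeting an accuracy threshold, and a repeated-run protocol with
per-run data reshuffling checks consistency of the selected bands.

Separability of a species pair on a band subset is scored by the J-M
distance. With Gaussian class models (μᵢ, Σᵢ) and Σ̄ = (Σ₁+Σ₂)/2, the
Bhattacharyya distance is

B = ⅛ (μ₁−μ₂)ᵀ Σ̄⁻¹ (μ₁−μ₂) + ½ ln( det Σ̄ / √(det Σ₁ det Σ₂) ),

and JM = 2(1 − e⁻ᴮ) ∈ [0, 2]. GA-selected bands are compared against
random band subsets with a per-pair Welch t-test over per-chromosome J-M
samples.

Because labelled mid/thermal-IR leaf libraries are rarely public, the
package ships a seeded synthetic generator that emulates a 13-species ×
35-leaf FTIR campaign: a smooth high-emissivity baseline, five planted
Gaussian absorption features with species-specific depths, per-leaf depth
jitter, correlated and iid noise, and the noisy 6–8 µm water-absorption
window masked out.

## Worked example

`examples/select_bands.py` generates the default synthetic library, runs
three GA band selections (k = 5, population 200) with reshuffled
train/validation splits, and groups the pooled winner genes:

```
run 1: fitness 100.00% after 59 generations, bands [3.414, 9.354, 9.849, 10.154, 11.525] um
run 2: fitness 100.00% after 55 generations, bands [3.452, 4.442, 9.316, 9.887, 11.525] um
run 3: fitness 100.00% after 56 generations, bands [3.452, 5.813, 9.354, 10.611, 11.487] um

pooled winner-gene groups (gap rule 0.15 um):
      mid infrared  n=3  3.41-3.45 um  mean 3.44 um  sd 0.018 um
      ...
  thermal infrared  n=3  11.49-11.52 um  mean 11.51 um  sd 0.018 um

planted centres for comparison: (3.44, 5.8, 9.36, 9.87, 11.52)
```

Each run's winner classifies all validation leaves correctly, and the
pooled gene clusters land on the planted feature centres (3.44, 9.36,
9.87, 11.52 µm here) — the selector recovers the wavelengths that actually
carry species information. The other examples show simulation
(`simulate_library.py`), SAM confusion matrices
(`evaluate_classifier.py`, 97.74% validation accuracy on the five planted
bands) and the J-M comparison (`separability_analysis.py`: mean J-M 1.997
on GA bands vs 0.797 on random bands; all 78 species pairs significant at
α = 0.05).

A thin CLI mirrors the library: `gasam simulate | select | evaluate |
run | report` (see `gasam --help`). Reflectance input is converted to
emissivity via Kirchhoff's law (ε = 1 − R) with `--reflectance`.

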