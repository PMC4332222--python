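# Methods

This note documents the models behind `lungfot`, the calibration of the
synthetic cohort, and the numerical and design choices a maintainer would
want to know. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Forcing protocol

The oscillation is a sum of 19 sinusoids delivered during an 8 s pause of
regular ventilation. Frequencies are integer multiples `k/8` Hz of the
window's bin width (0.125 Hz), so a rectangular-window DFT over one window
is leakage-free, and are pairwise **non-harmonic**: no component is an
integer multiple of another, which keeps each component's harmonic
distortion products off the other components' bins.

The instrument's exact frequency list is not public. The default set is a
deterministic greedy scan over bin multipliers k = 4…157 that force-includes
k = 4 (0.5 Hz), k = 6 (0.75 Hz) and k = 157 (19.625 Hz) — the frequencies
that appear in the reported group comparisons and the stated band edges —
then accepts each ascending k that is neither a multiple nor a divisor of
an accepted one, stopping at 19. This yields
{0.5, 0.625, 0.75, 0.875, 1.125, 1.375, 1.625, 2.125, 2.375, 2.875, 3.625,
3.875, 4.625, 5.125, 5.375, 5.875, 6.625, 7.375, 19.625} Hz. "Mutually
prime" is read as this pairwise non-harmonic criterion rather than
pairwise-coprime multipliers, because 0.5 Hz (k=4) and 0.75 Hz (k=6) — both
reported — are not coprime.

Phases default to Schroeder's quadratic schedule `φ_i = −π i(i−1)/n`
(bounded crest factor, no optimization); seeded random phases are
available. Sampling is 256 Hz (an integer number of samples per window,
>12× the top frequency). Component amplitudes are equal before a final
rescaling that sets the sampled peak-to-peak volume exactly to the tidal
volume (default 0.9 mL = 3 mL/kg × 0.3 kg). Flow is the analytic
derivative of volume, not a finite difference.

## Forward lung model

The generator is the standard low-frequency description of lung tissue: a
constant-phase element. Each of N = 10 parallel compartments has

    Z_i(f) = Raw_i + jω·Iaw_i + (G_i − j H_i)/ω^{α_i},
    α_i = (2/π)·atan(H_i/G_i),

with tissue damping `G` and elastance `H` in cmH2O/mL, behind a common
central airway `Rc + jω·Ic`. The lung impedance is
`Z_L = Rc + jωIc + (Σ_open 1/Z_i)^{-1}`.

Recruitment is a static threshold: compartment i participates at a given
PEEP iff `PEEP ≥ Pc_i` (closing pressure). The two 30-cmH2O recruitment
maneuvers that precede each measurement are modelled as resetting history,
so there is no hysteresis. A lung with every compartment closed is
*unmeasurable* — the same condition that excluded the most severe grade
from the original measurements. The cohort sampler guarantees at least one
patent compartment (Pc < 0) per animal so the study PEEP range {0, 2, 4,
6, 8} cmH2O is always measurable.

Two mild PEEP couplings beyond threshold recruitment are part of the
generator, because pure recruitment leaves a fully-open (grade A0) lung
PEEP-invariant while the observed index trends decline with PEEP in every
group:

- airway dilation: `Raw` and `Rc` are divided by `1 + 0.05·min(PEEP, 4)`,
  producing the observed fall-then-plateau of `R_high` at PEEP 4;
- tissue softening: `G` and `H` are scaled by `1 − 0.012·PEEP` (floor 0.5),
  scaling both together so α is untouched.

Both are generator plumbing — plausible physiology chosen for the shapes
they produce, not mechanisms asserted by the source study.

## Grade presets and calibration

Presets live in `src/lungfot/data/default_presets.yaml` (versioned). Per
grade they specify the per-animal tissue-fraction distribution (the printed
group means/SDs: isograft 22.5 ± 1.5 %, A1 26.1 ± 4.2, A2 33.8 ± 5.1,
A3 62.1 ± 4.7), lung-level peripheral resistance, inter-compartment
heterogeneity CV (0.10 / 0.20 / 0.35 / 0.50 from A0 to A3), and the
closing-pressure distribution (A0: all Pc < 0; A1 −0.2 ± 1.2; A2 1.0 ± 2.0;
A3 2.0 ± 4.0 cmH2O — the severe grade stays largely derecruited across the
study PEEP range).

Mechanics couple to histology through the per-animal tissue fraction:

    G, H ∝ (TF_eff / 0.225)^3.5,
    TF_eff = TF_group_mean + s_grade · (TF_animal − TF_group_mean).

The β = 3.5 power law makes log E_low approximately linear in TF across
the cohort (the reported TF–elastance relation). The within-group shrink
`s_grade` (0.4 / 0.25 / 0.7 / 0.7) exists because the raw power law would
amplify the printed TF SDs into 50–90 % within-group elastance scatter,
contradicting the much tighter printed per-group E_low SDs (e.g. A1:
6.4 ± 0.9 cmH2O/mL); `s` is calibrated so within-group elastance CVs match
those printed SDs while group medians still follow the full coupling law.

Hysteresivity is fixed at η = G/H = 0.30 (α ≈ 0.814) for all grades — in
the injured-lung range and consistent with the printed ratios of R_L(0.5 Hz)
to E_L. The A0 all-open lung elastance scale (3.8 cmH2O/mL) was set by a
one-dimensional calibration against the closed-form Z_L oracle so that
cohort medians land on the printed values: the closed-form estimate (3.08)
ignores the harmonic-mean shrinkage of a heterogeneous parallel
combination, which the calibration absorbs. With these constants the
default cohort's medians land near the printed group values — A1
E_low(PEEP 4) ≈ 6.5 vs 6.4 printed, A2 R_high(PEEP 0) ≈ 0.50 vs 0.48 —
and the acceptance suite verifies the orderings and correlation strengths.

Per-animal TF targets are drawn as a **stratified** sample of the group
distribution (quantile midpoints of the truncated normal, randomly
assigned to animals). Each realized cohort therefore reproduces the
printed group TF mean and spread by construction instead of only in
expectation; for group sizes of 4–7 this removes a ±2 pp drift of the
cohort mean that would otherwise dominate the recovery checks.

## Record simulation and impedance estimation

Because the forcing is bin-aligned, the noiseless pressure response is
computed exactly in the frequency domain (`P(f_k) = Z_L(f_k)·Q(f_k)` at the
protocol bins, inverse FFT), and white Gaussian noise is added to pressure
at a configurable SNR (default 40 dB; the instrument's noise floor is
unknown). The noiseless simulate → estimate round trip recovers the
closed-form impedance to better than 1e−6 relative at every bin — this
oracle equivalence is a test, with the analytic Z_L as the independent
reference.

The default estimator is the exact-bin DFT over full windows (rectangular
taper), which is unbiased for this generator. For imported data a
Welch-style estimator (`Z = S_qp/S_qq` over non-overlapping windows) adds
per-bin coherence γ²; bins with γ² below 0.9 are flagged, never dropped.
No detrending by default; a linear-detrend flag exists for drifting
recordings. Flow is positive in inspiration; both signals are referenced
at the airway opening.

Indices: `E_low = E_L(0.5 Hz)`; `E_max = max_k |E_L(f_k)|` over measured
bins only (the absolute value guards against inertance-dominated negative
E_L at the top of the band); `E_het = E_max − E_low` (≥ 0 whenever E_low is
positive, since E_max ≥ |E_low|); `R_high` averages resistance over the top
`n_high` frequencies, default 1 (the original report says "highest
frequencies", plural, without disambiguating — the knob exists, the
default is the single top bin).

## Synthetic histology

The micrograph generator is a morphological cartoon, not a staining
simulation; its contracted properties are the tissue fraction, its
regional dispersion, and the grade ordering of infiltrate burden — the only
image properties the downstream analysis consumes.

All structures are expressed as one distance-like field D(x) on a periodic
(toroidal) domain: alveolar walls as the Voronoi-edge distance of random
seeds (half the gap between the two nearest seeds), vessels/bronchioles as
ring walls `|r − R|`, perivascular infiltrate blobs seeded just outside
vessel walls, and (severe grade) free consolidation foci. Tissue is
`D < t`; bisection on t calibrates the rendered fraction to the per-animal
target within ±0.005 (≤ 50 iterations, error with the last achieved
fraction otherwise), and the achieved pre-noise fraction is recorded as
`tf_truth`. The grayscale rendering (tissue 40, airspace 220, hematoxylin
polarity) is blurred (Gaussian σ = 1 px) and dosed with pixel noise
(σ = 8 gray levels).

Periodicity makes the texture statistically stationary, so uniformly
placed sampling regions are unbiased anywhere in the field of view.
Structure sizes are physical (pixels at the nominal ×20 ≈ 0.5 µm/px
magnification) and fixed; structure *counts* scale with field area, so a
smaller rendering is a smaller field of the same tissue. Grade presets
increase infiltrate count and size from A0 (none) through A3 (large blobs
plus consolidation foci plus globally thickened septa via the calibration
scale), which makes region-level TF dispersion grow with grade.

## Morphometry

Binarization defaults to Otsu's global threshold (the original ImageJ
workflow does not specify its method; a mean-threshold alternative is
pluggable). Threshold-level pixels go to the dark (tissue) class, which
makes inverted-polarity input with the polarity flag reproduce the same
mask. Regions are axis-aligned squares (default 15 per image, 256 px)
placed uniformly at random, overlap allowed, seedable; a whole-image region
is possible. Per-animal statistics pool all regions across that animal's
images: `tf_mean` and sample SD (`ddof = 1`), reported in percent.

Known accuracy: the full-image Otsu mask matches `tf_truth` to well under
1 pp; a single-section 15-region estimate carries ~1–2.5 pp sampling noise
(larger for the patchy severe grade), which the pooled multi-section
protocol reduces below 2 pp. The mean-threshold alternative reads
systematically higher on blurred renderings (it sits ~0.6 σ into the edge
ramp), by a few pp at these wall thicknesses; the two methods agree to
<0.01 on sharp renderings.

## Statistics

- `correlate`: Pearson (optionally on log10 y), Spearman with average-rank
  ties, OLS with r² (= r² of Pearson for simple regression) and the 95 %
  confidence band of the mean response.
- `compare_groups`: two-way ANOVA with Type-II sums of squares for the
  unbalanced grade layout, Bonferroni-adjusted pooled-variance pairwise
  contrasts (contrasts of the first factor within each level of the
  second; the adjustment spans all of them); one-way path with either
  Bonferroni or Tukey–Kramer (studentized range via statsmodels).
- `repeated_compare_groups`: split-plot ANOVA for designs where every
  animal is measured at every within-level (frequency or PEEP). The
  between-groups effect is tested on animal means; the within effect and
  interaction are tested against the residual after fixed animal blocks,
  by nested model comparison (exact for the balanced within factor). The
  pooled-error two-way ANOVA is uninformative here because between-animal
  variance in the severe grade dwarfs the within-animal frequency
  structure.
- `grade_correlation`: grades mapped ordinally (A0 = 0 … A3 = 3,
  configurable); Pearson against log10 of the index (the index spans
  orders of magnitude), Spearman against the raw index.

The reported real-data coefficients (r² = 0.930 and 0.709, r = 0.931,
r_s = 0.964) are treated as qualitative templates: raw animal data are not
available, so the acceptance suite checks the calibrated synthetic cohort
against thresholds (r² ≥ 0.8, r_s ≥ 0.9) rather than those exact values.

## Problem sizes and determinism

The default study is the printed design: 29 animals (6 native + 6
isograft + 4 A1 + 7 A2 + 6 A3), five PEEP levels, one 8 s record per
(animal, PEEP) at 256 Hz, one 1024² micrograph per animal with 15 sampled
regions. The full pipeline runs in about a minute on one CPU; the
acceptance script recomputes its targets in under a minute. All
randomness is spawned hierarchically from one master seed
(`numpy.random.SeedSequence`), making cohorts, images and statistics
byte-reproducible; identical seeds give identical pipeline output files.

## Limitations

- The generator is single-lung, open-chest, linear and time-invariant: no
  chest wall, no gas exchange, no nonlinear harmonic distortion, no
  tidal-breathing dynamics — only the oscillation pause is modelled.
- The severe grade's PEEP-insensitivity is encoded purely as high closing
  pressures; airway–parenchyma decoupling is not modelled.
- Synthetic micrographs share only the contracted statistics with real
  sections; tests passing on them say nothing about stain variability,
  sectioning artifacts, or pathologist-level morphology on real slides.
- The split-plot ANOVA treats animals as fixed blocks; a mixed model with
  random animal effects would be the fuller treatment.
- Grade labels enter as ordinal integers for correlation; the underlying
  classification is categorical.
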