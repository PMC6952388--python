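# axonquant

Quantification of hemidesmosome attachment along *C. elegans*
touch-receptor axons from fluorescence microscopy, with a fully
synthetic, ground-truth-carrying data generator so that every analysis
stage can be validated without microscope data.

The posterior lateral microtubule (PLM) touch-receptor axon is ensheathed
in the epidermis and anchored to the cuticle by hemidesmosome attachment
complexes (imaged via fusions to components such as VAB-10a/spectraplakin
and LET-805/myotactin). At the L4 larval stage these complexes form
periodic puncta spaced ~1 µm along the axon; in 1-day-old adults the
pattern remodels into a continuous distribution. Loss of attachment in
localized regions precedes mechanical buckling and breakage of the axon.
This package implements the measurement chain used to quantify that
biology, for researchers analysing line scans of attachment-protein
fluorescence along traced neurites:

1. **Profile extraction** — maximum projection of a z-stack over a slice
   window, uniform arc-length line scan along a traced axon (63 nm
   default sampling; a 50 µm region yields exactly 793 samples), and
   normalization to the pooled mean of wild-type L4 controls, giving
   intensities in a.u. with reference mean 1.
2. **Periodicity metrics** — the profile autocorrelation r(τ) (biased,
   mean-subtracted, lag-0 normalized) with its *amplitude*
   `A = r(τ_peak) − ½·(r(τ_v1) + r(τ_v2))`, the difference between the
   first off-zero peak and the mean of its two flanking valleys (A ≈ 2
   for a pure sinusoid, ≈ 0 for aperiodic signal), plus peak detection
   and mean puncta spacing.
3. **Attachment classification** — the L4 rule (an axon has *gaps* iff
   more than 5 expected punctum positions score below 0.2 a.u.) and the
   adult rule (*gaps* iff some run of absent localization exceeds
   10 µm), with cross-tabulation against axonal breakage.
4. **Penetrance statistics** — breakage penetrance x/n per strain with
   Agresti–Coull 95% confidence intervals
   (ñ = n + z², p̃ = (x + z²/2)/ñ, p̃ ± z·√(p̃(1−p̃)/ñ)), all-pairs
   comparison of proportions with Tukey (studentized-range) family-wise
   control, and ordinal 1–5 axotomy degeneration-score summaries.
5. **Synthetic data** — axon images and line profiles with periodic
   Gaussian puncta, stage-dependent remodeling, configurable gap
   regions, PSF blur, Poisson/Gaussian camera noise, and binomial
   scored-animal tables; every generated element is recorded as ground
   truth.

## Worked example

Simulate a mutant-like adult axon carrying a 12 µm attachment gap,
extract its statistics, and attach a penetrance interval:

```python
import axonquant as aq

model = aq.PunctaModel(spacing_d=1.0, puncta_sigma=0.15, puncta_amplitude=1.0,
                       background=0.05, jitter_sd=0.03, amplitude_cv=0.1)
gaps = aq.GapSpec(intervals=((20.0, 32.0),), residual_fraction=0.0)
noise = aq.NoiseModel("poisson", photon_scale=100.0)

profile, truth = aq.generate_profile(model, gaps, noise, length=50.0, seed=42)
reference, _ = aq.generate_profile(model, seed=42)          # intact control
norm = aq.normalize_profile(profile, aq.compute_reference_mean([reference]))

ac = aq.autocorrelate(norm, max_lag=5.0)
pts = aq.detect_puncta(norm, min_prominence=0.8, smooth_um=0.1)
l4 = aq.classify_l4(norm, expected_spacing=1.0, smooth_um=0.15, peak_prominence=0.4)
adult = aq.classify_adult(norm, median_um=0.3, close_um=0.3)
lo, hi = aq.agresti_coull_interval(29, 40)
```

This prints:

```
samples: 794
reference mean (a.u.): 0.4190
first autocorrelation peak: 1.008 um, amplitude 1.313
detected puncta: 38, mean spacing 1.299 um
L4 call: 11 sub-threshold puncta -> gaps
adult call: longest gap 11.97 um -> gaps
ground truth: l4=gaps, adult=gaps
penetrance 29/40 = 0.725, 95% AC interval (0.570, 0.840)
```

The first autocorrelation peak sits at the 1 µm puncta spacing; the
amplitude (1.31) is below the noiseless periodic limit because a quarter
of the profile carries no signal. The mean detected spacing (1.30 µm) is
inflated by the single 12 µm jump across the gap. Eleven expected
punctum positions score below 0.2 a.u. (> 5 ⇒ *gaps*), and the longest
sub-threshold run is 11.97 µm (> 10 µm ⇒ *gaps*) — both matching the
generator's ground truth. A strain with 29 broken axons of 40 scored has
penetrance 0.725 with Agresti–Coull 95% CI (0.570, 0.840).

The same stages are scriptable from the shell:

```sh
axonquant fixtures --out-dir demo --seed 0
axonquant run --seed 0 --out-dir demo_run          # simulate → extract → classify → stats
axonquant extract --image demo/mutant_adult_0.tif \
    --trace demo/mutant_adult_0_trace.csv --region 0:50 --out profile.csv
```

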