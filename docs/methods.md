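# Methods

This note documents the models, conventions, and design choices behind
axonquant: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where genuinely open
decisions were made.

## Coordinates and sampling conventions

Physical positions are micrometres, origin at the centre of image pixel
(row 0, col 0); x runs along columns, y along rows. Line scans sample a
traced polyline at uniform arc-length steps (default 0.063 µm, the xy
pixel pitch of the spinning-disk acquisition this pipeline was designed
around). The sample count for a region of length L at step s is
n = ⌊L/s⌋, i.e. samples at k·s for k = 0..n−1, so n·s ≤ L < (n+1)·s.
A 50 µm region at 0.063 µm therefore contains exactly 793 samples —
matching the count conventionally reported for this measurement — and
spans 49.90 µm. Intensity at sub-pixel sample points is read by bilinear
interpolation (nearest-pixel lookup is available); bilinear reading of a
Gaussian punctum of width σ introduces a relative peak error of order
(h/σ)²/8 for pixel pitch h, ~2% at σ = 0.2 µm.

Maximum projection takes the pixel-wise maximum over an odd window of
z-planes (default 21) centred on the axon, clipping at stack bounds.

Normalization divides raw intensity by the pooled mean of all included
samples across the reference condition (wild-type L4 controls), so
normalized intensity is in arbitrary units (a.u.) with reference mean
exactly 1. Excluded samples — notably the gap near the anus present in
all animals, supplied as an explicit per-profile exclusion interval
rather than auto-detected, since no detection rule exists — never enter
any statistic.

## Periodicity statistics

The autocorrelation uses the biased (divide-by-N) mean-subtracted
estimator normalized by its lag-0 value; the biased form is positive
semidefinite and tapers large lags, which slightly shrinks peak values
(≈2% at lag 1 µm over a 50 µm profile). Maximum lag defaults to 5 µm
(~5 periods) and is capped at N/2 samples for estimator stability. The
first peak is the first local maximum at lag > 0 with prominence ≥ 0.05;
the two valleys are the local minima immediately flanking it (boundary
minima are used, and flagged, if the curve ends first). The amplitude is
first-peak r minus the mean of the two valley r values: 2 in the pure
sinusoid limit, ~0 for white noise (empirically ≤ 0.5 in >99% of seeded
white-noise profiles). The statistic is invariant to affine intensity
maps a·x + b (a > 0).

Puncta are local maxima with a minimum prominence (default 0.1 a.u.) and
minimum separation (default 0.3 µm), via standard peak finding; both
defaults are free analysis parameters, not measured constants. Mean
spacing is the mean consecutive-peak distance and is undefined (NaN)
with fewer than two peaks. On noisy profiles an optional Gaussian
pre-smoothing (`smooth_um`, ~PSF scale 0.1 µm) suppresses spurious
single-sample maxima; with smoothing 0.1 µm and prominence 0.8 a.u. the
true spacing d ∈ {0.8, 1.0, 1.5} µm is recovered within two sampling
intervals in ~100% of simulations at peak SNR 5. Note that mean spacing
is inflated when detections straddle a gap; the spacing statistic is
meaningful in regions of retained attachment.

## Attachment classification

Two stage-specific rules operate on normalized profiles:

* **L4 rule.** Expected punctum positions are laid out on a grid at the
  reference mean spacing (default 1.0 µm) across the included span. Each
  position is scored by the local intensity maximum within ± half a
  spacing; positions scoring below the threshold (default 0.2 a.u.)
  count as missing. More than 5 missing puncta ⇒ label *gaps*, otherwise
  *continuous*. The grid-based reading was chosen over counting detected
  peaks below threshold because completely absent stretches contain no
  detectable peaks at all and would otherwise be undercounted. Exactly 5
  is labelled *continuous* under the literal "> 5" rule; because the
  complementary "< 5" phrasing leaves the boundary undefined, every
  exactly-5 occurrence is logged as a boundary case.
* **Adult rule.** The longest contiguous run of included samples below
  the threshold, in µm (run samples × sampling interval); a run longer
  than 10 µm ⇒ *gaps*. The 0.2 a.u. threshold is reused for "no
  localization" since no separate adult intensity floor is defined.

The default settings implement the rules literally, which is exact on
clean (deconvolved or noiseless) profiles but fragile under strong
noise: a single upward noise excursion inside a true gap breaks the run,
and the window maximum is upward-biased. Optional noise-robust variants
are therefore provided and used by the noisy-data validations:
`classify_l4(smooth_um=0.15, peak_prominence=0.4)` scores a position as
present only if a prominent local peak of height ≥ threshold lies in its
window, and `classify_adult(median_um=0.3, close_um=0.3)` applies a
running median (bounded edge shift of ± half the window) and then
removes above-threshold islands shorter than `close_um` before measuring
runs — genuine puncta stand above threshold over ~0.6–0.8 µm and survive
the closing. With these settings, classifier labels agree with noiseless
ground truth in 100/100 noiseless and ≥95/100 shot-noise-limited
(peak SNR 5) simulations spanning both decision boundaries.

Cross-tabulation of adult calls with breakage status yields the 2×2
gaps/continuous × broken/intact table; break status is an input
annotation (breaks are scored manually), never inferred from images.
The predictive-linkage summary reports the broken proportion among
gap-bearing vs continuous L4-stage animals with Agresti–Coull intervals.

## Penetrance statistics

Penetrance is a binomial proportion x/n. Intervals use the
Agresti–Coull construction at confidence C: with z the standard-normal
quantile at (1+C)/2, ñ = n + z², p̃ = (x + z²/2)/ñ, half-width
z·√(p̃(1−p̃)/ñ), clipped to [0, 1] after the half-width computation. The
adjustment regularizes x = 0 and x = n; no extra continuity correction
is applied. Exhaustive equivalence with the closed form is verified for
all (x, n), n ≤ 50, and empirical coverage at p = 0.3, n = 30 is ~0.95.

Multi-group comparison: "ANOVA with Tukey multiple comparison of
proportions on an Agresti–Coull interval" is not a uniquely defined
textbook procedure. The implementation uses the closest defensible
construction — pairwise two-proportion z-statistics on
Agresti–Coull-adjusted counts (x + z²/2, n + z²), declared significant
when |z|·√2 exceeds the studentized-range quantile q(1−α; k, ∞) for k
groups — which reduces exactly to the two-sided z-test at k = 2.
Bonferroni adjustment is available as a sensitivity check. Simulated
family-wise type-I error for four null groups (p = 0.2, n = 60) is
~0.04 at nominal α = 0.05. Because the original procedure cannot be
recovered precisely, published p-values are not reproduction targets;
only the operating characteristics of this implementation are
guaranteed.

Axotomy outcomes use the ordinal 1–5 scale (1 = fully cleared axon,
2 = multiple breaks, 3 = one break, 4 = beading and thinning,
5 = intact axon), summarized as per-category counts and medians, with a
two-sided Mann–Whitney U comparison when exactly two conditions are
present (ties make the test mildly conservative on 5-level data).

## Synthetic data model

A profile is background plus a punctum train: Gaussian puncta of width σ
(default 0.15 µm, a deconvolved-confocal PSF scale) and peak amplitude
1 a.u. on an endpoint-inclusive grid k·d (k = 0..⌊L/d⌋, default
d = 1.0 µm), with optional positional jitter and per-punctum brightness
variation. Stage remodeling is a linear blend: `continuous_fraction` f
interpolates between the periodic train (f = 0, L4-like) and a constant
plateau (f = 1, adult-like) at level amplitude·σ·√(2π)/d — the arc-length
mean of the train — so integrated intensity is independent of f. Gap
intervals multiply above-background signal by `residual_fraction`
(deletion by arc position, so tails of outside puncta still end at the
gap edge); noise is applied after gap deletion, as in real detached
axons where epidermal background remains. Noise is Poisson shot noise at
`photon_scale` counts per a.u. and/or additive Gaussian read noise, with
clipping at zero. "Peak SNR 5" in the validations means the noise sd at
a punctum peak equals amplitude/5 (photon_scale ≈ 26 for pure shot
noise).

Images render each punctum as an isotropic 2D Gaussian (peak = its 1D
amplitude) at its position along the trace on a 63 nm pixel grid; the
continuous component is a dense line of sub-puncta approximating a ridge
whose crest equals the 1D plateau, so extracting the rendered image
along the true trace reproduces the 1D profile to bilinear-interpolation
accuracy. Ground-truth labels are produced by running the classifiers
themselves on the noiseless, gap-faithful profile normalized against the
gap-free version of the same model — label consistency with the
classification rules holds by construction.

The generator emulates the statistical structure the analysis assumes —
periodicity, remodeling, gaps, camera noise, binomial penetrance — and
deliberately not: optics beyond a Gaussian PSF (no Airy rings or
defocus), the 3D epidermal geometry, body curvature/deformation,
autofluorescent debris, or biological covariation between attachment
state and brightness. Passing tests therefore demonstrate correctness of
the measurement chain on data obeying the stated model, not robustness
to every real-microscope artifact.

The ridge tracer (a convenience replacement for manual tracing) blurs
the image at ~0.5 µm so the beaded axon becomes a continuous ridge, then
walks from a seed point in both directions with per-step crest
recentring, a turn limit, a stop criterion at 25% of seed contrast above
background, and a revisit-exclusion radius spanning the smoothed ridge
so terminal blobs cannot reflect the walk. On synthetic axons it stays
within ~0.2 px of a straight ridge and recovers curved arc length within
~3%; callers with low-SNR or crossing structures should supply explicit
traces.

## Pipeline and reproducibility

The `run` pipeline executes simulate → extract → periodicity → classify →
penetrance from one validated configuration whose defaults collect the
scoring conventions in one place (0.063 µm sampling, 0–50 µm region,
0.2 a.u. threshold, count rule 5, gap rule 10 µm, 21-slice projection,
95% confidence). All stage outputs are plain CSV/JSON; a manifest
records the config snapshot, package version, SHA-256 of every output,
and accumulated warnings (including every exactly-5 boundary case).
Identical config and seed reproduce byte-identical stage outputs; the
manifest's own timestamps are the only non-reproducible bytes. The demo
fixture cohort (8 animals: 2 genotypes × 2 stages × 2 animals, mutants
carrying a 12 µm gap; 4 gaps / 4 continuous by construction) is
generated deterministically from a seed, never stored.

Validation problem sizes were chosen to make sampling error negligible
relative to each acceptance margin: 100 seeds per recovery/agreement
rate, 10,000 draws for interval coverage, 5,000 simulated experiments
for the family-wise error, 200 seeds for null-distribution checks.

## Known limitations

* Autocorrelation amplitudes depend on estimator conventions (bias,
  max lag, prominence floor) that the source field literature leaves
  unspecified; amplitudes are comparable within this implementation
  only.
* The exactly-5-missing-puncta boundary of the L4 rule is undefined in
  its original phrasing; the literal "> 5" reading is used and logged.
* The adult rule's intensity floor reuses the 0.2 a.u. L4 threshold for
  lack of a stated adult value.
* Deconvolution is upstream and out of scope; the pipeline consumes
  already-deconvolved (or synthetic) TIFFs.
* The line scan averages over a single sample line by default; the
  original line width is unknown (`line_width` option provided).
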