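# Methods

This note records the models behind `evcq`, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Image formation and camera model

Simulated acquisitions render each emitter as an isotropic 2-D Gaussian
whose peak amplitude is `copy_number × unit_peak_adu`, evaluated at pixel
centres `(index + 0.5) × pixel_size_um`, on a local ±5σ window (beyond 5σ
the contribution is exactly zero, which the noiseless worked examples rely
on). Camera counts are `Poisson(background + signal) + N(0, read_noise) +
baseline`, clipped at zero. Defaults:

- `pixel_size_um = 0.108` — a 2048-px sCMOS chip spanning a 200×200 μm
  field at 60×.
- `psf_sigma_um = 0.15` — the nominal diffraction σ (≈0.21·λ/NA ≈ 0.07 μm
  for λ = 510 nm, NA = 1.49) deliberately inflated for frame averaging and
  slight defocus, so that a bright spot's >2-fold-background mask clears
  the 0.1 μm² area filter.
- `background_adu = 20`, `read_noise_adu = 3` — a dim, read-noise-limited
  background typical of short-exposure fluorescence imaging; with a
  100 ADU fluorophore this puts the per-frame trace SNR near 10.
- Spot placement is uniform with rejection, enforcing a minimum pairwise
  separation of 4σ (the dilution the wet protocol achieves by serial
  dilution is enforced geometrically here); the factor is configurable, and
  the noiseless worked examples use 12σ so that render windows are disjoint
  and intensities are exact to machine precision.

Not modelled: vignetting (the analysis crops the field centre precisely to
avoid it), fluorophore blinking, chromatic/drift effects, and instrument
file formats.

## Photobleaching and the step classifier

Each fluorophore carries an independent exponential lifetime; a spot's
noiseless trace is `surviving_count × unit + background`, sampled per
frame. The analysis extracts a measured trace at the brightest pixel of the
averaged detection image (a fixed pixel, so post-bleach frames fluctuate
around zero instead of being max-biased) and segments it by exact
dynamic-programming least squares over 1..K+1 piecewise-constant segments
(default K = 5).

Model selection minimizes `SSE + c · m · log(n) · σ̂²` with `σ̂` a MAD
estimate from first differences and `c = 3` (configurable). The classical
`c = 1` BIC penalty is too permissive once change-point *locations* are
free parameters: a ~2σ noise excursion of one or two frames already pays
for an extra segment, which would reject ≈20% of genuine single-step traces
at SNR 10. Inflating the penalty is the standard modified-BIC remedy; at
`c = 3` the classifier accepts ≥95% of single-step traces and rejects ≥95%
of 2–4-step traces at step:noise 10:1 (verified on 1000 traces each).

Step counting is asymmetric by design: only *downward* level changes count
(an upward change marks a segment boundary but no bleaching event), a
change must exceed `max(3σ̂, 10⁻³ × trace range)` (the relative floor keeps
cross-talk epsilons on noiseless traces from registering), and when at
least one step was seen but the final level stays above background by more
than the same floor, one *pending* step is added — the trace did not bleach
to completion, so at least one more fluorophore must be present. A trace
with no downward step reports 0. This keeps the invariant
`accepted_single ⇔ n_steps = 1` while still rejecting incomplete bleaches:
a constant bright trace reports 0 steps (never confirmed single), a
one-step trace ending at background reports 1, a one-step trace ending high
reports 2.

Benchmark traces for the classifier use "spaced" step placement (minimum
gap 3 frames, bleached tail): with physical exponential lifetimes two
fluorophores bleach within one frame ~10% of the time, and such a collision
trace simply does not contain k distinguishable steps, so it is not a valid
member of a k-step benchmark class. Field simulations keep exponential
lifetimes.

## Calibration and copy-number estimation

The unit intensity is the mean background-subtracted *peak* intensity of
reference spots whose trace was accepted as single-step (≥30 required;
integrated intensity is carried along for diagnostics but not used). Copy
number is the real-valued ratio `peak / unit`; no rounding, since the
division does not produce integers and downstream summaries bin them.
Estimates below the detection limit (default 3.0 molecules) are flagged and
excluded from condition means; the limit applies to the estimate, not to
ground truth.

Two attenuation factors act identically on reference and vesicle peaks and
therefore cancel in the ratio: sub-pixel position (expected peak-pixel
attenuation ≈0.96 at σ = 1.39 px) and bleaching during the 4-frame
averaging window. For the second cancellation to hold, `simulate_ev_field`
accepts a `bleach_rate_per_s` so that study simulations can image vesicles
under the same illumination as the calibration; its default stays 0
(static rendering, exact linearity). One residual bias remains: a reference
fluorophore that bleaches before contributing a bright frame is rejected
by the step classifier rather than measured low, which raises the
calibrated unit slightly; at the study's gentle illumination
(rate 0.05 s⁻¹, 1 s frames) the end-to-end condition means recover ground
truth within ~4%, comfortably inside the 10% recovery target at n = 500
vesicles per condition with calibration n = 200.

Thresholds follow the strict readings: detection keeps pixels strictly
above 2× background; the area filter removes strictly below 0.1 and
strictly above 10 μm² (the closed interval is retained); density QC passes
strictly below 0.1 spots/μm². Background is a global robust median per
image, refined once over pixels ≤ median + 3·MAD to shed spot pixels.
Components use 8-connectivity (switchable to 4); centroids are
intensity-weighted with background-subtracted weights.

## Nanoflow cytometry

Simulated side scatter follows `SSC = scale · (d/100 nm)^p` with lognormal
multiplicative noise (default cv 5%) and `p = 4` — sub-wavelength silica
and vesicles scatter with a strong positive power of diameter; the exponent
is configurable and nothing downstream assumes its value beyond
monotonicity. Bead modes are located by 1-D k-means with quantile
initialization (deterministic); knots pair each mode's median SSC with the
known diameters in ascending order, and fitting fails loudly if the pairing
is not strictly monotone. Interpolation is piecewise-linear in
(log SSC, log diameter), which is exact for any power law and monotone by
construction; beyond the knots the end-segment slopes extrapolate, unless
extrapolation is disabled, in which case sub-range events are flagged
rather than sized. Evaluation at a knot short-circuits to the knot diameter
so the identity holds exactly, not merely to log/exp round-off.

Gates sit at the 99.5th percentile of a negative control (≥200 events
required); the quantile is configurable since the instrument software's
internal rule is proprietary. Events exactly at a threshold are negative.
%positive is reported with MFI over *all* events (the total-population
convention) and over positives alongside. EV diameters default to
lognormal with mean 74 nm, cv 0.25; purity defaults to 0.9 dye-labelled
vesicles, with non-vesicular particles drawn broader and larger and never
dye-labelled or cargo-positive.

## Capture chips

An EV appears on a tetraspanin spot iff it carries the matching marker;
the isotype spot captures any EV at a small nonspecific rate (default 1%).
Marker co-occurrence uses an equicorrelated Gaussian copula when requested.
An EV's probability of carrying cargo is `1 − Π(1 − p_m)` over its markers
(independent loading routes). CF647 intensity scales with the number of
tetraspanins carried (the labelling mix targets all three), CF555 with the
GFP copy number; both gates default to 20 ADU ≈ 4× the simulated 5 ADU
background sigma, calibrated so that label-free events are positive at
< 10⁻⁴. The %GFP⁺ ratio uses all CF555⁺ events in the numerator (the
literal count-ratio definition); values above 100 are reported and flagged,
never clipped, and a colocalized-only numerator is available behind a flag.
The 50–200 nm sizing window is closed on both ends.

## Statistics

Kruskal–Wallis uses midranks with the standard tie correction and the
χ²(k−1) approximation regardless of N (all-identical observations return
H = 0, p = 1 rather than an error). An exact permutation p by full
enumeration is provided for N ≤ 10; the χ² approximation tracks it within
0.02 only when the groups are well separated so both p's sit in the tail —
for weak-effect tiny samples (e.g. two groups of two with H = 2.4) the
exact p is 0.33 against χ²'s 0.12, which is the known small-sample
behaviour of the approximation, not an implementation artefact. Dunn's
z tests share the pooled midranks and tie term; the family-wise adjustment
is Bonferroni over all k(k−1)/2 pairs — the original Dunn procedure — which
can differ from software that multiplies by the number of comparisons
actually displayed. Pearson r is undefined on zero-variance vectors and
reported as NaN with a flag. Two-way ANOVA of size-distribution profiles is
out of scope.

## What passing tests do and do not show

The generator reproduces the statistical *structure* the analysis assumes —
Gaussian PSF, Poisson+read camera noise, exponential bleaching, power-law
scatter, Bernoulli marker composition. Parameter recovery under this
structure validates the estimators' correctness and their robustness to the
modelled noise, and the worked-example constants pin the filtering rules
exactly. It does not certify performance on real instrument data, where
PSF asymmetry, focal drift, fluorophore maturation/blinking, refractive
index sensitivity of scatter-based sizing, and antibody affinity bias are
all present and unmodelled. Problem sizes in the test suite (500 vesicles
per condition, 200 calibration fluorophores, 4000 bead events, 5000 flow
events, 2000 chip events) were chosen to keep Monte-Carlo standard errors
a few times smaller than the tolerances they are tested against.
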