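# evcq

Quantification of protein-cargo loading in engineered extracellular
vesicles (EVs), at single-vesicle and single-molecule resolution.

When producer cells are engineered to express an EV-sorting protein
(CD63, CD81, CD9, TSPAN14, CD47, SDCBP, APMAP, ...) fused to a fluorescent
cargo such as GFP, the central quantitative questions are: *what fraction of
secreted vesicles carries the cargo, and how many copies does each vesicle
carry?* `evcq` implements the analysis side of the three single-vesicle
readouts used to answer them, together with the rank statistics that compare
engineering conditions, and a synthetic-data generator that makes the entire
pipeline verifiable by parameter recovery — no instrument data required.

## What the package computes

**SMLM copy-number counting** (`evcq.smlm`). Vesicles adsorbed on glass are
imaged as diffraction-limited spots. The pipeline averages the first
*k* = 4 frames, estimates a robust scalar background *B* (median refined
below median + 3·MAD), detects spots as 8-connected components of pixels
strictly above 2*B*, removes components with area outside [0.1, 10] μm²,
and requires a retained-spot density below 1 per 10 μm². The signal of one
fluorophore, *u*, is calibrated from reference spots whose photobleaching
trace shows exactly one downward step — steps are found by exact
least-squares change-point segmentation with a BIC-type model-selection
penalty. Each vesicle's copy number is then

&nbsp;&nbsp;&nbsp;&nbsp;*n̂* = peak intensity / *u*,

with estimates below the 3-molecule detection limit flagged and excluded
from condition means.

**Nanoflow cytometry** (`evcq.nanoflow`). Side scatter (SSC) is mapped to
diameter through a standard curve anchored on the 68/91/113/155 nm silica
bead cocktail (modes by 1-D k-means, log–log piecewise-linear
interpolation); concentration scales a 250 nm bead standard by the
event-rate ratio and dilution; %GFP⁺ and MFI are computed against a
99.5th-percentile negative-control gate; membrane-dye labelling gives the
vesicular purity of a preparation.

**Tetraspanin-chip colocalization** (`evcq.chipscan`). For each capture
spot (anti-CD63/-CD81/-CD9, IgG isotype), events sized within 50–200 nm are
counted in a total-EV channel (CF647 anti-tetraspanins) and a cargo channel
(CF555 anti-GFP); %GFP⁺ = 100 × CF555⁺/CF647⁺, with isotype counts
subtracted and flagged when they exceed 10% of a capture spot.

**Statistics** (`evcq.statsrep`). Kruskal–Wallis *H* (tie-corrected,
χ²(k−1) p, with an exact permutation option for tiny samples), Dunn's
post-hoc z tests with Bonferroni adjustment, normalization of per-condition
vectors to the untransfected control, and Pearson R² between methods.

**Synthetic data** (`evcq.simgen`). Gaussian-PSF image stacks with Poisson
shot noise, read noise and per-fluorophore exponential photobleaching; flow
event tables with a power-law SSC–diameter relation; chip capture tables
with per-EV tetraspanin composition. Every generator exports ground truth,
so each analysis stage is tested by recovering the parameters it was fed.

## Worked example

```python
import numpy as np
from evcq import simgen, smlm

# calibrate the single-fluorophore unit intensity from a reference field
ref_cfg = simgen.SimImageConfig(width_px=602, height_px=602, n_frames=100, seed=11)
stack, _, _ = simgen.simulate_reference_field(
    ref_cfg, 200, unit_peak_adu=100.0, bleach_rate_per_s=0.05)
image = smlm.average_frames(stack, k=4)
background = smlm.estimate_background(image)
retained = [s for s in smlm.filter_spots(smlm.detect_spots(image, background))
            if s.status == smlm.RETAINED]
traces = smlm.extract_spot_traces(stack, retained, background)
cal = smlm.calibrate_unit_intensity(retained, traces)
print(f"unit intensity: {cal.mean_unit_peak_adu:.1f} ADU "
      f"(cv {cal.cv_unit:.2f}, n = {cal.n_accepted} single-step spots)")

# quantify copies per vesicle in a simulated EV field (true mean 70, cv 0.5)
ev_cfg = simgen.SimImageConfig(width_px=1852, height_px=1852, n_frames=4, seed=12)
dist = simgen.CopyNumberDistribution.lognormal_mean_cv(70.0, 0.5)
ev_stack, truth = simgen.simulate_ev_field(
    ev_cfg, 500, dist, unit_peak_adu=100.0, bleach_rate_per_s=0.05)
ev_image = smlm.average_frames(ev_stack, k=4)
ev_bg = smlm.estimate_background(ev_image)
spots = smlm.filter_spots(smlm.detect_spots(ev_image, ev_bg))
records = smlm.estimate_copy_numbers(spots, cal, detection_limit=3.0)
summary = smlm.summarize_condition(records, "TSPAN14-like")
truth_mean = truth.loc[truth.copy_number_true >= 3, "copy_number_true"].mean()
print(f"retained vesicles: {summary.n_retained}, "
      f"above detection: {summary.n_above_detection}")
print(f"estimated mean copy number: {summary.mean_copy_number:.1f} "
      f"(ground truth {truth_mean:.1f})")
```

Output:

```
unit intensity: 93.1 ADU (cv 0.14, n = 157 single-step spots)
retained vesicles: 492, above detection: 492
estimated mean copy number: 66.6 (ground truth 69.1)
```

The calibrated unit sits below the nominal 100 ADU because a random
sub-pixel spot position attenuates the peak pixel and some bleaching occurs
during the 4-frame averaging window — the same factors attenuate the
vesicle peaks, so their ratio (the copy number) recovers the ground-truth
mean within a few percent.

A command-line interface mirrors the library
(`evcq simulate smlm|flow|chip`, `evcq smlm calibrate|quantify`,
`evcq flow calibrate-size|calibrate-conc|quantify`, `evcq chip quantify`,
`evcq stats compare|correlate`); run `evcq --help` for details.

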