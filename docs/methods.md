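# Methods

This note documents the models behind each stage of the measurement
chain, the parameters that matter, the numerical choices that were
genuinely open, and what the synthetic-data validation does and does not
demonstrate about real data.

## Two-pool exchange forward model

Hyperpolarized [1-¹³C]pyruvate magnetization converts to lactate
unidirectionally at the apparent rate kPL while both pools relax:

    dMp/dt = R(t) − (1/T1p + kPL)·Mp
    dMl/dt = kPL·Mp − Ml/T1l

`R(t)` is an optional boxcar infusion (`m0/bolus_duration` over the
arrival window); the default is an instantaneous bolus at t = 0, because
no arterial input function is available for a tail-vein injection and
the summed-ratio statistic is insensitive to the arrival shape.  The
system is solved in closed form between excitations (the degenerate
λp = λl case by its limit).  Each pulse samples `Mz·sin α` and leaves
`Mz·cos α`; hyperpolarized magnetization is never re-established, so the
readout itself depletes the pools.  Omitting the reverse (lactate →
pyruvate) rate keeps the ground truth closed-form; net conversion is what
the summed-ratio statistic measures anyway.

Defaults: flip 25°, TR 2 s, 60 acquisitions, 2048 complex points over a
5 kHz sweep at 75.515 MHz.  T1p = 43 s and T1l = 33 s are plausible
in vivo values at 7 T chosen to make the 2-minute window informative;
they are modeling assumptions, not measured quantities.  ¹³C shifts
default to the literature convention (pyruvate 171.0 ppm, lactate
183.2 ppm) and are configurable.

The true nLac of a simulated experiment is the summed sampled-amplitude
ratio over all pulses — the same functional the spectral estimator
targets, so estimator error is measured against an exact reference.

## Spectral processing and the nLac estimator

Each FID is apodized (`exp(−π·lb·t)`), half-first-point corrected,
zero-filled ×2 and DFT'd onto an ascending ppm axis.  Processing choices
that required decisions:

- **Automatic phasing.**  The phase error at the apex of a symmetric
  resonance equals the complex argument of the spectrum there, so
  (φ0, φ1) are solved from the two strongest peaks: apex positions are
  refined to sub-bin precision (the apex-bin argument alone is biased by
  up to atan(bin-offset/linewidth)), the argument is averaged under
  weights symmetric about the true center, and the 2π branch of the
  inter-peak difference is selected by the smallest sum of squared
  negative real intensities.  A second pass on the corrected spectrum
  removes the small bias the phase ramp induces across each peak window.
  Peak selection is restricted to the windows known to contain the
  resonances, the second peak must clear a local-contrast floor (running
  median) so smooth baseline structure cannot pose as a resonance, and
  it must come from a different window than the first so a corrupted
  peak's own wings cannot either.
- **Stack-consistent phasing.**  Phase errors are common across a
  dynamic series (receiver and sequence, not chemistry), so spectra whose
  strongest peak falls below an SNR threshold (default 15) adopt the
  phase of an anchor acquisition — the one where the *weaker* species is
  strongest, since both resonances constrain φ1 there — as do spectra
  whose own estimate deviates wildly from the anchor.  Phasing pure noise
  individually would randomize its real channel and corrupt the summed
  areas.
- **Baseline.**  Degree-3 polynomial fit to the real channel outside the
  peak-exclusion windows by IRLS with symmetric Cauchy weights.
  Asymmetric weights (classic "ignore everything above the fit") bias
  the baseline below the noise mean by ~0.2 σ, which inflates every
  integral; symmetric weights are unbiased under symmetric noise while
  still damping residual signal.
- **Integration.**  Peaks are integrated between their quarter-maximum
  crossings (linear interpolation between samples; trapezoidal rule).
  For a Lorentzian the FWQM bounds sit at ±√3 γ and capture exactly
  (2/π)·arctan √3 = 2/3 of the area, *independent of γ* — which is why a
  ratio of FWQM areas of two Lorentzians is unbiased even when the
  windows truncate the tails.  Overlap between the two species is
  resolved by truncating bounds at the midpoint between their centers.
- **Bounds across the stack.**  The FWQM bounds per species are
  determined once, on that species' best-SNR acquisition (on a lightly
  smoothed copy — σ = 2 bins, with the detection floor rescaled for the
  smoothing — because a raw noise spike yields near-zero-width bounds),
  and every acquisition is integrated over those fixed bounds.
  Re-searching bounds on each noisy spectrum truncates weak peaks (any
  noise dip crosses quarter-max early) and biases the summed ratio;
  with fixed bounds the per-acquisition noise integrates to zero mean.
  The stronger species' quarter-max half-widths are reused for the
  weaker one about its own apex: the captured lineshape fraction is then
  identical for (near-)equal linewidths and cancels in the ratio, where
  per-species bounds would inherit the weak peak's noise-inflated apex
  estimate.  A species whose apex never clears `k·σ` (k = 3) — or a
  relative floor of 1e-3 of the other species' apex, which screens the
  tall peak's own tail in noiseless data — contributes zero.
  `integrate_fwqm` itself keeps the simple contract (area 0 below the
  detection floor) for single-spectrum use.

Measured behavior of the full estimator under the default acquisition:
noiseless absolute error ≤ 4e-4 across kPL ∈ [0, 0.1] s⁻¹, and a mean
drift of ~0.004 caused by ±60° zero-order phase plus random cubic
baseline corruption at peak SNR 20 (paired against the same noise
realizations without corruption, 50 replicates).

## ¹H quantification

Processing reuses the spectral operators with two specializations:
phasing is zero-order only and estimated on the DSS singlet.  A
pulse-acquire spectrum with a short dead time needs no first-order term;
more importantly, estimating phase on a multiplet component inherits its
twin's dispersion tail (several degrees of bias that propagates into
area errors of a few percent through the quarter-max crossings), while
the reference singlet is isolated by construction.  A residual *global*
phase error biases every Lorentzian by the same lineshape factor and
cancels in the DSS ratio; a first-order residual would not.

The axis is referenced by shifting the parabolically interpolated DSS
apex to exactly 0 ppm.  Assignment matches library multiplet components
(Pascal-weighted, spacing J/f0) against picked peaks within a tolerance
(default 0.02 ppm); quantification integrates each component of the
designated quantification multiplet between FWQM crossings within a
tight window around its matched position (±0.005 ppm — the position is
already known, and a wide window would lock onto taller neighbors such
as the phosphocholine/glycerophosphocholine pair 5.5 Hz apart).
Proton normalization (A/N) is applied explicitly; without it absolute
concentrations are undefined.

The shipped library covers ten metabolites prominent in brain-tumor
extracts (alanine, lactate, glycine, valine, phosphocholine,
glycerophosphocholine, phosphoethanolamine, glutathione, NAD⁺, creatine)
with literature shifts; the table schema accepts arbitrary panels.
Measured recovery: dilution-series slope within 1 ± 0.013 per metabolite
(noiseless), ≤ 5% relative error at SNR ≥ 20.

## IHC morphometry

Color deconvolution follows the optical-density formulation:
OD = −log10(max(I,1)/255) per channel, unmixed by the pseudo-inverse of
the stain matrix completed with the normalized cross product of the two
stain vectors; negative concentrations are clipped.  Default vectors are
the standard published H-DAB pair (as shipped by scikit-image);
configurable.  The DAB channel is thresholded at a fixed 0.15 OD by
default — chosen as a round value well above nonspecific background and
well below specific staining in the forward model — with Otsu as the
data-driven alternative; both are recorded in provenance.  Three
non-overlapping 340×256 ROIs are placed uniformly at random among the
fully-contained corner positions (with restarts, so an unlucky first
placement cannot exhaust the feasible region), plus one background ROI
fully outside the tumor; background percent area is subtracted per ROI
and negative values are kept so the average stays unbiased.

The synthetic scene thresholds a smoothed Gaussian random field at the
designed quantile, so the positive fraction is exact by construction;
nuclei are hematoxylin-only disks, making the unmixing genuinely
two-stain.  Membrane localization thins blobs to rings at equal total
area.

## Volumetry

Volume per plane is voxel count × in-plane pixel area × slice spacing.
For gapped 2-D acquisitions the default spacing is thickness + gap
(center-to-center): each excited slab represents its full repeat
interval, which is how gapped stacks are conventionally volumetrized.
The thickness-only mode is exposed because segmentation tools differ;
the two differ by the gap fraction (25% here), so the choice must be
reported with any absolute volume.  The three T2-weighted planes are
averaged arithmetically.

## Longitudinal statistics

Fisher's LSD is deliberately unadjusted (that is its definition);
adaptive FDR control is applied where many parallel contrasts arise (the
metabolite panel).  The two-stage BKY procedure runs BH at q/(1+q),
estimates the null count as m − r1, and re-runs BH at the sharpened
level; the reported q-values are defined so that (q-value ≤ Q) ⇔
rejection, and are therefore level-dependent — the rejection set is the
contract, the q-values bookkeeping.  Logrank O, E and the hypergeometric
variance come from an explicit risk-table walk; the hazard ratio is
(O₁/E₁)/(O₂/E₂) and is flagged non-estimable when an arm has no events.
Median survival is the smallest time with S(t) ≤ 0.5.  Trend slopes are
OLS on per-day group means by default (an "average trajectory" reading;
per-observation mode is provided); an exactly linear input is reported
with p = 1 for a zero slope and p = 0 otherwise, using a rounding-level
residual floor.  Slope equality is tested through the interaction term
of a pooled two-line regression.  Repeated measures use complete-case
one-way RM-ANOVA with the Greenhouse–Geisser epsilon from the
double-centered condition covariance (ε = 1 identically for two
conditions); a full unbalanced mixed-effects model is out of scope, and
exact reproduction of software that fits one is not claimed.

## Synthetic cohort design

The cohort generator encodes the study conditions as trajectory
parameters: control arm (n = 3) flat at nLac 0.26; untreated arm (n = 5)
linear with slope 0.0069/day anchored at 0.45 on Day 34, tumor volume
log-linear from 1.4 mm³ (Day 5) to 88.6 mm³ (Day 34); treated arm
(n = 10) declining from a Day-28 baseline of 0.44 to 71% of baseline by
Day 48, then rising at 0.0067/day; administrative censoring at Day 94.
Subject-level intercepts and residuals are Gaussian (log-normal
multiplicative for volumes); measurements after death are absent.  With
both noise terms at zero the per-day arm means equal the design exactly,
which is what the end-to-end demo verifies.

The survival-only design uses the full study scale (102 untreated vs 59
treated) with log-normal death times.  The medians (34 and 88 days) and
the logrank hazard ratio (≈4.6) are all design conditions; a single
shared spread cannot satisfy all three, so the per-arm sigmas were
calibrated once against them (σ = 0.58 untreated, 0.30 treated).  Under
Day-94 censoring the treated median is occasionally non-estimable
(~7% of replicates); replicate averages exclude those.

## What the synthetic validation does not show

The forward models use ideal Lorentzian lines, a common linewidth per
stack, no frequency drift, no B1 inhomogeneity, no alanine or
pyruvate-hydrate resonances, pixel-independent stain noise, and exactly
elliptical tumors.  Passing the suite demonstrates the chain is
internally consistent and unbiased under these conditions; real data add
lineshape distortions, baseline roll from dead-time effects, stain
variability and segmentation uncertainty that the corruption models only
approximate.  Problem sizes throughout (60-spectrum stacks, 32k-point
¹H FIDs, 1360×1024 scenes, 400-replicate calibrations) were chosen so
every claim is testable in seconds to minutes on one core.
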