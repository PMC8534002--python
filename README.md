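# hypermet

Longitudinal tumor-metabolism measurement chain for preclinical
glioblastoma studies: dynamic hyperpolarized ¹³C MRS processing into the
normalized-lactate statistic, ex vivo ¹H-NMR metabolite quantification,
DAB immunohistochemistry morphometry, plane-averaged MRI volumetry, and
the longitudinal statistics that tie them together — plus synthetic
forward models for every input, so the whole chain is verifiable at desk
scale with known ground truth.

## Who this is for

Groups running serial hyperpolarized [1-¹³C]pyruvate experiments in tumor
models (development → radiotherapy → regression → recurrence) who need a
tested, scriptable replacement for the usual mix of vendor tools and
one-off scripts, and a way to validate each processing stage against
simulated data before trusting it on animals.

## The core quantities

**nLac.** A time-resolved stack of ¹³C spectra (one spectrum every TR
during the hyperpolarized bolus) is processed per spectrum — exponential
apodization, DFT, automatic phase correction, polynomial baseline
correction — and the pyruvate and lactate resonances are integrated
between their full-width-quarter-maximum (FWQM) crossings.  Summing the
integrals over the stack gives

    nLac = Σₜ A_lac(t) / ( Σₜ A_lac(t) + Σₜ A_pyr(t) )  ∈ [0, 1],

a model-free surrogate for the apparent pyruvate→lactate conversion rate
kPL.  The forward model is a unidirectional two-pool exchange
(dMp/dt = −(1/T1p + kPL)·Mp, dMl/dt = kPL·Mp − Ml/T1l) sampled by
repeated small-flip excitations.

**Pool sizes.** ¹H spectra of tissue extracts are referenced to the DSS
singlet (0 ppm, 9 protons, known concentration) and quantified by
proton-normalized area ratios,
c_met = c_DSS · (A_met/N_met)/(A_DSS/9), then divided by the pulverized
tissue mass → µM/mg.

**Percent stained area.** RGB brightfield images are unmixed by
optical-density color deconvolution (Beer–Lambert, published H-DAB stain
vectors), the DAB channel thresholded, and percent-positive area computed
in three random 340×256 tumor ROIs minus one background ROI.

**Volumes.** Voxel counts × voxel geometry per imaging plane
(center-to-center slice spacing by default), averaged over the coronal,
sagittal and axial T2-weighted segmentations.

**Statistics.** One-way ANOVA with Fisher-LSD follow-ups, the
Benjamini–Krieger–Yekutieli two-stage adaptive FDR, Kaplan–Meier medians
with Mantel–Cox logrank and O/E hazard ratio, trend-slope fits and
comparisons, complete-case repeated-measures ANOVA with the
Geisser–Greenhouse correction, percent-of-baseline normalization, and
cutoff classifier metrics.

## Worked example

```python
from hypermet.hp_mrs import AcquisitionConfig, compute_nlac
from hypermet.synthetic_data import (ExchangeParams, simulate_hp_dynamics,
                                     synthesize_fid_stack)

acq = AcquisitionConfig()            # FA 25°, TR 2 s, 60 spectra, 5 kHz
dyn = simulate_hp_dynamics(ExchangeParams(kpl=0.05), acq)
stack = synthesize_fid_stack(dyn, seed=1)
res = compute_nlac(stack)
print(f"true nLac {dyn.true_nlac:.4f}  estimated {res.nlac:.4f}")
```

prints

```
true nLac 0.3573  estimated 0.3572
```

i.e. at an apparent conversion rate of 0.05 s⁻¹ the spectral pipeline
recovers the ground-truth summed-amplitude ratio to ~1e-4.  The numbered
scripts under `analysis/` run each stage end to end and write their
tables and figures to `results/`; `analysis/05_longitudinal_statistics.py`
prints, for a noisy three-arm cohort, the fitted development slope
(~0.0069/day by design), the flat control arm at nLac ≈ 0.26, the
recurrence slope (~0.0067/day), the treated arm bottoming near 71% of its
post-treatment baseline, the two-arm survival comparison (medians near 88
vs 34 days, hazard ratio ≈ 4.6), and the nLac > 0.4 classifier
(sensitivity 100%, specificity 60% on the worked outcome table).

## Layout

- `src/hypermet/` — the library: `hp_mrs`, `nmr_metabolomics`,
  `ihc_quant`, `volumetrics`, `stats_longitudinal`, `synthetic_data`,
  `io`, `deposit`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — models, assumptions, numerical choices and limits.
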