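# rssi-nwu

Quantification and improved visualization of recent small subcortical
infarcts (RSSIs) of the thalamus on non-contrast CT.

Acute lacunar infarcts are reliably seen on diffusion-weighted MRI but are
easy to miss on early CT, where ionic edema lowers attenuation by only a few
Hounsfield units. This package implements the full measurement and
display-optimization chain for that problem, aimed at imaging researchers who
want a tested, reproducible reference pipeline:

* **Phantoms** — seeded synthetic CT/DWI head pairs with exact analytic
  ground truth (lesion masks, rigid misalignment, net water uptake).
* **Spatial** — threshold brain extraction, DWI lesion segmentation with
  erosion and ~10 % boundary shrink, rigid multimodal co-registration
  (SimpleITK, Mattes mutual information), normalization to a built-in
  symmetric head template, and mirroring of the lesion across the
  mid-sagittal plane to sample homologous contralateral tissue.
* **Quantify** — net water uptake
  `NWU (%) = (1 − HU_ischemic / HU_normal) × 100`, onset-to-CT time-window
  grouping (0–6, >6–12, >12–24, >24–36 h), cohort summaries with paired
  t-tests.
* **Enhance** — data-driven display windowing (level = mean, width = 2 × SD
  of the measured infarct attenuations) and frequency-selective non-linear
  blending (FSNLB): band-limited amplification of low-spatial-frequency
  contrast with a tanh remap, slope 0 → bit-exact identity.
* **Evaluate** — reader-study statistics: confidence dichotomization,
  localization-gated true positives, three-reader majority consensus,
  sensitivity/specificity/PPV/NPV, Fleiss kappa, Fisher exact comparisons.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_quantify_cohort_nwu.py` builds one noise-free phantom per
time window (ground-truth NWU 6.4 / 7.3 / 14.4 / 16.6 %), runs the whole
pipeline — DWI lesion segmentation, shrink, rigid registration, template
normalization, midline mirroring, attenuation sampling — and prints:

```
    window  truth NWU %  measured NWU %
     0–6 h          6.4            6.40
   >6–12 h          7.3            7.30
  >12–24 h         14.4           14.40
  >24–36 h         16.6           16.60
```

The recovered NWU matches truth to well under one percentage point: the
eroded, shrunken lesion sample stays inside the true lesion after
registration (typical recovery error ≈ 0.3°, 0.05 mm), and its mirror stays
inside homologous contralateral tissue. `examples/04_enhance_fsnlb.py` prints
the derived display parameters:

```
optimized window level/width: 30/6 HU
windowed display: lesion mean 0.46, contralateral mean 0.84 (0 = black, 1 = white)
plateau pair at centre +/- 1 HU: contrast 2.00 -> 3.63 HU
```

i.e. a 3.7 HU lesion/contralateral difference that occupies a sliver of a
standard brain window fills most of the grayscale after optimization, and
FSNLB amplifies in-band plateau contrast ~1.8×.

A thin CLI mirrors the library:
`rssi-nwu phantom|coregister|quantify|enhance|evaluate|run` (exit codes:
0 success, 1 validation error, 2 computation failure), e.g.

```sh
rssi-nwu phantom --nwu 10 --seed 1 --out case1
rssi-nwu enhance --mode fsnlb --center 30 --delta 6 --slope 5 case1/ct.nii.gz out.nii.gz
```

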