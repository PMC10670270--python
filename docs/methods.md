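# Methods

## Problem and model

Recent small subcortical infarcts (RSSIs) of the thalamus are poorly visible
on early non-contrast CT: the ischemic tissue loses only a few Hounsfield
units relative to the contralateral thalamus. The package quantifies this
loss as net water uptake,

    NWU (%) = (1 − HU_ischemic / HU_normal) × 100,

where `HU_ischemic` is the mean attenuation inside the infarct region (defined
on DWI, where acute infarcts are bright) and `HU_normal` the mean inside the
homologous mirrored region of the unaffected contralateral thalamus. Negative
measured NWU values are kept — clipping at zero would bias cohort means
upward when noise dominates an early, subtle lesion.

Cases are grouped by onset-to-CT time window (0–6, >6–12, >12–24, >24–36 h;
lower-exclusive/upper-inclusive boundaries, 0 included in the first window).
Window summaries report sample means and SDs (n−1 denominator) and a paired
two-sided t-test of infarct vs contralateral attenuation: the two samples
come from the same subject, so an unpaired test would discard the pairing and
overstate the variance. The window NWU summary is the mean of per-case NWU
values, which differs in general from the NWU of the window-mean HU values.

## Spatial workflow

1. **Brain extraction** — threshold segmentation (default 0–100 HU), largest
   connected component, hole filling.
2. **DWI lesion segmentation** — voxels brighter than brain mean + k·SD
   (default k = 3) within the brain mask, largest component, one binary
   erosion pass, hole filling.
3. **Lesion shrink** — the mask is further reduced to ~90 % of its volume by
   peeling boundary voxels in order of Euclidean distance to the background
   (anisotropy-aware, in mm). "90 % of volume" rather than diameter, because
   the point of the shrink is excluding partial-volume boundary voxels from
   the attenuation sample. Ties within the cut distance class are broken by
   voxel index order so the result is deterministic.
4. **Rigid co-registration (DWI → CT)** — SimpleITK, Mattes mutual
   information (50 bins, 20 % random sampling with a fixed seed), 3-level
   pyramid (shrink 4/2/1, smoothing 2/1/0 mm), regular-step gradient descent.
   Because the optimizer normalizes the gradient, its first move always steps
   away from the start; the final transform is therefore compared against the
   initialization by metric value and the better of the two is returned,
   which makes the already-aligned case exact.
5. **Template normalization** — a symmetric head template is generated by the
   package itself (the lesion-free, noise-free phantom anatomy); its only
   role is to fix the mirror plane at x = 0 in template coordinates, so no
   external atlas is needed. Normalization runs in two stages, rigid then
   full affine refinement, because the near-ellipsoidal head geometry gives
   the 12-DOF problem a weak rotational gradient; the rigid stage carries the
   pose. The metric is correlation (both images are CT-like).
6. **Midline mirroring** — the lesion mask is carried to template space,
   reflected about x = 0, and carried back, composed into a single affine so
   only one nearest-neighbour resampling occurs. Masks always use
   nearest-neighbour interpolation, images linear.

Transforms map source-space world mm to target-space world mm; all I/O is in
physical RAS millimetres through the NIfTI affine, and voxel indices never
appear in user-facing output.

## Display optimization

The display window and the frequency-selective non-linear blending (FSNLB)
band are both derived from the measured infarct attenuation distribution:
level/centre = sample mean, width/delta = 2 × sample SD, rounded half-up to
integer HU. Delta is interpreted as the full band width, by analogy with the
window width.

FSNLB decomposes the CT into a Gaussian low-pass component L (default scale
3 mm) and the residual high-pass H = I − L, and remaps L inside
[centre − delta/2, centre + delta/2] with

    S(v) = centre + (delta/2) · tanh(α (v − centre)/(delta/2)) / tanh(α),

identity outside the band, blended at intensity slope/5 (slope ∈ [0, 5]).
α is fixed at 2.0, giving a bounded centre gain α/tanh(α) ≈ 2.08. The
implementation computes `I + (slope/5)(S(L) − L)`, which is algebraically the
blend `(1 − slope/5)L + (slope/5)S(L) + H` but returns the input *bit-exactly*
at slope 0 and wherever L lies outside the band. Output stays in HU so
enhanced volumes can be re-windowed. The commercial blending curve this
emulates is proprietary; only the contracts above (band-limited action,
slope-0 identity, low-frequency selectivity, monotone continuous remap) are
promised, not bit-compatibility.

**Limitation (measured, not assumed).** Amplifying in-band low frequencies
also amplifies their share of the noise, so the lesion/contralateral
contrast-to-noise ratio improves only when the contrast itself lies inside
the band and the lesion is resolved relative to the low-pass scale. At this
cohort's configuration — 0.35 cm³ lesions and a 30/6 HU band that leaves the
33.3 HU contralateral value just outside — the mask-mean CNR is *not*
improved; partial-volume mixing pulls the low-pass lesion values off-centre.
The CNR property test therefore uses a resolved lesion (1.5 cm³) and a band
wide enough to contain both tissues (delta 10 HU), where the ratio exceeds 1
for every seed tested. For 0.35 cm³ lesions the narrow derived window, which
spreads the 3.7 HU contrast over the full grayscale, carries the visual
improvement.

## Reader-study statistics

Reader calls use a 4-level confidence scale; 1–2 count as positive. On a
positive case, a true positive requires both a positive call and a correct
lesion mark (a mark is correct inside the true lesion dilated by 2 mm — a
pointing tolerance for sub-centimetre targets); a correctly marked case read
with confidence 3–4 counts as not marked. A wrong-location positive call on
a positive case is a false negative only, never simultaneously a false
positive, because specificity is computed over the negative-control cases
alone. Consensus of three readers is a majority vote (a consensus TP needs
two positive-and-correct calls) — "consensus" without a protocol is not
reproducible, majority is. Percentages are rounded half-up to integers.
Fleiss kappa (via statsmodels, oracle-tested against the closed formula) is
undefined when every rating falls in one category and raises rather than
returning a number. Fisher exact comparisons use the two-sided hypergeometric
tail; a zero margin yields p = 1 by convention.

## Synthetic phantoms

The phantom is an analytic tissue model evaluated on the voxel grid: an
ellipsoidal brain (semi-axes 58/73/48 mm, 30 HU) inside a skull shell
(900 HU) surrounded by air (−1000 HU), two mirror-symmetric ellipsoidal
thalami (semi-axes 8/10/8 mm, default 33.3 HU with 2.6 HU voxelwise texture),
and a thalamus-shaped lesion of configurable volume (default 0.35 cm³) whose
attenuation is `thalamus_mean × (1 − NWU/100)`. The DWI channel shows the
same anatomy on its own grid (default 1 × 1 × 3 mm), rigidly misaligned by a
known perturbation, with the lesion at least 5 noise-SDs above the brain
signal. CT noise is additive Gaussian (default SD 1 HU), added after the
deterministic tissue model; optional rounding to integer HU is off by default
so analytic checks stay exact.

Two constructions make ground truth exact rather than approximate:

* the within-thalamus texture field is generated mirror-symmetrically and
  demeaned over the lesion footprint, so the lesion and contralateral sample
  means equal their nominal values to machine precision while texture
  variance is preserved elsewhere;
* the DWI volume is produced by evaluating the analytic anatomy at rigidly
  transformed coordinates — no interpolation — so the true lesion masks on
  both grids are exact indicator functions.

What the phantom does **not** emulate: cortical folding, CSF spaces,
beam-hardening or streak artifacts, white-matter lesion backgrounds,
multi-lesion anatomy, and the split between between-patient and
within-measurement attenuation variance (both knobs — `thalamus_sd_hu` and
`noise_sd_hu` — are exposed instead of guessing the split). Passing tests
therefore demonstrate correctness of the measurement machinery under known
geometry, not clinical performance on real heads.

## Problem sizes and numerical choices

* Default CT grid 96 × 112 × 80 at 1.5 mm (the thin-slice protocol the method
  targets); DWI 1 × 1 × 3 mm.
* Cohort-level checks use 4 windows × 11 cases (the largest window count of
  the cohort the defaults emulate) at 1 HU noise; a full 44-case pipeline run
  takes a few minutes on one CPU. Noise-free single-case-per-window runs
  bound the systematic error (< 0.1 percentage points NWU); the noisy cohort
  bounds the statistical error (window means within 2 points).
* Registration tolerances are contract values: 1 mm / 1° recovery of imposed
  perturbations, mirror involution Dice ≥ 0.95, template mid-plane mapping
  within 2 mm. Fixed sampling seeds make all registrations reproducible;
  `RunConfig.seed` feeds every stage and is recorded in output sidecars.
* Degenerate inputs fail loudly with typed errors: empty selections, constant
  windows (SD = 0), single-category rating matrices, out-of-range onset
  times, non-invertible transforms.
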