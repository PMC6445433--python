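# Methods

## Scope and model of the data

`octaq` quantifies perfusion from 2-D *en face* OCT-angiography projections
and compares the resulting metrics between a cognitively impaired arm
(amnestic MCI pooled with early AD) and 1:1 matched controls. An angiogram is
modelled as a square grid of SSADA decorrelation values normalised to [0, 1],
with a physical field width (3.0 mm macular scans centred on the fovea,
4.5 mm disc scans centred on the optic nerve head, nominally 304×304
samples). The package assumes exported intensities are linear in
decorrelation; if a device applies a display gamma before export, the AFI
(but not VD/VLD) changes meaning. Layer segmentation (SCP, DCP, whole
retina, RPC, SVC) is consumed as given, never computed.

## Regions of interest

All metrics are computed over annuli: the parafovea (1.0–3.0 mm ring
diameters around the fovea) and the peripapillary "donut" (2.0–4.0 mm around
the disc centre), optionally one of four 90° quadrants. Conventions chosen
for exact reproducibility:

* 0-based (row, col) indices; distances between pixel centres;
  `um_per_px = 1000 · field_mm / width` (≈9.87 µm at 3 mm/304 px, ≈14.8 µm at
  4.5 mm/304 px).
* Annulus membership is half-open (`inner_radius ≤ d < outer_radius`) so
  concentric rings partition without overlap; quadrant boundaries are the two
  45° diagonals, half-open, so the four quadrants partition the annulus
  exactly. Pixel-counted area converges to the analytic ring area with
  resolution (within 1 % at 304 px for the parafovea).
* Image "up" is the superior retina. Temporal/nasal depend on laterality:
  for OD, image-left is temporal (configurable per eye, since export
  orientation is device-dependent).
* An outer ring that exceeds the field is clipped at the image edge and
  densities are taken over the clipped mask.

## Binarization

Three thresholding routes, all strict (`value > t` is vessel; ties are
background):

* **Phansalkar local threshold** (disc scans):
  `t = m·(1 + p·e^(−q·m) + k·(s/r − 1))` with local mean `m` and SD `s` over
  a 15×15 px window, mirror padding at the edges. Constants `p=2, q=10,
  k=0.25, r=0.5` are the canonical defaults of the ImageJ auto-local-threshold
  family for [0, 1] images; the window size follows the published protocol.
  Implementation is two `uniform_filter` passes; a brute-force per-pixel
  oracle in the tests checks exact mask equality.
* **Shanbhag global threshold** (used inside the large-vessel mask): the
  fuzzy-entropy information measure of Shanbhag (1994), minimised by an
  exhaustive scan over all 256 histogram bins. A constant image has no
  threshold; the defined fallback is all-background with a warning.
* **FAZ-background threshold** (macular scans): the foveal avascular zone is
  delineated by flood growth from a seed (default: image centre) over pixels
  at or below `mean + 2·SD` of a 0.3-mm seed disc; the global noise threshold
  is then `mean + 2·SD` of the delineated zone. The multiplier, seed and
  growth rule are configuration parameters; `mean + 2·SD` is the conservative
  reading of "background signal as the threshold". Two safeguards make the
  delineation robust: growth is bounded to the central 1.0-mm zone (the
  fovea lies inside the parafoveal inner ring) and isolated supra-threshold
  noise pixels inside the zone are hole-filled — without the bound, a region
  grown at a 2-SD threshold leaks through gaps of any imperfect capillary
  ring into the image background. A seed landing above the image's Otsu
  split is rejected as lying on a vessel.

## Metrics

* **VD** = 100·|vessel ∧ ROI| / |ROI|.
* **VLD** = 100·|skeleton ∧ ROI| / |ROI|, with the skeleton the 1-px-wide
  topology-preserving thinning of the binary map (scikit-image
  `skeletonize`, equivalent in its guarantees — one-pixel width, idempotence,
  subset of the mask, topology preservation — to the ImageJ 2-D skeletonizer
  used in the published workflows). Length is the skeleton pixel count, so
  VLD shares VD's percent scale and VLD ≤ VD for the same binarization.
* **Microcapillary VD**: the large-vessel mask is built by contrast
  stretching (0.5/99.5 percentiles), Shanbhag thresholding, and removal of
  8-connected components below a size floor; surviving components are the
  major arterioles/venules, and they are removed from both numerator and
  denominator of the density. The published removal criterion "< 25 µm²" is
  smaller than one pixel at the native disc sampling (1 px ≈ 219 µm²), so it
  cannot have been applied in physical units at that resolution; applied in
  ImageJ pixel units (an uncalibrated image) it means 25 px ≈ 5 475 µm²,
  which is the default here (`min_component_px = 25`). A physical µm²
  criterion with a one-pixel floor is available instead; the discrepancy is
  deliberate and surfaced, not silently resolved.
* **AFI** = mean decorrelation over vessel pixels inside the ROI (macular
  scans, FAZ-background binarization; ROI-restricted rather than whole-image
  by default). Computed on the [0, 1]-normalised image, so absolute values
  depend on export scaling.
* **FAZ area** = delineated-zone pixel count × pixel area, in mm².

Per-eye orchestration applies the device quality gates (SQ ≥ 6; SSI ≥ 50
macula, ≥ 45 disc); failing scans are skipped with a log entry and the run
continues.

## Cohort statistics

One eye per participant: OD if it passes the gates and has no pathology
flag, else OS, else exclusion (logged). Group comparisons use Student's
t-test when both groups pass Shapiro–Wilk at α = 0.05 and Mann–Whitney U
otherwise (exact U for combined n ≤ 25 without ties, tie-corrected normal
approximation with continuity correction otherwise); the gate can be forced
either way because published tables rarely state the per-variable choice,
and the per-variable normality p-values and chosen tests are written to a
diagnostics file. Effect sizes are Hedges' g = J·(m_c − m_i)/s_pooled with
J = 1 − 3/(4N − 9); the uncorrected d is also reported. Correlations with the
MoCA score over the entire cohort use the same normality gate
(Pearson/Spearman); Spearman p-values are exact permutation enumerations for
n ≤ 8 without ties. Inter-grader reliability uses two-way single-measure
ICCs computed directly from ANOVA mean squares (McGraw–Wong): ICC(A,1)
(absolute agreement, penalises rater offsets) and ICC(C,1) (consistency).
No multiple-testing correction is applied, matching the single-study
analysis the package reproduces; missing values are dropped listwise per
variable with n reported per row.

## Synthetic data

The generator exists to make every pipeline stage testable against known
truth; it aims for controllable density truth, not biological realism.

* **Angiograms**: random branching arteriole/venule trees walked in from the
  image border (trunk calibre 4–7 px, thinner branches) plus a jittered-grid
  capillary mesh (spacing 14 px, calibre 2 px; a density factor scales line
  count and hence true VD monotonically). Macular scans carry an elliptical
  avascular zone (0.30 × 0.25 mm radii) cleared of vessels and bounded by a
  continuous 2-px capillary ring — the synthetic analogue of the capillary
  arcade that encircles the real FAZ, and the feature that lets seed-grown
  delineation terminate. Perfused pixels draw decorrelation N(0.40, 0.05)
  (capillaries) or N(0.60, 0.06) (major vessels — large vessels decorrelate
  brighter, which is also what makes the Shanbhag large-vessel mask
  separable); background is Rician with floor ν = 0.08 and σ = 0.04. The
  Rice floor was chosen over a half-normal because its `mean + 2·SD`
  exceedance (≈2.3 %) keeps the FAZ-threshold false-positive load compatible
  with ±2 pp VD recovery; a half-normal floor exceeds its own 2-SD threshold
  ≈4.5 % of the time at any scale, which no noise magnitude can fix. Truth
  masks, per-ROI true VD/AFI, skeleton length and FAZ area are recorded at
  construction. Everything is deterministic given the integer seed.
* **Cohorts**: per participant a latent severity u ~ N(0, 1) is shared by
  every variable: `x = µ_g + σ_g (λ·u + √(1−λ²)·ε)`, so group means/SDs match
  their targets up to sampling error and loadings λ set the within-group
  correlation structure (MoCA λ = 0.8; vascular metrics 0.1–0.55). Pooled
  cohort-wide correlations between MoCA and the metrics therefore combine
  the between-group contrast with the shared factor and come out somewhat
  stronger than typical single-study reports. Default moments are the
  16 + 16 early-impairment case-control structure (e.g. parafoveal SCP VD
  40.67 ± 5.23 vs 44.50 ± 4.11 %, AFI 0.376 ± 0.041 vs 0.407 ± 0.037, MoCA
  20.25 ± 3.80 vs 27.06 ± 2.21). Controls are matched 1:1 on age (±3 y),
  gender and race; CDR is generated on its discrete scale (0.5/1.0 mixture
  for cases, 0 for controls); cognitive scores are clipped to instrument
  ranges and rounded to integers, which shrinks near-ceiling SDs slightly
  (e.g. control MoCA SD ≈2.0 vs the 2.21 target) — clipping counts are
  logged, and the 2-standard-error calibration check is asserted on the
  vascular metrics, which are unclipped in practice.
* **End-to-end fixture**: a miniature study (default 4+4 participants, two
  152-px scans each) written to disk together with the tables the pipeline
  must reproduce byte-for-byte. The expected tables are computed from the
  images *as stored* (16-bit quantisation included), and cohort CSVs are
  written/parsed at full round-trip float precision, so regeneration and
  re-analysis are bit-identical.

What passing these tests does **not** show: recovery on real angiograms with
projection artifacts, motion lines, media opacity, or vessel-calibre and
brightness distributions unlike the generator's; nor robustness of the
statistics to the matching failures and informative missingness real cohorts
contain.

## Problem sizes and numerical choices

Synthetic angiograms default to the native 304-px sampling; fixture studies
use 152 px and 4+4 participants to keep golden-file runs fast. Simulation
checks use 200 cohort replicates (moment calibration, effect-size recovery)
and 2 000 null replicates (type-I calibration of the gated test). At the
default conditions the gated test rejects a true parafoveal-VD deficit
(d ≈ 0.81, n = 16/16) in ≈60 % of replicates — the package's own power
analysis of that design. Degenerate inputs are defined, not undefined:
zero-width annuli are empty; constant images fall back to all-background
with a warning; empty ROIs and all-large-vessel ROIs are rejected; AFI over
an empty selection is NaN with a warning; zero pooled variance flags g as
undefined rather than raising.

## Known limitations

* The FAZ delineation is seed-grown and bounded to the central 1 mm; very
  large or displaced avascular zones would be truncated (a warning-free
  limitation of the default bound).
* VLD's pixel-count length slightly undercounts diagonal runs (a diagonal
  step is √2 px long but counts 1); all published VLD percent values share
  this convention, so comparisons are internally consistent.
* Thinning is not exactly isotropic: a 90° rotation changes VLD by up to
  ~0.1 pp while VD and AFI are exactly invariant.
* The statistical battery reproduces a specific published analysis; it
  deliberately omits covariate adjustment, multiple-testing correction and
  classification metrics.
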