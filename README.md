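# octaq

Vascular quantification of *en face* OCT-angiography (OCTA) images and the
matched case-control statistics built on top of it.

OCTA maps perfused retinal vessels by the decorrelation of repeated B-scans.
In early Alzheimer's-spectrum cognitive impairment (amnestic MCI and early
AD), capillary dropout and reduced flow in the inner retina are candidate
non-invasive biomarkers. `octaq` implements the standard quantification
recipe for this literature — per-layer binarization, skeletonization and
region-of-interest densitometry — plus the two-group statistical battery
used to compare a pooled impaired arm against 1:1 matched controls, and a
synthetic-data generator so the whole pipeline is testable without any
patient imaging.

## Metrics

For an annular region of interest **R** (the parafovea, 1.0–3.0 mm ring
diameters around the fovea, or the peripapillary donut, 2.0–4.0 mm around
the disc) and a binary vessel map **B**:

* **Vessel density** VD = 100·|B ∩ R| / |R| — Phansalkar 15×15 local
  thresholding on disc scans (`t = m(1 + 2e^(−10m) + 0.25(s/0.5 − 1))`),
  a noise threshold of mean + 2·SD of the foveal avascular zone (FAZ)
  background on macular scans.
* **Vessel length density** VLD = 100·|skeleton(B) ∩ R| / |R| — the
  1-px-wide skeleton removes the calibre weighting of VD.
* **Microcapillary VD** — VD after removing the large arterioles/venules
  (contrast stretch → Shanbhag threshold → small-component removal; the
  survivors mask out the big vessels).
* **Adjusted flow index** AFI = mean decorrelation over B ∩ R, a flow-velocity
  surrogate in [0, 1].
* **FAZ area** in mm² from the seed-grown avascular-zone mask.

Cohort statistics: per-participant eye selection with device quality gates
(SQ ≥ 6, SSI ≥ 50 macula / ≥ 45 disc), Shapiro–Wilk-gated Student's
t / Mann–Whitney U comparisons, Hedges' g = J·Δm/s_pooled with
J = 1 − 3/(4N − 9), gated Pearson/Spearman correlations of every metric with
the MoCA cognitive score, and two-way single-measure ICCs — absolute
agreement ICC(A,1) and consistency ICC(C,1) — for inter-grader reliability.

## Worked example

Generate a synthetic macular angiogram with known ground truth and quantify
it:

```sh
$ octaq synth angiogram --seed 7 --out syn/
{
  "seed": 7,
  "true_vd_percent": { "global": 49.04, "parafovea": 51.57 },
  "true_afi": { "global": 0.4822, "parafovea": 0.4830 },
  "faz_area_mm2": 0.2032,
  "skeleton_len_px": 13482
}
$ octaq quantify --macula syn/angiogram.tif --out metrics.csv
layer       roi       metric     value
  SCP parafovea           vd 52.984797
  SCP parafovea          vld 16.658393
  SCP parafovea          afi  0.474822
  SCP     fovea faz_area_mm2  0.202757
```

The measured parafoveal VD (52.98 %) recovers the generator's truth
(51.57 %) within 1.5 percentage points — the residual is the false-positive
load of the FAZ-background threshold on the Rician noise floor; AFI (0.475
vs 0.483) and FAZ area (0.2028 vs 0.2032 mm²) recover within 0.01 and 0.5 %
respectively.

A full synthetic case-control study, through eye selection and the
statistical battery:

```sh
$ octaq synth cohort --seed 1 --n-per-group 16 --out cohort.csv
$ octaq cohort --table cohort.csv --out tables/
```

writes `table1.csv` (demographics/cognition), `table2.csv` (vascular
metrics: mean ± SD, range, test used, p, Hedges' g per group), `table3.csv`
(MoCA correlations) and `tableS1.csv`, plus a `diagnostics.json` with the
per-variable normality p-values and test choices. The same `cohort` command
accepts an externally deposited participant spreadsheet (XLSX/CSV) with a
JSON column-name mapping (`--config columns.json`).

As a library:

```python
import octaq

image, truth = octaq.generate_angiogram(seed=7, layer="SCP")
roi = octaq.make_annulus(image, 1.0, 3.0)            # parafovea
binary, faz = octaq.faz_background_binarize(image)
vd  = octaq.vessel_density(binary, roi)
vld = octaq.vessel_length_density(octaq.skeletonize(binary), roi)
afi = octaq.adjusted_flow_index(image, binary, roi)
```

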