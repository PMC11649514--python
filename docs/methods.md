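# Methods

`ki67hotspot` simulates and scores the comparison between automated and
manual Ki67 hotspot assessment in invasive breast carcinoma. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic material does and does not establish.

## The quantity being measured

The Ki67 hotspot proliferation index (PI) is the percentage of
Ki67-positive tumour nuclei among nuclei counted in the tumour subregion
with the apparently highest proliferative activity. The automated
definition used here: an axis-aligned square window of fixed area
(default 0.5 mm², side √0.5·1000 ≈ 707.107 µm) containing at least 500
invasive-tumour nuclei, chosen to maximize the ratio of Ki67-positive to
total nuclei; PI = 100·n⁺/n over *all* nuclei in the winning window. The
manual protocol counts ~500 cells in a typewriter pattern inside a
visually chosen region of interest (ROI).

## Synthetic slides

A case is a pair of RGB "sections" plus exact per-nucleus ground truth.

**Geometry.** Default slide 4×4 mm at 1 µm/px (configurable). The slide
holds exactly one invasive-tumour region (a lobed star-convex blob
covering ≥30% of the slide and fully containing the planted hotspot
window), a configurable number of benign-epithelium and
carcinoma-in-situ distractor blobs placed in the surrounding stroma, and
stroma elsewhere. Coordinates are µm, origin at the top-left pixel
corner, x rightward, y downward; every window is half-open
[x0, x0+s) × [y0, y0+s).

**Nuclei.** Centres follow a hard-core (dart-throwing) point process:
the centre separation of any two nuclei is at least the larger of their
diameters, so rendered discs never overlap. Diameters are uniform in
[6, 10] µm. The target count per region is Poisson(density × area) with
default density 3000 nuclei/mm². Each invasive nucleus is Ki67-positive
with probability

  p(x, y) = base + (peak − base) · exp(−d²/(2r²)),

where d is the distance to the planted hotspot centre, defaults
base = 0.15, peak = 0.6, r = 400 µm. An isotropic Gaussian bump is a
deliberate stand-in: any unimodal field with a known argmax supports the
recovery checks; nothing here is a fitted model of real spatial Ki67
heterogeneity. Benign nuclei are positive at a fixed 5%; in-situ nuclei
at a configurable rate (default 70%, intentionally hotspot-like, so that
*masking* — not luck — must exclude them).

**Rendering.** Nuclei are anti-aliased discs of haematoxylin optical
density 0.8; positive nuclei add DAB OD 0.6, far above the classifier
threshold. A smooth background texture (H OD ≤ 0.02) is added; its
amplitude is far below the nuclear threshold so it cannot create
spurious detections. Pixels are composed by Beer–Lambert (below).

**Serial CK8/18 section.** Epithelial regions are rendered as a
DAB-like membrane blush after a rigid transform (default shift
(60, −40) µm, rotation 1°, about the image centre), and the same nuclei
are re-rendered in haematoxylin at transformed positions with ≤5 µm
per-cell jitter, emulating the ~3 µm section offset. In `non_serial`
mode the CK layout is regenerated from an unrelated seed as scattered
fragments, so no rigid transform aligns the pair — the failure mode of
sections not cut in serial order.

Everything is driven by `numpy.random.Generator` streams spawned from
the case seed: the same seed reproduces bit-identical images and tables.

## Stain model

Forward: I_c = round(256·10^(−OD_c)) − 1 with OD_c = H·S_H,c + DAB·S_D,c;
read-out: OD_c = −log10((I_c + 1)/256), the exact quantized inverse, so
white is exactly OD 0 and saturated black stays finite (ODs clamped at
3.0). Stain vectors default to the Ruifrok–Johnston haematoxylin
(0.65, 0.70, 0.29) and DAB (0.27, 0.57, 0.78), normalized to unit norm;
they are configurable as JSON. Deconvolution is the unweighted
least-squares projection of each pixel's OD 3-vector onto the two stain
vectors; the residual (cross-product) direction is discarded, so the
output is invariant to perturbations along it. Small negative
concentrations are clamped at −0.05.

8-bit quantization bounds the round trip: with both concentrations ≤ 1.5
the darkest channel reaches OD ≈ 1.9, i.e. intensity ≈ 3/255, where one
grey level is worth ~0.07 OD; the measured worst-case recovery error
over the [0, 1.5]² grid is ≈ 0.05 per stain, concentrated at that
corner, and ≤ 0.02 wherever the total per-channel OD stays ≤ ~1.6. This
is an information limit of 8-bit rendering, not an estimator choice: no
decoder can do materially better at that corner. The generator's own
working range (H 0.8, DAB ≤ 0.6) sits well inside the accurate region.

## Nucleus detection and classification

Deconvolve → total nuclear OD (H+DAB) → Gaussian smoothing at a quarter
of the minimum nucleus diameter → threshold (default 0.25 OD) →
distance-transform watershed to split touching blobs → filter by area
(π(min_d/2)² … π(max_d/2)², defaults min_d 5 µm, max_d 13 µm) and
circularity 4πA/P² ≥ 0.4 (permissive, tolerating watershed fragment
shapes). Each surviving component records its centroid, area and mean
stain ODs. Classification: positive iff mean DAB OD ≥ 0.15 — a low
threshold by design, honouring the protocol rule that any intensity of
brown nuclear staining counts as positive; the boundary is inclusive.
On the synthetic forward model this detector achieves F1 ≈ 0.997 and
class accuracy ≈ 1.0; the commercial detector it stands in for is
proprietary, so its contract is stated (and tested) in exactly these
terms rather than cloned.

Evaluation uses greedy one-to-one nearest-neighbour matching within
5 µm — adequate at hard-core spacing and simpler to audit than optimal
assignment.

## Masking: the two automated arms

**VDS arm.** The CK section is registered to the Ki67 section
rigidly: a coarse exhaustive search (rotations ±5° in 1° steps at
~8 µm/px, FFT translation search within ±500 µm) over epithelial
foreground overlap, then refinement on the haematoxylin maps — tissue
outlines of roundish lesions are nearly rotation-blind, while the
shared nuclei lock the angle — with a 0.3°-step sweep at ~4 µm/px and a
0.1°-step sweep with subpixel (parabolic) translation at ~2 µm/px. The
alignment score is the foreground IoU after applying the estimate;
below 0.6 the case is declared a VDS failure and excluded from that arm
(the threshold is configurable; the study's failure criterion is an
artifact decision — the source protocol reports only failure causes).
Typical recovery on serial pairs is ≤0.4 µm and ≤0.12°. The epithelial
mask is the thresholded CK DAB channel warped into the Ki67 frame,
closed at nucleus scale, minus operator-supplied exclusion polygons
(benign/in-situ GeoJSON — the human "manual discard" step).

**Rule arm.** Stands in for the trained tumour-detection model, which
is out of scope (no weights or training data exist here): it rasterizes
the ground-truth invasive-tumour polygons behind the same interface
(`build_mask_rule` also accepts any pluggable detector). It never reads
the CK section and therefore cannot fail for alignment reasons —
reproducing the availability asymmetry between the arms.

Cell membership is centroid-in-mask (not whole-nucleus-in-mask): the
simplest rule that makes counts exactly reproducible.

## Hotspot search

Candidate origins lie on a lattice of pitch `stride_um` (default 25 µm)
with windows fully inside the slide; the paper-level definition is
silent on placement granularity, and a lattice keeps the optimum
well-defined and testable against exhaustive enumeration
(`brute_force_hotspot`, the definitional oracle — the two must agree
exactly). Eligibility: ≥ `min_cells` (default 500) mask-filtered cells.
Objective: positive ratio, compared exactly as integer fractions; ties
break by higher cell count, then smaller y0, then smaller x0. The PI is
over all window cells, not the first 500. Heatmap bins with zero cells
carry an undefined (NaN) ratio, never 0, so stroma cannot dilute the
display.

## Simulated observers

Observers read the *ground-truth* cells, not the detector output: human
perception does not share the algorithm's segmentation errors, so their
noise is modelled separately — a coarse perception grid (250 µm bins),
additive N(0, 0.05) noise on perceived bin ratios, down-weighting (×0.5)
of bins sparser than the 500-cell window-density equivalent (observers
prefer dense tumour over sparse margins), deterministic tie-breaks, and
a per-cell misread probability of 0.03. The ROI (window-sized by
default) is centred on the winning bin, clipped into the invasive
region's bounding box, and grown by 10% steps if it holds fewer than
500 invasive cells.

The typewriter count visits fields of view (default 100 × 50 µm) in
raster order and stops at the end of the field in which the 500th cell
is reached, so counts overshoot 500 by at most roughly one field's
population (~15 cells at default density). This field-quantized stop is
the mechanism chosen to reproduce the count ranges standardized manual
scoring produces in practice (minima 500, maxima in the low 530s);
stopping only at the end of a full ROI-wide row would overshoot by ~100
cells at default density. Setting the field width to the ROI width
recovers the full-row rule.

## Study orchestration and statistics

`run_study` generates n cases, scores each requested arm (vds / rule /
two observers), averages the observers into a consensus, and reports
per-arm six-number summaries (mean, min, Q1, median, Q3, max; quartiles
by linear interpolation — a documented, fixed convention) plus pairwise
agreement: Spearman (Pearson on mid-ranks; Pearson also reported,
labelled), Bland–Altman (differences A−B, SD with n−1, limits
mean ± 1.96·SD, cases strictly outside |d − mean| > 1.96·SD listed) and
a two-sided paired t-test (t undefined→0/p 1 for identical vectors,
±∞/p 0 for constant non-zero differences). VDS-failed cases are
excluded pairwise from VDS comparisons only; a case failing every arm is
reported, never dropped silently. Plots (scatter + Bland–Altman PNGs)
are artifacts; every asserted number comes from the CSV/JSON.

Per-case heterogeneity: unless the study config pins the positivity,
each case draws its hotspot peak positivity from U(0.05, 0.95) and its
baseline as peak × U(0.2, 0.6), spanning the clinical PI range
(~1–90%). Without this the cohort would have a single true PI and
between-case correlations would be vacuous.

## Problem sizes

Defaults were sized so a full check of every contract runs on a laptop
in minutes: image-level checks (detection, registration, the VDS study
arm) use compact slides — 1×1 mm for detection (≈2000 nuclei/case,
20 cases), 1.5×1.5 mm for registration and the 15-case two-arm study —
while cell-level checks (hotspot recovery, observer simulation, the
100-case comparison study) use the full 4×4 mm geometry (≈25,000
nuclei/case). Registration recovery is assessed over 50 seeded pairs
with |shift| ≤ 300 µm and |θ| ≤ 3°; limits-of-agreement coverage uses
4000 Monte-Carlo cohorts per cohort size.

## Known limitations

- The synthetic slides have clean, non-overlapping, circular nuclei and
  a single unimodal positivity bump; real tissue has overlapping,
  pleomorphic nuclei, staining gradients and multimodal heterogeneity.
  Passing contracts here validate the *pipeline logic* (masking,
  search optimality, counting rules, statistics), not real-slide
  segmentation accuracy.
- The rule arm's default mask is ground truth; with a plugged detector
  its accuracy becomes that detector's problem.
- Rigid-only registration: 3 µm serial sections justify small rigid
  offsets; per-cell jitter is absorbed by the IoU score. Deformable
  registration is out of scope.
- Observer parameters (noise SD, flip probability, field size) are
  plausible, not fitted to any real observer.
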