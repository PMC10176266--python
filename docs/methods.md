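# Methods

## Scope and model of the data

`trophoquant` implements the quantitative layer of a single-cell
immunofluorescence experiment on differentiating human trophoblast stem
cells (hTSCs): multichannel fields (DAPI nuclei in blue, two marker stains
in green/red, optionally a membrane stain) acquired per condition and
replicate, backed by matched isotype-control fields that define the
nonspecific-signal baseline. The pipeline detects cells from the DAPI
channel, assigns each cell a per-channel marker intensity, normalizes by the
isotype baseline, and feeds the per-cell table into spatial classification,
quartile stratification, fusion-index scoring and hypothesis tests. A
companion ΔΔCT module covers the qPCR side of such experiments.

Coordinates are `(row, col)`, 0-based, pixel centers at integer positions;
physical distances use `um_per_px`. Intensities are floats on a [0, 255]
scale mirroring 8-bit exports; quantization is optional and off by default
so recovery tests can assert exact equality.

## Nucleus detection

The DAPI channel is binarized (Otsu by default; a fixed global threshold is
available), the mask is cleaned (hole filling; components below
`min_area_px` removed — default 30 px, about a 3.4 μm-radius nucleus at the
default 0.62 μm/px), and 8-connected components become nuclei, labeled in
raster-scan order with pixel-mean centroids. An optional distance-transform
watershed splits touching nuclei: seeds are distance-transform maxima at
least `watershed_min_distance` px apart (deterministic (row, col) ordering),
and pixels 8-adjacent to a different watershed region are erased so split
nuclei remain separate components — a one-pixel watershed line alone leaks
diagonally under 8-connectivity.

The binarization method, area floor and watershed settings are explicit
configuration recorded in the run manifest. Source material for pipelines of
this kind often calibrates these steps by eye on a few images with known
counts; here the calibration is replaced by explicit parameters whose
defaults are validated on synthetic fields, trading fidelity to an
undocumented manual step for reproducibility.

## Per-cell marker assignment

Two modes, selectable per channel:

**nearest-stain** — the stain channel is binarized and cleaned with the same
operator family as DAPI; the cell receives the mean *original* intensity of
the connected stain component containing the stain pixel nearest its nucleus
centroid (the whole component, matching "average intensity of the stain",
not the single pixel). If no stain pixels exist, or the nearest stain pixel
is farther than the nearest DAPI pixel of a *different* nucleus, the signal
plausibly is not the cell's own and the cell instead receives the
isotype-control reference (fallback). Distances are centroid-to-nearest-mask-
pixel, Euclidean, in pixels; ties (`d_stain == d_other`) keep the stain.
Reading "nearest blue stain" as *any* blue pixel would make a cell's own
nucleus (distance ≈ 0) trigger fallback always; the neighbor-nucleus reading
makes the rule a stain-ownership test and is the default
(`fallback_rule="other_nucleus"`), with the literal `"any_blue"` reading
retained for sensitivity analysis.

**nuclear** — the cell receives the mean of the channel's original values
over its own nucleus pixels; used for nuclear factors (HIF1α/HIF2α), where
only DAPI-overlapping pixels are informative. Distance fallback does not
apply.

Stain channels default to a *fixed global threshold* in the shipped run
configuration rather than Otsu: with a dim and a bright marker population
over a dominant dark background (the two-population structure the EVT
heterogeneity produces), Otsu maximizes between-class variance by merging
the dim population into background. The default threshold 25 sits between
the synthetic background level (8) and the dimmest population mean (50); on
real data it is a parameter to set from the isotype images.

**Isotype reference** — per-cell raw values from 1–3 isotype fields,
processed in the same mode as the experimental fields, are pooled across
fields (weighted by cell count; a per-field-mean option exists) and
averaged. During isotype processing in nearest-stain mode no reference
exists yet, so a fallback there uses the field's mean channel intensity —
the nonspecific background the isotype image exists to measure. Normalized
intensity is raw / reference, so fallback cells normalize to exactly 1.0,
and quantifying an isotype field against its own reference gives mean
normalized intensity 1.0 exactly at zero noise. Channels are quantified
independently; a cell may fall back in red but not green.

## Spatial classes, quartiles, fusion index

A cell is a **single cell** if no other cell's centroid lies within the
neighbor radius (default 50 μm, boundary inclusive), else a **colony** cell;
fields are classified independently. **Quartile stratification** first
excludes cells negative for *both* markers (negativity = fallback-assigned,
equivalently normalized ≤ 1.0; an explicit threshold rule is available),
then sorts the remaining n cells by the primary marker with ties broken by
cell identity, and extracts bottom and top groups of exactly floor(n/4)
cells each — equal-sized by construction, matching the equal group sizes
such stratifications report. The **fusion index** is (N − S)/T (N nuclei
inside syncytia, S syncytia, T total nuclei); manually counted (N, S, T)
tables are the reference input path, and an auxiliary automated path
partitions a membrane-stained image into closed regions (membrane pixels
above threshold as boundaries, 4-connected complement components as
regions), assigns nuclei to the region containing their centroid (nearest
region if the centroid falls on a boundary pixel), and calls regions with
≥ 2 nuclei syncytia. Fusion-index summaries report mean ± SD across
measurements; qPCR summaries report SE, each following the convention of
the corresponding assay.

## Statistics

Per-cell normalized intensities are not normal, so group comparisons use the
**Mann-Whitney U test** in its large-sample normal approximation: U from
midranks, z = (U − n₁n₂/2)/σ_U with the standard tie-corrected variance
(ties are frequent: fallback cells share the value 1.0 exactly), two-sided
p from the standard normal, no continuity correction by default (a flag
enables it). An exact enumeration oracle (all C(n₁+n₂, n₁) labelings,
n₁+n₂ ≤ 20) bounds the approximation error: at n₁ = n₂ = 8 the worst-case
absolute p-error across all U values is 0.0465 without continuity
correction and 0.0109 with it, concentrated where exact p > 0.1; at the
n ≈ 250–7000 per group typical of per-cell comparisons the approximation
error is negligible, and the null rejection rate at 0.05 with n = 500 per
group is calibrated to within [0.04, 0.06] over 10⁴ simulations.

All other comparisons use a **two-tailed t-test gated by a two-sample
F-test** for equality of variances at α = 0.05: Welch if the F-test rejects,
pooled Student otherwise; the decision is recorded. **ΔΔCT**: per sample,
ΔCt(gene) = Ct(gene) − geometric mean of the housekeeping Cts (GAPDH and
ACTB by default; the geometric mean is taken over the Ct values themselves,
a literal reading of the stated normalization), ΔΔCt is referenced to the
day-0 condition, log2 fold change = −ΔΔCt, SE across replicates, and the
p-value compares per-replicate ΔCt against the reference with the gated
t-test (ΔCt-level testing, standard practice where the level is unstated).
Raw p-values are reported with ns/*/**/*** markers at 0.05/0.005/0.0005; no
multiple-testing correction by default (optional Benjamini-Hochberg).

Note on a geometric-mean subtlety: adding a constant c to one housekeeping
gene's Cts shifts every ΔCt by −c/2 only to first order under the geometric
mean (exactly under an arithmetic mean); ΔΔCt is exactly invariant either
way when the shift is uniform across conditions, because it cancels in the
difference.

## Synthetic data generator

The generator renders fields with complete ground truth so every stage is
testable without microscopy data: nuclei as non-overlapping disks (radius
6–9 px) of DAPI intensity 200, laid out as colonies (members within half the
50 μm neighbor radius of their colony center, guaranteeing mutual
neighbors) and isolated single cells (no centroid within the radius);
per-cell stain disks whose intensity is drawn from per-population models —
the default is two anti-correlated populations (HLA-G-high/Notch1-low at
green 200/red 50, and the mirror) emulating mature single-cell EVTs vs.
column-stage colony EVTs; background 8 filling unsignaled pixels; optional
Gaussian noise, clipped to [0, 255]. A `stain_offset_px` option displaces
blobs from their nuclei to deliberately trigger the fallback rule, and a
`touching_pairs` option places nucleus pairs at 1.5× radius spacing to
exercise watershed splitting. Isotype fields render nuclei identically with
stain channels at pure background. Membrane fields realize a target fusion
index f with T nuclei as one syncytial region of k + 1 nuclei, k =
round(f·T) (within 1/T of any reachable target), plus singleton regions, on
a rectangular membrane grid. Ct tables encode true log2 fold changes as Ct
shifts against constant housekeeping genes, so the ΔΔCT pipeline recovers
the truth exactly at zero noise.

Field geometry defaults (512×512 px, 0.62 μm/px, 8-bit scale) are declared
assumptions standing in for unreported acquisition parameters. What the
generator deliberately does *not* emulate: optics (PSF blur, chromatic
aberration, channel bleed-through), uneven illumination, 3-D structure,
irregular nucleus shapes, mitotic figures, or segmentation-hostile density.
Passing tests therefore certify the *computational* contracts — counting,
assignment, normalization, stratification, scoring, inference — not
segmentation robustness on real confocal images.

## Problem sizes used in the shipped checks

Counting is verified at k ∈ {1, 5, 50, 200} nuclei (noise-free, then noise
SD 5); nearest-stain assignment against the pixel-scan oracle on 1000 random
48×48 scenes; spatial classification against the O(n²) brute force at 500
cells; quartile sizes across random n ∈ [4, 5000]; Mann-Whitney against full
enumeration at n₁ = n₂ = 8 (500 instances) and under the null at n = 500 per
group (10⁴ simulations); the gated t-test under an equal-variance null
(n = 10, 10⁴ seeds) and a variance-ratio-25 alternative (n = 50, 10³ seeds);
ΔΔCT at 3 replicates over 10³ noise seeds. These sizes were chosen to make
the Monte-Carlo bands (rejection rates within ±0.01 of 0.05, log2FC bias
within 0.05) tight enough to detect calibration errors.

## Known limitations

- Segmentation defaults are tuned on synthetic disks; real confocal images
  need per-dataset thresholds and min-area settings (the manifest records
  them for reproducibility).
- The automated membrane-region path assumes closed membrane boundaries;
  broken membranes merge regions and inflate N. Manual counts remain the
  reference path.
- The nearest-stain rule assigns whole-component means; overlapping cells
  whose stains merge into one component share a value.
- No cytoplasm/membrane compartment segmentation, spectral unmixing, or
  per-pixel colocalization; no hierarchical modeling of replicates.
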