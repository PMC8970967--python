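# Methods

`lymphoquant` quantifies the assays used to study chemotherapy-driven
lymphatic remodeling: lymphatic vessel density (LVD) in IHC sections,
endothelial monolayer integrity and marker positivity in fluorescence
fields, explant sprouting, nodal/pulmonary metastatic burden, an RPPA
ratio-outlier screen, cytometry gating, and a dispatched statistics layer.
Because the original measurements were made on animal and patient material
(and interactively, in ImageJ or a bespoke MATLAB tool), every stage here is
validated against a synthetic-data module that renders the same kinds of
inputs with exact ground truth. This note records the models, the
parameters that matter, and the design choices that were genuinely open.

## Stain model and vessel morphometry

Brightfield rendering and analysis share one color model: Beer–Lambert
optical-density (OD) mixing over the standard Ruifrok
hematoxylin/eosin/DAB basis (`skimage.color.rgb_from_hed`). The synthetic
IHC generator composes a hematoxylin-like stroma (base concentration 0.35
with smooth spatial texture) with DAB-like vessel walls (concentration 0.9)
and Gaussian pixel noise (default sd 0.03); deconvolution inverts the same
basis and thresholds the DAB channel.

The vessel pipeline mirrors the classic binarize → flood-fill → extract
workflow:

- **Threshold.** Otsu on the DAB OD channel, clamped to a minimum OD
  (default 0.1). The clamp matters on sparse fields: with two vessels in
  1 mm² the chromogen histogram is nearly unimodal and unclamped Otsu
  splits background noise. A fixed threshold can be supplied instead; the
  applied value is always logged.
- **Flood fill.** Enclosed background components (lumens) are filled before
  labeling, so vessel area is lumen-inclusive — the natural reading of
  "filling the vessel area" for an annular cross-section.
- **Morphometry.** Area and centroid are pixel statistics in physical
  units; perimeter uses the 4-direction Crofton estimator (plain pixel-edge
  counting overestimates circular perimeters by ~27%, Crofton is within
  ~1% for radii ≥ 10 px). Components below `min_area_um2` (default
  50 µm²) are discarded as debris.
- **Manual ROIs.** User-drawn polygons (GeoJSON, µm coordinates) become
  manual records; an automatic record is replaced when it overlaps an ROI
  with IoU ≥ 0.5, otherwise the ROI is appended.
- **LVD.** Vessels per mm² of stroma. The stroma mask is total OD above a
  small floor with enclosed holes filled (a vessel whose centroid sits in
  its own lumen must not be excluded from the tissue compartment), minus
  optional exclusion polygons for non-stromal compartments. Vessels whose
  centroids fall outside the stroma are excluded and counted.

Synthetic vessels are annuli or mildly eccentric ellipses rather than
realistic contours: analytic areas (πab) and Ramanujan perimeters then
serve as oracles, which is the point of the shapes.

## Monolayer fields

**Tessellation model.** Cell territories are a jittered-grid Voronoi
tessellation (default 400 cells in a 512 µm field, ≈ 650 µm² per cell);
the junction channel marks territory boundaries, nuclei are 3 px disks at
territory seeds.

**Gaps.** A junctional gap is planted by deleting a contiguous cluster of
whole territories (default ~6 cells, ≈ 4,000 µm²) and redrawing the
junction network around the hole, so each gap is an enclosed junction-free
region much larger than any single cell interior. Border-touching cells
are never removed (a border gap would fall partly outside the junction
hull and is not a well-posed "hole"), and near the requested fraction the
cluster shrinks to the remaining deficit, so the realized fraction lands
within ~0.3 points of the request. Analysis mirrors the model: gaps are
background components inside the closed hull of junction signal with area
≥ `min_gap_area_um2` (default 2,000 µm², i.e. about three cell
interiors); the gap fraction is gap pixels over field pixels. A cell is
non-cohesive when its territory (nearest-nucleus partition) borders a
detected gap.

**Positivity.** The positive-cell count in the generator is a deterministic
assignment, `round(f_positive · n)`, not a binomial draw, so recovery error
measures segmentation, not sampling. Nuclei are segmented by Otsu plus a
distance-transform watershed with 5 µm minimum seed separation. A cell is
positive when ≥ 50% of its nuclear pixels carry marker signal above
threshold; the `nucleus_plus_perinuclear` rule additionally requires the
same coverage over a 3 µm perinuclear ring — an operational stand-in for
"signal in both the nucleus and mitochondria" that makes off-target signal
score exactly zero. Live/dead and Ki67 percentages are the same operation
with the respective marker channel.

**Hotspots.** No published definition of a "hotspot region" exists, so one
is fixed here: 200 µm square windows sliding at a quarter-window stride,
ranked by positive-cell density; the top 10% of windows (those containing
at least one positive) form the hotspot, and the reported percent is
positives over cells in the hotspot union. Under spatial uniformity the
hotspot percent is mildly upward-biased (order selection bias, a few
points at 500 cells/field), which is intrinsic to any maximum-based window
statistic.

**Invasion.** Percent invasion is counted cells extrapolated by the imaged
fraction of membrane area, over cells seeded; the area fraction is an
explicit parameter because the counting protocol images only a few fields
per membrane. Fields average into a well value and wells into one
biological value, each over non-missing entries.

## Sprouts, metastatic burden

A sprout is a skeleton side-branch: the vessel mask is skeletonized, the
trunk is the longest geodesic path between endpoints, and a branch counts
when its geodesic length to the trunk is ≥ `min_sprout_len_um` (default
20 µm) and its mean local width (twice the distance transform along the
branch) is ≤ `max_sprout_width_um`. Skeleton spurs below 2 px are ignored
as discretization artifacts. Density is sprouts per mm² of filled vessel
area.

Metastatic burden is thresholded tumor signal (Otsu within the tissue mask,
clamped to a floor of 0.25 so a signal-free node reads 0%) as a percent of
tissue area. Lesion counting is a connected-component stand-in for by-eye
macroscopic counting — touching components are one lesion, components
below 0.01 mm² are ignored — and is flagged as automated in the output
metadata.

## RPPA screen and fold-change lists

Ratios are treated/control per protein on the linear scale; the
distribution is assessed once (mean and sample SD over all ratios, no
iterative trimming) and a protein is an outlier when its ratio is strictly
more than `k_sd` (default 2) SDs from the mean — a ratio at exactly
mean + 2 SD is not flagged. Flags and z-scores are invariant to global
intensity rescaling by construction.

The synthetic ratio generator draws bulk noise from a truncated normal
(|z| ≤ 1.2) rather than an unbounded one: the screen's rule flags
everything beyond 2 SD, so a generator claiming exact planted truth must
keep the null distribution's support strictly inside the flagging region.
With unbounded noise ~2.3% of null proteins would cross 2 SD per panel and
"exact recovery" would be undefined. Passing tests therefore show the rule
is implemented correctly, not that real RPPA panels are free of borderline
proteins.

Fold-change filtering applies the cut values verbatim to the table's
declared scale (defaults up > 1.25, down < 0.75; the miRNA variant uses
up > 2) and records the cuts in the output.

## Cytometry gating

Sequential gates in fixed order: live (viability dye below threshold —
the dye marks dead cells), then CD45−, then CD31 × gp38 quadrants on the
live CD45− parent: LEC (CD31+gp38+), BEC (CD31+gp38−), FRC (CD31−gp38+),
DN (CD31−gp38−). Values exactly at a threshold are marker-positive.
Quadrant counts partition the parent exactly, and because the gates are
intersections the final LEC count is order-independent. Thresholds come
from config; missing ones fall back to the deepest KDE valley between the
two main modes of the channel. The synthetic event generator draws
per-population channel values from well-separated normals (negative mode
≈ 1, positive mode ≈ 3 on arbitrary log-like units, thresholds at 2), so
recovery tests measure gating logic rather than classifier power;
compensation and spillover are out of scope.

## Statistics

Two-group comparisons are dispatched: Shapiro–Wilk per group (a
reproducible surrogate for visual QQ inspection); if both groups pass, a
two-sided F test on the variances chooses Student's vs Welch's unpaired t
test; otherwise the Mann-Whitney U test. The full trace (normality p per
group, variance p, levels) is returned with every comparison.

The normality pre-test runs at α = 0.01 while the comparison and variance
test stay at α = 0.05. At 0.05 per group, roughly one in ten genuinely
normal comparisons would fail the pre-test purely by chance and be routed
to the rank test — and those misrouted samples are selected for being
atypical, which measurably inflates the realized type-I error of the
parametric branches. At 0.01 the misrouting rate drops to ~2% while power
against clearly skewed data (e.g. lognormal with unit log-sd) remains
essentially 1. `normality_alpha` is exposed for users who want the looser
behaviour.

Multi-group comparisons are one-way ANOVA (or a balanced two-way factorial
with interaction; unbalanced designs are rejected with an explicit error
rather than silently refit) followed by Tukey's multiple-comparison test.
Summaries are mean ± SEM (sample SD/√n) with fold change against a named
control; a zero control mean flags the fold change as undefined instead of
dividing.

## Problem sizes and what passing shows

Validation runs use 512 µm fields (500 µm for LVD at 2 µm/px), 400-cell
monolayers, 500-nucleus positivity fields, 200-protein RPPA panels,
50,000-event cytometry tables, and 1,000-replicate null calibrations —
sizes at which every recovery band (LVD ±10%, gap ±1 point, positivity
±2 points, LEC ±0.5 points, type-I 0.05 ± 0.02) is checked in seconds per
stage. The generators emulate geometry, staining physics at the
Beer–Lambert level, and channel separation; they do not emulate scanner
artifacts, uneven illumination, stain batch variation, touching vessels,
or dim/ambiguous populations. Passing tests therefore demonstrate that the
quantification rules are implemented exactly and are stable under the
stated noise, not that the pipeline is robust to every pathology of real
slides.

Determinism is by construction: all randomness flows from one integer seed
through a named substream per generator (seed + operation tag), CSV output
uses a fixed float format, and identical (seed, config) reproduce
byte-identical artifacts.
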