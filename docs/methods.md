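# Methods

## The proximal-pressure statistic

Proximal pressure asks, for each cancer cell, "how strongly is this marker
expressed in my immediate surroundings?" and answers with a high quantile
rather than a mean, so a single strongly positive neighbor registers even
when most neighbors are negative.

Given a segmented sample with centroids (x, y) and marker intensities, the
computation is:

1. **Cancer labels.** Either planted ground truth (synthetic data) or the
   epithelial gate (below).
2. **Cell diameter d̂.** Median over cancer cells of the area-equivalent
   diameter 2·√(area/π). When areas are unavailable, the median
   nearest-neighbor distance among cancer cells is the fallback; on a
   dense regular packing both coincide up to a constant near one. A sample
   with a single cancer cell and no areas is unusable and is reported as
   such rather than guessed at.
3. **Neighborhood.** All cells of any class within centroid distance
   r = k·d̂ of the cancer cell, the cell itself excluded, the boundary
   distance r included. Other cancer cells are deliberately *included*:
   the statistic measures marker context, not immune context alone. The
   radius multiplier k is an explicit parameter because the two natural
   phrasings of a "one-cell-diameter surrounding" differ — a ring of one
   diameter around a cell of diameter d̂ reaches centroids out to 2·d̂ —
   and the default k = 2 takes the wider reading; k = 1 gives the literal
   narrower one.
4. **Pressure.** The 90th percentile, with numpy's linear interpolation
   between order statistics, of the marker's values over the neighborhood.
   The convention matters only at small neighborhood sizes (ten neighbors
   valued 1…10 give 9.1, where nearest-rank would give 10); it is fixed
   and documented for reproducibility. Empty neighborhoods yield missing
   values and are counted, never imputed as zero.
5. **Summaries.** Per sample and marker, the median over non-missing
   per-cell pressures; across samples, z-scores with the population (n)
   denominator so that the scores have exactly mean 0 and variance 1.
   z-scoring is across sample summaries; collapsing multiple cores per
   patient first is the caller's choice (pass per-patient tables).
6. **Comparison.** Two-sided Wilcoxon rank-sum (Mann-Whitney U) on the
   per-sample summaries between groups, per marker; Benjamini–Hochberg
   FDR across markers; direction = sign(resistant median − sensitive
   median). A marker with fewer than two usable summaries in a group is
   reported untestable instead of dropped.

Marker intensities are normalized per sample and marker (log1p, then
center/scale to unit population variance) before pressure computation.
This is a stand-in for normalization against internal control tissues,
which requires the control tissues themselves; it preserves the within-
sample rank structure that the percentile statistic consumes. Mode "raw"
passes pre-normalized intensities through untouched.

## Epithelial gating

The positivity threshold per sample and epithelial marker (E-cadherin,
pan-CK) is the equal-posterior point of a two-component Gaussian mixture
on log intensities, components seeded at the 25th/75th percentiles. Zeros
are handled by a data-relative offset (half the smallest positive value),
which keeps the whole gate covariant under a global positive rescaling of
a channel — thresholds scale, labels do not change. Ties at the threshold
are called non-cancer, a conservative choice for the pressure denominator.
A collapsed fit (components closer than 1e-6 of the log range, or a
component weight under 1e-3) falls back to the 75th-percentile threshold
and is flagged. "any" (default, matching an and/or marker definition) and
"all" policies combine multiple markers.

## Response classification and scores

Response labels partition [0, 100]: Ki67 ≤ 2.7 sensitive, ≥ 7.4 resistant
(both boundaries inclusive, per the printed ≤/≥), strictly between
intermediate. The Ki67 labeling index is ln(AQUA + 0.01); the 0.01 offset
accommodates AQUA scores of zero and makes the index exactly invertible.
Signature scores default to the geometric mean with pseudocount 0.01 over
{GZMA, PRF1} for cytolytic activity; the gene set and method ("geomean",
"meanz") are configurable because activation-gene panels vary between
studies and are not standardized.

## Segment normalization (LOQ / Q3)

"Geometric mean plus 2 SDs of the negative probes" is ambiguous between
an arithmetic SD added to a geometric mean and two *geometric* SDs. Both
are implemented; the default geometric mode, geoMean × geoSD², is the
platform-standard convention. SDs use the population (n) denominator in
both modes — the geometric worked example (probes {1, 100} ⇒ LOQ 1000)
pins this down. Zero counts receive a 0.5 pseudocount before logs; a
segment whose probes are all zero is unquantifiable and flagged. Gene
filtering retains a gene expressed above LOQ in ≥ 10% of quantifiable
segments by default (the fraction is a package choice; no canonical value
exists). Q3 normalization divides each segment by its 75th-percentile
count over retained genes, scaled so the cohort target is the geometric
mean of those percentiles. Because the target itself is a geometric mean
over segments, rescaling one segment by k rescales the whole normalized
matrix by the common factor k^(1/m); normalized values are therefore
invariant up to that single global scalar, and exactly idempotent.

## The synthetic-tissue generator

The generator emulates the features the analysis depends on and nothing
else:

- **Geometry.** A 600 × 600 unit field (a tissue-microarray-core scale,
  units micrometre-like); 300 cancer cells in 6 Gaussian nests of spread
  40 (a Thomas cluster process, nest centers uniform); coincident
  centroids permitted, as after segmentation rounding.
- **Immune attraction.** Each population mixes uniform placement with an
  attracted component: an attracted cell sits at an isotropic
  exponentially distributed displacement (scale = one nominal cell
  diameter, ≈ 10.1 units from the mean area of 80) from a uniformly
  chosen cancer cell, so placement density decays with distance to the
  nearest cancer cell. The mixing weight is λ/(1 + λ) — zero at λ = 0
  (complete spatial randomness, verified against uniform placement by
  rank tests), saturating as λ grows. Defaults: CD8 λ=2, CD4 1.5, CD20
  0.5, CD68 1, FOXP3 1, sizes 80/80/50/60/30.
- **Planted group difference.** "Resistant" samples multiply λ per class
  by `group_effect` (default CD8 × 5), which increases CD8 proximal
  pressure monotonically in λ and is the ground truth that the
  pressure–comparison chain must recover.
- **Intensities.** Lognormal; defining marker of a class (epithelial
  markers for cancer, CD45 for all immune cells, the class marker per
  population) at log-mean 3, background at 0, log-SD 0.5 — a 6-SD
  separation, comfortably above the 3-SD level at which gating is
  expected to recover classes at ≥ 95% accuracy.
- **Clinical values.** Ki67 drawn uniformly from [0.5, 2.7] (sensitive)
  and [7.4, 25] (resistant): every synthetic sample falls unambiguously
  inside a classification band.
- **Counts.** Expressed genes lognormal(5, 0.6), negative probes
  lognormal(0.5, 0.3), unexpressed genes lognormal(−0.5, 0.3) — below the
  probe background, as unexpressed targets are relative to probes designed
  to capture background; per-segment lognormal scale factors (SD 0.4 on
  the log scale) make raw Q3 differ across segments.

What the generator does **not** emulate: pixel-level images, segmentation
error, autofluorescence, staining-round registration artifacts, spatial
marker gradients within a class, cell-shape anisotropy, or patient-level
heterogeneity beyond the group multiplier. Passing tests on synthetic
cohorts therefore demonstrate that the statistics recover a planted signal
of the stated geometry, not that they are robust to every real-data
artifact.

All randomness flows from one root seed: each sample's stream is a
`SeedSequence(seed, spawn_key=(offset,))` child, clinical values use a
reserved offset, and identical configurations are bit-identical across
runs (the pipeline writes no timestamps for the same reason).

## Statistical kernels

The rank-sum test uses exact enumeration when the smaller group has ≤ 10
observations and there are no ties, and the mid-rank normal approximation
with continuity correction otherwise; the continuity-corrected
approximation is within 0.011 of the exact p in the worst case at 8 vs 8
(the worst attainable deviation over all U values; no two-sided
convention does better). Samples with all values identical carry no
ordering information and return p = 1, flagged. BH adjustment preserves
input order and commutes with permutations. AUC is computed from
mid-ranks (the Mann-Whitney formulation, ties counted half), with the
ROC curve itself from the standard threshold sweep.

## Problem sizes

Replicate-cohort checks use 20 samples per group of ~600 cells each
(100 cohorts for detection power, 200 for null calibration), and the
exhaustive-reference comparison uses 20 random tables of up to 2,000
cells; these sizes give binomial noise on a 5% rate of well under two
percentage points while keeping a full verification run to a few minutes
on one CPU.

## Known limitations

- Gating assumes an (approximately) bimodal log-intensity distribution;
  on unimodal channels the mixture still splits the data and the
  75th-percentile fallback only triggers on truly degenerate fits.
- The attraction kernel is a displacement from *one* cancer cell; the
  induced density decays with distance to the nearest cancer cell but is
  not an exact nearest-distance Gibbs model.
- Q3 normalization presumes the 75th percentile sits above the
  expression floor in every retained segment; segments failing that are
  flagged and excluded from the target rather than rescued.
- The LOQ filtering fraction (0.1) and mixture-gate fallbacks are
  package defaults, not values with an external standard.
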