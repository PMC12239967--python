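# Methods

This note documents the models and procedures implemented in `nichemap`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data experiments do and do not demonstrate.

## Coordinate and unit conventions

All coordinates are FOV-local micrometres, origin at the field of view's
lower-left corner, y increasing upward. Label rasters are indexed
`image[row, col]` with pixel `[i, j]` covering `y ∈ [i·s, (i+1)·s)`,
`x ∈ [j·s, (j+1)·s)` at pixel size `s` (default 0.18 μm/px). One scalar
pixel size converts between raster and physical coordinates everywhere;
all statistics are computed in μm. Geometry is strictly 2-D.

## Cell distance geometry

Cell-to-cell distance is the minimum Euclidean distance between boundary
polygons (edge-to-edge), not between centroids: centroids misrepresent
irregular cells and impose a spurious ranking on equidistant touching
neighbors. Conventions:

- Touching, overlapping or nested polygons are at distance 0. Overlap can
  arise from imperfect segmentation; a negative or undefined distance would
  poison downstream statistics.
- Ring neighborhoods around each leukemia cell are half-open,
  lower-inclusive bands `[e_i, e_{i+1})` over the edges
  0, 5, 15, 25, 35, 45 μm; a cell at exactly 45 μm is outside the last
  ring. The same neighbor may sit in rings of several leukemia cells;
  overlapping neighborhoods are deliberately left uncorrected.
- The distance table keeps only pairs within a cutoff (default 45 μm). An
  STRtree prunes candidates; the result is defined to equal the all-pairs
  scan, and a pure-numpy segment-pair oracle (endpoint-to-segment distances
  plus an orientation-based intersection test) verifies that equality on
  random tissues to 1e-9 μm.

## Mask fusion and segmentation evaluation

Nucleus and membrane channels are segmented separately upstream; fusion
builds one mask per cell:

1. A nucleus pairs with the membrane object containing the largest
   fraction of its pixels if that fraction is ≥ `pair_overlap_min`
   (default 0.5); ties break by larger absolute overlap, then smaller
   membrane label. A membrane claimed by several nuclei keeps the
   largest-overlap nucleus.
2. Unpaired nuclei are expanded isotropically by `expansion_radius`
   (default 3 μm) with a distance-transform tie-break where expansions
   collide, and never onto membrane-derived cells. Restricting expansion
   to cells without a detected membrane avoids the systematic
   over-expansion that captures transcripts from outside the cell.
3. Orphan membranes are kept as cells (configurable); fused objects below
   `min_cell_area` (10 μm²) are dropped.

Evaluation matches predicted to truth objects greedily by descending IOU,
one-to-one; matched pairs with IOU ≥ 0.7 are true positives and
`F1 = TP / (TP + (FP + FN)/2)`. Greedy matching (rather than optimal
assignment) is the common instance-segmentation convention and is
deterministic; with the one-to-one constraint and a 0.7 threshold the two
rarely differ. The pairing threshold, expansion radius and matching rule
are this package's choices; only the F1 formula and IOU threshold are
fixed by the analysis being reproduced.

## Cell typing

Typing runs within each sample, after cells prelabeled from imaging
(leukemia, RBC) are removed:

- **QC.** Cells with fewer than 20 assigned transcripts are dropped, then
  FOVs left with fewer than 300 cells are dropped whole.
- **Reference cells.** A cell is a reference for a type when that type is
  the only one with positive mean marker expression. "Positive" defaults
  to *above the cell's own average per-panel-gene count* rather than
  simply nonzero: at high depth almost every gene carries a stray count,
  so an absolute zero threshold would disqualify every cell, while a
  depth-relative threshold keeps the rule meaningful from tens to
  thousands of transcripts per cell. An absolute threshold remains
  available.
- **Profiles.** Per-type mean expression over reference cells, over all
  panel genes. The mean negative-control probe count `b` estimates
  nonspecific background.
- **Assignment.** Counts are modeled as independent Poisson with rates
  `total_c · (profile_{g,t} + b) / Σ_g (profile_{g,t} + b)`; the additive
  background is the simplest standard form of probe-background adjustment
  (the exact adjustment in the original tooling is not specified).
  Posteriors use a uniform prior over types; assignment is the argmax.
  Because each type's rates sum to the cell total, assignment is invariant
  to jointly rescaling profiles and background.
- **Second round.** Cells assigned to a lymphocyte class are re-scored
  against subtype profiles built from their own reference cells; the broad
  class never changes, only the subtype.
- **Size validation.** The fraction of very large cells (> 648 μm²)
  assigned to megakaryocytes — the giant cells of the marrow — serves as
  an orthogonal, imaging-based check on the annotation.

## Ring-composition mixed model

For each focal type, the count of focal-type cells in ring `r` of leukemia
cell `l` in FOV `f` is modeled as

    count ~ Poisson(total · exp(x' β + u_f)),    u_f ~ N(0, σ²)

with `log(total)` as offset (the model describes the focal type's *share*
of the neighborhood), a full factorial response × timepoint × ring fixed
structure, and a FOV random intercept. Records sharing a FOV and covariate
cell are collapsed by summing counts and totals before fitting — exact
under the model, and it makes each fit take milliseconds.

Estimation is maximum likelihood with a Laplace approximation: penalized
IRLS finds the joint (β, u) mode at fixed σ, and a bounded 1-D search
maximizes the Laplace marginal likelihood over log σ (the nAGQ=1 scheme of
standard mixed-model software). Fixed-effect covariances come from the
penalized information matrix at the optimum, conditional on σ̂. An
`lme4::glmer` fit on the same records reproduces the per-condition linear
predictors to ~1e-2 in the test suite. A fixed-effect-per-FOV Poisson GLM
is also provided as a cross-check on within-FOV (ring) effects; it cannot
identify response or timepoint effects because FOVs are nested within
samples.

Contrasts (per ring: responders post-ICI vs baseline, nonresponders
post-ICI vs baseline, responders vs nonresponders at baseline) are Wald
tests on linear combinations of β — Wald rather than likelihood-ratio,
since the recalculated p-values are defined on the fitted model — with
Bonferroni adjustment over the family of all contrasts × all fitted
models.

The parameter-recovery experiment generates ring-count records directly
from this generative model (6 patients, 20 FOVs each split over two time
points, 15 leukemia cells per FOV, ring totals with Poisson means
2/6/10/14/18, FOV intercept SD 0.3, baseline focal share 0.10, planted
post-vs-baseline rate ratio 2.5 in responders — the magnitude reported for
the strongest monocyte effect in the source analysis). Coverage of the
95% CI and the type-I error of the Wald test at 0.05 are measured over
100 and 500 replicate cohorts respectively.

## Density-shift statistic

For target type T and one patient, minimum edge distances from every T
cell to the nearest leukemia cell are pooled over the FOVs of each time
point. The shift between time points A and B is the difference of
Gaussian-kernel density estimates on a common grid (512 points on
[0, 45 μm]); bandwidths follow Silverman's rule, matching the default
family of standard density routines. The permutation background draws,
per FOV, `J = 100` random same-size subsets of the non-leukemia (non-RBC)
cells; permutation `j`'s shift pairs the `j`-th background of A with the
`j`-th of B (the literal reading of the background-shift definition; the
alternative — independent pairing — mainly inflates the background SD).
A grid point is flagged when the observed shift lies strictly more than
one background SD from the background mean. This ±1 SD rule is a
deliberately liberal screen, not a 5% test, and no multiplicity
correction is applied across type pairs. For display the curve is divided
by the per-point background median, floored in magnitude at machine
epsilon.

The validation experiment plants enrichment by relabeling the cells
nearest to (or furthest from) leukemia as the target type at one time
point and requires a flagged positive shift in the corresponding distance
window; identical inputs give a shift of exactly zero.

## Proximity ligand-receptor test

Non-leukemia cells are split by edge distance to the nearest leukemia
cell into close (≤ 5 μm) and far (≥ 30 μm) groups; the band between is
excluded. Expression is pseudo-bulked: per FOV, the mean raw count of a
gene over a cell type's close (or far) cells; no per-cell normalization,
matching the mean-expression aggregation of the source analysis (a
median-aggregation and a depth-scaled mode exist behind flags).
Leukemia-high genes on the ligand (or receptor) side are those whose
leukemia median across FOVs exceeds the mean of the other cell types'
medians by more than two standard deviations of those medians — the
dispersion is computed over the other types' medians, the simplest
reading of "2 SD away from the other cell types". For each leukemia-high
gene, the complementary partner gene of every pair is tested per cell
type with a two-sided Mann-Whitney U across FOV replicates
(close-group means vs far-group means, requiring ≥3 FOVs with both groups
non-empty), in both orientations. Benjamini–Hochberg adjustment is
applied within each (orientation, sample) family; Bonferroni is reserved
for the mixed-model contrasts, where it is explicitly specified.

A caveat the experiments exposed: within one tissue, per-FOV mean
expressions of *different genes* share the same per-cell depth factors
and are nearly perfectly correlated, so p-values of many pairs from one
cohort carry far less evidence than their count suggests. The null
calibration study therefore fixes one tissue geometry (the grouping the
test conditions on) and redraws expression independently per replicate,
yielding exactly independent p-values for the uniformity check.

## Synthetic tissue generator

The generator emulates the structure the analyses rely on, with defaults
matching the emulated assay: 0.985 × 0.657 mm FOVs, ~4146 cells per FOV,
a 960-gene panel plus 19 negative-control probes, per-cell depth
log-normal with median 102 transcripts and log-SD 1.0 (matching the
reported median and interquartile spread), leukemia fraction 0.064, and a
marrow-like type mixture. Cells are a Voronoi tessellation of a uniform
point process with a 3 μm hard-core minimum separation between cell
centers (centers cannot coincide in real tissue, and the separation keeps
every Voronoi cell wide enough for the inter-polygon gap), clipped to the
FOV and shrunk by half a 0.4 μm gap so polygons are disjoint — polygonal, size-heterogeneous cells make the
edge-vs-centroid distinction material. Leukemia cells are placed first;
other types are sampled with placement weights multiplied by an
enrichment factor within a radius of the nearest leukemia cell (thinning
at placement time, so the mixed model's rate ratio has a generative
analogue). Counts are Poisson with per-type rate vectors (marker genes
elevated, including realistically shared markers); negative-control
probes have a flat per-cell background rate (0.05). An optional
ligand-receptor effect multiplies the receptor rate by a fold in receiver
cells within a radius of a leukemia cell. Mask pairs rasterize the
polygons (truth), erode each cell to ~40% area (nucleus), and drop cells
from the membrane raster with a given probability.

What the generator does **not** emulate: marrow histology (vessels,
trabeculae, spatially correlated density), segmentation errors other than
membrane dropout, transcript misassignment between adjacent cells,
cell-type-dependent depth, overdispersed (non-Poisson) counts, and
batch/sample effects beyond the FOV intercept. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not robustness to every artifact of real tissue.

## Experiment problem sizes

The validation studies use scaled-down tissues chosen so each study's
statistical target is well resolved: 110 × 70 μm / 50-cell FOVs for the
geometry oracle (100 tissues); 300 × 200 μm / 385-cell FOVs for the
density-shift validation (100 replicates per variant, J = 100);
250 × 160 μm / 400-cell FOVs with 3% leukemia for the ligand-receptor
studies (8 FOVs per power replicate; 24 FOVs and 500 expression redraws
for calibration — the 3% leukemia density keeps close and far groups of
comparable size, mirroring the full-scale geometry where both groups are
large); 1200 cells for the typing depth study. Cell density matches the
full-scale default (~156 μm²/cell) throughout.

## Numerical notes and degenerate inputs

- KDE of a degenerate (constant or single-point) sample falls back to a
  narrow Gaussian bump (SD 0.5 μm); samples with fewer than 5 distances
  mark the curve unreliable.
- The GLMM's variance search is bounded (log σ ∈ [−6, 2]), so a null
  variance component lands at the lower bound rather than a singularity;
  PIRLS linear predictors are clipped at ±30 before exponentiation.
- Cells with zero total counts are an error in `assign_types` (QC removes
  them upstream); types with no reference cells are dropped with a
  warning.
- WKT is written with shortest-round-trip float formatting so cell-table
  IO is bit-exact.
- Sub-pixel polygons rasterize to nothing and are skipped with a warning.
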