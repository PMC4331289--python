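# Methods

## The procedure

The classification unit is the census parcel: a polygon with a stable
administrative identity. Inputs are (a) a time-ordered series of
co-registered, radiometrically normalized four-band rasters (Blue
450–510 nm, Green 510–580 nm, Red 655–690 nm, NIR 780–920 nm, digital
numbers on a north-up grid), and (b) a parcel vector layer in the same
projection, with ground-truth land-use labels on a training subset.
Co-registration, orthorectification and radiometric normalization are
assumed done upstream and are out of scope; CRS tags are compared for
string equality only, never reprojected.

Per parcel and acquisition, the arithmetic mean of each band over the
parcel's pixels is extracted, plus three vegetation indices — NDVI =
(NIR−R)/(NIR+R), the stubble index Stu = R/G, and B/G. With n
acquisitions this yields 7n features per parcel (column names `T{k}{Var}`,
time-major). A CART tree is grown on the labeled parcels per grouping
level (Veg/NonVeg, cropping system, individual crop, related by a fixed
crop → system → Veg/NonVeg hierarchy), each terminal node is exported as
one SQL predicate rule, and the rules classify unlabeled parcels.
Accuracy is assessed by confusion matrix.

## Pixel membership

A pixel belongs to a parcel iff its center lies in the closed polygon
(boundary centers count as inside). This is the standard zonal-statistics
default: deterministic, unweighted, and unbiased for parcels much larger
than a pixel. No partial-pixel weighting is attempted. An optional
negative buffer (map units, default 0) shrinks parcels before the test to
exclude mixed boundary pixels. Parcels covering no pixel center at any
time are excluded from the matrix and reported.

Two modes exist for the indices: `per_pixel` (default) computes the index
per pixel and averages over the parcel, respecting the nonlinearity of
NDVI; `from_means` evaluates the formulas on the band means. At realistic
noise the difference (a Jensen gap) is far below the between-class
separation; both modes are tested. Ratios with zero denominators yield
NaN, and a parcel missing any feature at any time is dropped from the
matrix with a warning — the tree has no missing-value machinery.

## The CART model

Splitting is binary on a single variable: left child takes values ≤ the
threshold, thresholds are midpoints of consecutive distinct sorted
values. The split chosen maximizes the Gini improvement

    improvement = Gini(parent) − (n_L/n) Gini(L) − (n_R/n) Gini(R),
    Gini(t) = Σᵢ pᵢ(1−pᵢ).

Maximizing the improvement at a fixed parent is equivalent to maximizing
Σ_child Σᵢ cᵢ²/n_child over the children's integer class counts, so
candidate splits are compared by exact integer cross-multiplication:
floating-point round-off can never reorder candidates, and the documented
tie-breaks — earlier variable in column order, then smaller threshold —
are exact. A node becomes terminal when pure, smaller than `min_parent`,
at the depth limit, or when no admissible split (both children ≥
`min_child`) improves impurity by a strictly positive amount.

Parameters (absolute counts, not percentages):

| parameter    | default | meaning |
|--------------|---------|---------|
| `max_depth`  | 5       | splits allowed along a root-to-leaf path |
| `min_parent` | 8       | smallest node that may be split |
| `min_child`  | 4       | smallest child a split may create |
| `cv_folds`   | 10      | stratified cross-validation folds |
| `seed`       | 0       | drives fold assignment only |

"10%-fold cross validation" is read as plain 10-fold CV (the only
standard reading); folds are stratified by class with a seeded
generator, and the fold count is reduced with a warning when a class has
fewer members than folds. Class priors are the empirical frequencies, so
the prior-adjusted risk reduces to the plain misclassification
proportion; its standard error is binomial, √(r(1−r)/N). There is no
pruning, no surrogate splits and no misclassification costs. Variable
importance sums (node_size/root_size)·improvement over the primary splits
of each variable and is normalized so the top variable reads 100%;
commercial implementations fold surrogate splits into this statistic, so
published importance rankings are comparable only qualitatively.

### Equal class sizes and tree depth

One structural fact matters for synthetic studies: if all classes have
exactly equal counts, every class-pure partition of a node has *the same*
Gini improvement (for k equal classes any clean split improves impurity
by exactly 1/k of the node's cases, regardless of how many classes go
left). The deterministic tie-break then always takes the smallest
threshold on the earliest variable, and the greedy tree peels roughly one
class per level. A depth-5 tree therefore cannot separate 12 equally
sized classes even when the features could; real surveys, with unequal
class sizes, break these ties. For this reason the recovery studies and
the worked example set `max_depth` to the number of classes — a capacity
requirement that follows from the tie analysis, while the package default
stays at the conventional 5.

## Rule models

Each leaf becomes the conjunction of its path conditions, collapsed to
the tightest interval per variable, with the leaf's majority class and
within-leaf frequency as probability. The rules of one tree partition
the feature space, so rule application reproduces `predict` exactly —
class and probability — which is asserted, not assumed. The `.sqlmodel`
file format is one rule per line (`WHEN <conj> THEN '<CLASS>' PROB <p>`,
`WHERE` accepted on input), with a commented header carrying model name,
model level and the acquisition tags used in training; thresholds are
printed with 17 significant digits so write → parse is lossless. A JSON
sidecar duplicates the content for machine use. The original published
rule files are not available, so this dialect is a documented stand-in
designed for round-trip fidelity, not a reproduction. A model is
applicable only to extractions covering the times it was trained on; the
CLI refuses otherwise. No cross-level consistency is enforced between
Veg/system/crop outputs — they are reported side by side.

## Accuracy statistics

UA_c = 100·diag/row-total (observed rows), PA_c = 100·diag/column-total
(predicted columns), OA = 100·trace/total. **This row/column assignment
is the reverse of the common remote-sensing convention**; it is used
because every published table this package recomputes computes them this
way, and consistency with those tables takes precedence. Zero
denominators yield NaN. The shipped reference matrices
(`src/cropclass/data/*.tsv`) are re-entered from a published 311-parcel
accuracy assessment; two internal inconsistencies of the printed source
(one summer-crop row's predicted total, the off-diagonal placement of two
testing-phase rows) are annotated in the files and left unresolved —
they do not affect diagonals, row totals or OA. Comparisons against
printed values round half-up to the printed precision; the printed
80.7% overall accuracy of the individual-crop training table is a
truncation of the exact 126/156 = 80.769%.

## The synthetic generator

`cropclass.synth` emulates twelve classes spanning all grouping levels:
three winter crops, three summer crops, three adult orchards, one young
orchard, built-up and water. Noise-free NDVI trajectories are fixed
per-class module parameters validated against their declared patterns
(winter: ≥0.6 in early spring, ≤0.25 from mid-season; summer: ≤0.25
early, ≥0.6 peak near mid-season, ≤0.3 at the end; adult orchards: range
≤0.15; non-vegetation: ≤0.2 throughout). Band means derive from the NDVI
value and a per-class brightness (NIR+R total, DN): R = S(1−v)/2, NIR =
S(1+v)/2, G = R/(1.35−0.5v), B = G(0.9−0.3v). The three winter crops
intentionally share an identical stubble signature from early summer on —
post-harvest stubble is agronomically indistinguishable across winter
cereals/legumes — so single mid-season acquisitions genuinely confound
them, which is what makes the image-timing study meaningful.

Pixels are drawn independently as Normal(mean, 8·noise_scale DN), clipped
at zero, from one seeded generator; parcels are 12×12-pixel rectangles
(2 m pixels) on a gapped grid. The default study has 20 parcels per class
and 7 times, split 50/50 stratified by class (train size = ⌈fraction·N⌉
overall, largest-remainder allocation per class). What the generator does
**not** emulate: spatial noise autocorrelation, mixed boundary pixels,
clouds and atmospheric variation, within-class agronomic spread (sowing
dates), or georeferencing error. Passing recovery tests therefore show
the pipeline's correctness and the information content of clean
phenological signal — not expected accuracy on real imagery, which the
published assessment puts near 80% at the individual-crop level.

## Scenario study

`default_scenarios` builds the standard subset battery (full series, two
stride-2 triplets, two stride-3 pairs, all singletons — 12 scenarios for
7 times; shorter series keep what fits). Per scenario a tree is grown on
the restricted columns; per-class %correct is the resubstitution user's
accuracy on observed rows, and the risk is 10-fold cross-validated.
Resubstitution is used for the per-class cells (the published table's
usage is consistent with this); the CV risk column carries the honest
generalization signal.

## Problem sizes and runtimes

The default acceptance/recovery study is 240 parcels (12×20), 7 times,
144-pixel parcels — a deliberate desk-scale choice that keeps the full
suite under ten seconds while leaving every statistic well out of the
small-sample regime. Oracle checks run 200 random split instances
(n ≤ 30, ≤ 3 variables, integer-valued features to force exact ties) and
100 random trees for the rule-equivalence check.

## Known limitations

* GeoJSON is the only vector input format; rasters are GeoTIFFs with
  pixel-scale/tiepoint tags (no CRS WKT interpretation, tags compared as
  opaque strings).
* Only numeric, complete features: no categorical predictors, no
  missing-value surrogates.
* No pruning; depth and node-size limits are the only regularization.
* Importance from primary splits understates correlated variables
  relative to surrogate-aware implementations.
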