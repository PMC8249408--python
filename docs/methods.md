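# Methods

## Data model

A patient is a marked planar point pattern: cells with coordinates in μm,
a phenotype mark and a tissue-category mark, plus a region of interest
(ROI). The phenotype enum is `{B, T, T_CD8, T_helper, Treg, cancer,
other}`; `T` denotes CD3⁺ T cells when subtype resolution is unavailable,
and the three subtypes all count as CD3⁺ T cells wherever "T cells" are
pooled. A cell is a lymphocyte iff its phenotype is B or any T lineage.
Tissue category (`cancer_island` / `stroma`) is taken from the per-cell
mark assigned by upstream tissue segmentation, never recomputed from
geometry. The ROI area in mm² is the denominator of every density; when
neither an explicit area nor a boundary polygon is supplied, the bounding
box of the cells is used and flagged in the validation report — a
documented fallback, never silent.

## Occupancy and box-count fractal dimension

Grids are anchored at the minimum corner of the ROI bounding box; squares
are half-open `[x0+iL, x0+(i+1)L)`, and a cell exactly on the maximal edge
is clamped into the last square. The anchor choice is arbitrary in
principle; fixing it makes every statistic deterministic, and sharing it
across the L ladder makes dyadic grids nest (so n(2L) ≤ n(L) ≤ 4·n(2L),
bounding any two-point slope in [0, 2]). A square counts toward N(L) iff
it contains at least one cell of any type (squares without cells lie
outside the tissue and are omitted); it counts toward n(L) iff at least
one cell answers the binary question. Edge squares partly outside the ROI
polygon are retained if they contain cells — the omission rule is
cell-based, not geometry-based. For simulated reference processes there
is no tissue to delimit, so an option counts all squares tiling the
window as N(L).

The default L ladder is 13 geometrically spaced values
{10, 14, 20, 28, 40, 57, 80, 113, 160, 226, 320, 453, 600} μm; the
small-scale fit uses members ≤ 40 μm, the large-scale fit members
≥ 200 μm. The ladder is a package choice: the analysis is specified over
the 10–600 μm range with fit windows 10–40 and 200–600 μm, but the exact
evaluation points inside those ranges are free; geometric spacing weights
the log-log fit evenly.

The fractal dimension is the least-squares slope of ln n(L) versus
ln(1/L) (natural logs) over the scale window. Scales with n(L) = 0 are
dropped; fewer than three surviving scales is an error rather than a
silent degenerate fit. The slope uses **un-normalised** ln n(L): dividing
by N(L) shifts curves vertically for cross-image comparison but also
leaks the scale dependence of N(L) into the slope — a uniform Poisson
field then no longer yields the large-scale dimension ≈ 2 that the raw
definition gives. The normalised variant is available behind an option
for plotting and comparison use.

The occupancy AUC integrates occupancy against ln L by the trapezoid
rule, treating the 60-fold scale range scale-free (each octave weighted
equally); a linear-L abscissa is available as an option. Constant
occupancy 1 over [10, 600] μm gives ln 60 ≈ 4.094.

Δs = s_large − s_small is positive for dispersed arrangements and small
for nearly self-similar clustered ones. Positivity is an empirical
property of the pattern families the generator builds, not an enforced
invariant.

## Lymphocyte clusters

Clustering runs on lymphocytes only (B and all T lineages pooled) with
DBSCAN, eps = 20 μm and min_pts = 5 counting the centre cell. The
criterion "five lymphocytes within a circle of 40 μm diameter" is read
with eps as the circle **radius** of the neighbourhood: five contiguous
10 μm cells along a line then make the middle cell a core point,
reproducing the defining construction. Both parameters are configurable
because the diameter-versus-radius reading of the neighbourhood is
genuinely ambiguous. Border cells reachable from several clusters join
the cluster of the first core neighbour in stable input order (the
scikit-learn assignment rule), making results deterministic across runs
and platforms; a brute-force density-connectivity oracle in the test
suite pins the partition of core points and the noise set exactly.

LC types: pure_T (no B members), pure_B (no T-lineage members),
heterotypic (both). Pure-B LCs are detected and reported but excluded
from the size-distribution type index, which covers pure_T and
heterotypic only (pure-B LCs are rare and tiny in practice).

TLS detection runs a second density pass within each LC's members with
eps = 70 μm and min_pts = 200: the cluster is flagged iff some member has
at least 200 fellow members (itself included) within 70 μm. This
operationalises "≥ 200 lymphocytes in a 70 μm-radius circle" with circles
centred on cells; an exhaustive sliding-circle check over all members is
kept as a test oracle. TLS flags never modify membership, so TLS ⊆ LCs by
construction. TLS are sought within detected LCs, not over all
lymphocytes, since TLS are a subset of LCs and every TLS-dense region
necessarily contains core points at the LC scale.

The size distribution for outcome o and type i stores P_{o,i}(s), the
number of clusters of size s, and N_{o,i}, the total lymphocytes in those
clusters; the normalised curve P/N satisfies Σ_{s≥5} P(s)·s / N = 1
exactly, and the cumulative fraction f(s) accumulates the summand,
reaching exactly 1 at the largest size. Composition proportions are
computed per cluster over lymphocyte members (summing to 1), then
averaged unweighted across a patient's clusters; cohort values average
the per-patient values.

## Densities and distances

Densities always divide by the full ROI area, never by compartment area,
so island + stroma densities add exactly to the overall density for any
phenotype set and membership scope. Membership scopes (isolated only, in
any LC, in heterotypic LCs, in pure-T LCs) filter on the cluster
assignment. Fractions of lymphocytes isolated / in LCs / in TLS are
reported per scope; a scope with zero lymphocytes reports the fraction as
missing, never as zero.

The LC-to-island distance is the exact minimum Euclidean distance between
any cluster member and any cancer-phenotype cell carrying the
cancer-island tissue mark — cancer cells define islands, so lymphocytes
located inside islands are not targets. The minimum is evaluated through
a k-d tree over the cancer cells, which returns exact nearest neighbours;
the test suite checks bit-level agreement with the all-pairs minimum.
Per-patient summaries report the mean of per-LC distances (medians are
also emitted). The size–distance association is the Pearson
product-moment correlation of per-patient (mean LC size, mean LC-island
distance) pairs with the two-sided t-transform p-value.

## Cohort statistics

Every metric is summarised per patient and cohort values are means of
per-patient values — cells are never pooled across patients. Group
comparisons report the classical equal-variance Student t-test (the
Welch variant is computed alongside and included in machine-readable
output), the two-sided Mann–Whitney p, and the ROC AUC as the scaled
Mann–Whitney U — P(good > poor) with ties counting ½. Metric direction is
never auto-flipped; AUC < 0.5 is reported as-is. No multiple-testing
correction is applied; p-values are raw and documented as such.

The RFS threshold places two thirds of patients strictly above the cut
and one third below, mirroring the good:poor proportions: the cut sits
midway between the ⌈n/3⌉-th smallest value and the next distinct value;
when ties straddle it, the largest candidate cut keeping at least 2n/3
above is chosen (deterministic and closest to the stated proportions).
Kaplan–Meier curves per stratum use the standard product-limit estimator
(via lifelines); a log-rank companion test is provided and flagged as a
conventional addition, not part of the core battery.

## Synthetic tissue generator

The generator emulates the statistical structure the analysis assumes,
not tissue biology: cancer-cell islands as non-overlapping discs
(truncated-normal radii, dart-throwing placement, cancer cells at
2000/mm² of island area), a dispersed homogeneous-Poisson lymphocyte
field over the window, island-infiltrating lymphocytes on the discs, and
a Thomas-process clustered component whose parents are placed at a
controlled mean offset outside the nearest island boundary. Phenotypes
are assigned independently per lymphocyte: B with probability
`b_fraction`, otherwise a T lineage split helper:cytotoxic:regulatory =
0.50:0.35:0.15. Tissue category follows disc containment. Points landing
outside the window are discarded (no toroidal wrap), matching bounded
ROIs whose edge squares are kept if occupied. All generators are
deterministic given their seed; cohort generation derives per-patient
sub-seeds from (seed, patient index) so patterns are independent of
cohort composition and ordering.

The default window is 3×3 mm and the Poisson reference intensity
300 points/mm². Default outcome profiles encode the qualitative effect
directions the analysis is meant to detect — good: dispersed B background
(150 lymphocytes/mm², 30% B), many small clusters (10 parents/mm², mean
size 15) near islands (60 μm offset), more island infiltration; poor:
sparse background (50/mm²), few large clusters (5/mm², mean size 40) far
from islands (220 μm offset). These constants were fixed once as
plausible magnitudes for the parameter-recovery suite; they are
documented package constants, not claims about real tumors. Because
phenotypes are i.i.d. within clusters, synthetic LCs are predominantly
heterotypic — pure-T LCs arise but are rare, unlike real tissue where
pure-T LCs are common. Passing tests therefore demonstrate that the
machinery recovers built-in spatial effects (dispersion, abundance, size,
island proximity) under Poisson/Thomas structure; they do not certify
behaviour under real-tissue features such as anisotropy, holes, serial
sections, segmentation errors or phenotype spillover.

Synthetic relapse-free survival draws poor-outcome relapse times uniform
on 6–36 months (event observed) and good-outcome censoring times uniform
on 60–120 months, matching the outcome definitions (relapse within
3 years vs event-free ≥ 5 years).

## Numerical choices and degenerate inputs

Zero-cell patterns cannot be gridded (N would be 0) and empty tables are
rejected at read time; zero-lymphocyte patterns yield empty cluster
results, densities of 0, and missing-flagged LC metrics. Coordinates are
float64 μm throughout; table serialization keeps 10 significant digits,
and the read-write round trip is the identity to 1e-6 μm. Duplicate
coordinates are allowed with a warning (digitization can place two cells
on one centroid). FD fits require ≥ 3 scales with n > 0. Distance metric
is Euclidean everywhere.

Problem sizes in the test and acceptance suites: Poisson references use
20 replicate seeds at 300/mm² in 3×3 mm (~2700 points each); the
normalization identity is checked on 50 patients in 1.5×1.5 mm windows;
parameter recovery uses 10 cohorts of 24 good + 12 poor full-size
patients. These sizes give stable averages for the stochastic checks
while keeping the default suite quick on one CPU.

## Known limitations

- The occupancy/FD machinery assumes one pattern per patient; pooling
  multiple images per patient is out of scope.
- The grid anchor is fixed, not averaged over offsets; box-count slopes
  carry the usual mild anchor dependence.
- TLS detection is purely density-based; it does not use immunostain
  evidence (PNAd, DC-LAMP) or B/T zonation.
- Distances are straight-line Euclidean, not within-stroma path
  distances.
- The RDS-to-CSV conversion of externally deposited spatstat `ppp`
  cohorts is not bundled; the CSV contract in `tilspatial.io` defines the
  target format for any converter.
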