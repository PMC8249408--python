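# tilspatial

Spatial statistics for tumor-infiltrating lymphocytes (TILs) in marked
2-D cell point patterns, as produced by multiplex immunohistochemistry:
each cell carries coordinates in micrometres, a phenotype (CD20⁺ B cell,
CD3⁺ T-cell lineages, cancer, other) and a tissue category (cancer-cell
island vs stroma). The package quantifies *where* B and T cells sit — not
just how many there are — and compares the resulting per-patient metrics
between clinical outcome groups.

## What it computes

**Occupancy.** The tissue is tiled with squares of side *L* (10–600 μm);
each square answers a binary question such as "is there at least one
stromal B cell here?". Squares containing no cell at all are omitted as
non-tissue. Occupancy is the fraction of cell-containing squares answering
yes, traced as a function of *L* and summarised by its area under the
curve (against ln *L*).

**Fractal-dimension difference.** With *n(L)* the number of yes-squares,
the box-count fractal dimension is the least-squares slope *s* of
ln *n(L)* versus ln(1/*L*) over a scale window (natural logarithms). An
area-filling arrangement gives *s* → 2 (*n* ∝ 1/*L*²); an isolated point
gives *s* → 0. The dispersion score

&nbsp;&nbsp;&nbsp;&nbsp;Δ*s* = *s*<sub>large</sub> − *s*<sub>small</sub>

contrasts the 200–600 μm window with the 10–40 μm window: spatially
dispersed cells look two-dimensional at large scales and point-like at
small scales (large Δ*s*), while clustered, nearly self-similar
arrangements keep the slope flat (small Δ*s*). For a uniform Poisson
process at 300 points/mm², *s*<sub>large</sub> ≈ 2 and
*s*<sub>small</sub> ≈ 0.15.

**Lymphocyte clusters (LCs).** DBSCAN over all lymphocytes with
eps = 20 μm and min_pts = 5 — at least five lymphocytes within a circle of
40 μm diameter — partitions lymphocytes into LCs and isolated cells. LCs
are typed pure-T, heterotypic (B + T) or pure-B, and a cluster qualifies as
a tertiary lymphoid structure (TLS) when at least 200 of its members fall
in a 70 μm-radius circle. Cluster-size distributions are normalised so
that Σ<sub>s≥5</sub> *P*(*s*)·*s* / *N* = 1, with cumulative fraction
*f*(*s*) of lymphocytes in clusters of size ≤ *s*.

**Region-resolved metrics.** Densities by phenotype × tissue compartment ×
cluster membership (denominator always the full ROI area), isolated
vs clustered fractions, and the distance from each LC to the nearest
cancer-cell island (minimum member-to-cancer-cell distance).

**Cohort statistics.** Per-patient metrics first, then cohort means of
per-patient values; two-sided Student t-tests (equal-variance, Welch
alongside), Mann–Whitney, ROC AUC by pair counting, a two-thirds/one-third
relapse-free-survival threshold rule, and Kaplan–Meier curves.

A synthetic-tissue generator (`tilspatial.synthetic`) builds patterns with
cancer-cell disc islands, dispersed Poisson and clustered Thomas-process
lymphocytes, B/T phenotype mixes and good/poor outcome profiles, so every
stage runs and is tested without patient data.

## Worked example

```python
from tilspatial import (BinaryQuestion, GOOD_PROFILE, detect_clusters,
                        detect_tls, fd_difference, occupancy_auc,
                        occupancy_curve, region_density, synthesize_patient)

patient = synthesize_patient(GOOD_PROFILE, seed=42, outcome="good")
q = BinaryQuestion.b_cells("stroma")
dd = fd_difference(patient, q)
auc = occupancy_auc(occupancy_curve(patient, question=q))
clusters, isolated = detect_clusters(patient)
tls = detect_tls(patient, clusters)
```

prints, via the obvious f-strings:

```
cells: 4558, ROI: 9.0 mm^2
stromal B FD: s_small=0.222, s_large=1.961, delta_s=1.739
stromal B occupancy AUC: 2.143
LCs: 67 (67 heterotypic, 0 TLS), isolated lymphocytes: 1437
B-cell density in cancer islands: 8.7 cells/mm^2
```

The large Δ*s* (1.74) says this synthetic good-outcome patient's stromal
B cells are spatially dispersed — close to the Poisson reference (≈1.85)
and far from the confined arrangements that depress *s*<sub>large</sub>.
The occupancy AUC is the integral of the yes-fraction across the 60-fold
scale range (maximum ln 60 ≈ 4.09 for occupancy ≡ 1).

A command-line interface wraps the pipeline:

```
tilspatial simulate --n-good 24 --n-poor 12 --seed 1 --out cohort/
tilspatial analyze cohort/*.csv --out run/
tilspatial report run/
```

`analyze` writes `patient_metrics.tsv` (one row per patient, one column
per registry metric), `cohort_comparison.json` (group means, t and
Mann–Whitney p-values, ROC AUC per metric), `clusters.tsv` and a run
manifest; `report` renders them as a table.

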