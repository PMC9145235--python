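# Methods

This note documents the models, defaults and numerical choices behind
`shankvb`, and what the synthetic generators do and do not emulate.

## Synthetic cross-sections

A section image is an 8-bit raster at a default resolution of 13.55
µm/pixel (the working resolution of bench-top micro-CT stem scans).
Tissue contrast is reduced to three intensity bands — background 0,
tissue 120, bundles 220 — plus additive Gaussian noise (sd 8, clipped to
0–255). This keeps the scene separable by a single threshold while still
exercising the segmentation stack; it deliberately does not model CT
physics, beam hardening, staining gradients or partial-volume effects,
so passing recovery tests here says the *geometry* pipeline is correct,
not that the thresholding strategy would survive arbitrary real stain
variation.

Section outlines cover the five shapes seen in real shank slices: round,
crescent and bell (Boolean carving of a secondary disk from the primary
disk), horseshoe (an angular notch of configurable depth and width), and
irregular (a disk perturbed by radial harmonics of order 2–5, relative
amplitude 0.06). Exact outlines of real sections are not standardised;
these are qualitative stand-ins.

Bundles are hard disks placed by dart throwing. Defaults: 100 periphery
bundles in the annulus between the epidermis (0.08 mm deep) and 1.0 mm
below it, 80 inner bundles uniform over the remaining disk; equivalent
radii drawn from N(0.139, 0.02) mm (periphery) and N(0.176, 0.025) mm
(inner), truncated to [0.06 mm, 2.5·mean]. The numbers reproduce the
two facts that matter downstream: the periphery is several-fold denser
than the pith (≈2.5 vs ≈0.73 bundles/mm² here), and inner bundles are
individually larger (planted area ratio ≈0.62). Counts are scaled below
real sections because the placement rule enforces a minimum centre
separation (0.40 mm, raised pairwise to the two radii plus a 6-px
clearance); at realistic per-zone counts the periphery would have to pack
at close to the hard-disk limit, which dart throwing cannot reach
reliably. A cumulative-area precheck fails grossly infeasible requests
up front, naming the first unplaceable bundle, and the per-bundle
rejection budget (2000 attempts) fails marginal ones the same way.
Placement keeps each planted centre at least 2 px clear of the planted
PZ/IZ boundary so that ground-truth zone labels are unambiguous under
±0.5 px centroid error.

## Imaging pipeline

Segmentation is Otsu thresholding (or a fixed threshold), largest
8-connected component, holes filled. Bundle detection applies a second
Otsu threshold restricted to tissue pixels, labels candidates
(8-connected), and validates each against an area window (defaults
0.01–0.5 mm²) and a solidity floor (0.5). Candidates failing any filter
— fused neighbours, noise specks — are reported in a rejects list; the
pipeline never attempts to split a fused blob.

Zones are defined on the Euclidean distance from the section contour
("depth"). EZ is the band shallower than 0.08 mm (the population-median
epidermis thickness); the PZ/IZ boundary is found per section by the
`density_valley` policy: bin bundle-centroid depths (0.02 mm bins),
divide by the shell area at each depth, smooth both with a Gaussian of
0.25 mm bandwidth, and place the boundary where the profile first falls
to the midpoint between the peripheral peak and the interior plateau.
The midpoint-crossing rule is used instead of "first local minimum"
because the per-depth profile declines monotonically into the pith
(shell circumference shrinks with depth), so its only interior minima
are noise wiggles, biased a couple of bandwidths too deep; the midpoint
crossing of a smoothed step sits at the step itself and recovers planted
boundaries to within ~0.1 mm. When there is no peripheral density
contrast (interior plateau above 60 % of the peak, or no bundles) the
boundary falls back to a fixed 1.0 mm depth; `("fixed_depth", d)` is
also available directly and ignores the bundles entirely.

Label conventions: the partition is exact by construction
(EZ: 0 < depth < t, PZ: t ≤ depth < b, IZ: depth ≥ b — a pixel exactly
on a boundary belongs to the inner zone). A bundle takes the zone of its
centroid pixel; centroids inside the epidermis map to PZ, since bundles
are never epidermal.

## Trait definitions

Areas are pixel counts scaled by (resolution/1000)²; the convex hull is
taken over pixel-corner points (a single pixel has hull area 1 px²), so
`A ≤ CA ≤ CCA` holds identically; the circumcircle is the minimal
enclosing circle of the hull vertices (GEOS). Long/short axes are those
of the moment-equivalent ellipse, clamped to ≥ 1 px so degenerate
one-row regions keep a positive width. The perimeter follows the
8-connected Moore contour chain with Vossepoel–Smeulders corner-corrected
weights (0.980 axial, 1.406 diagonal, −0.091 per direction change),
which keeps digitised circles within ~1 % of their true circumference;
the plain (1, √2) weighting, available via `corner_corrected=False`,
overshoots circles by ~5 %. Thin (≤ 2 px wide) regions are
underestimated by any centerline chain; bundles are far above that
scale.

Zone thicknesses are radial measurements along 720 rays from the section
centroid: EZ_T and PZ_T are mean band widths, IZ_T the mean radial
distance to the PZ/IZ boundary. For convex, roughly centred sections
these agree with the depth-band parameters to within a pixel.

Two Table-style traits have no standard formula and are defined here
explicitly: **SRVB** (separation ratio) is the mean nearest-neighbour
centroid distance divided by the mean bundle equivalent diameter, and
**ARIVB** (area ratio of individual bundles) is the mean bundle area in
the periphery divided by the mean bundle area in the inner zone —
dimensionless, below 1 whenever inner bundles are larger. **VB_LWR** is
implemented as its name demands, VB_LAave / VB_SAave ≥ 1; published
tables have printed this trait on an unexplained 10⁻³ scale, which a
length ratio cannot reproduce, and this package does not try to match
that scale. Zones with zero bundles report averages as missing (NaN)
and densities as 0; a scene with no bundles at all is an error.

## Population statistics

Fold variation is max/min over non-missing values, flagged undefined
when the minimum is ≤ 0. Spearman correlation uses pairwise-complete,
tie-corrected ranks with two-sided p-values from the t approximation;
trait clustering is average-linkage agglomerative clustering on `1 − ρ`,
cut to k = 4 groups by default, with columns processed in registry order
so tie-breaks are deterministic. ANOVA is one-way and fixed-effects;
Duncan's multiple range test uses studentized-range quantiles computed
numerically (`scipy.stats.studentized_range`, no lookup tables) at the
protection level `1 − (1−α)^(r−1)` for a range of r means, with the
ANOVA MSE and residual degrees of freedom, the harmonic-mean group size
for unequal n, and the classical protected sweep (a non-significant
range shields its sub-ranges). Letters are assigned to maximal
non-significant contiguous runs of the descending means, which makes the
display transitively consistent by construction. With two groups the
test coincides with the pooled two-sample t-test (`q = √2·t`).

## Mixed model, BLUP, heritability

The panel model is `y_ijr = μ + env_j + f_i + (fe)_ij + ε_ijr` with
environments **fixed** and line and line×environment effects random.
Environments are fixed because two or three locations cannot support a
variance estimate and the heritability formula involves only Vg, Vgl and
Ve; the panel simulator still draws an environment main effect
(`env_sd`, default 1.0) so the fixed part is non-trivial. The
interaction component is fitted only when it is estimable (more than one
environment and replicates within cells); with one environment Vgl is
structurally zero.

Estimation is EM-REML on Henderson's mixed-model equations: tolerance
1e-8 on the relative change of every component, at most 1000 iterations,
negative updates truncated at zero, components collapsing to zero frozen
and dropped from the model, non-convergence returned with a flag and a
warning. For balanced panels the closed-form expected-mean-square
estimates (which equal REML there when interior) are used directly as
the `auto` fast path and as the EM starting values; on unbalanced panels
the EM estimates agree with lme4's REML to ~3 decimal places in the test
suite. BLUPs solve the same equations at the final components and are
reported as μ plus the predicted line effect; with Vg = 0 every line
collapses to μ. Heritability is the plug-in
`H² = Vg / (Vg + Vgl/L + Ve/(LR))` with the design's nominal L and R;
for unbalanced designs substituting harmonic-mean replication is the
user's choice of L and R.

## Association

QC removes SNPs with call rate < 0.9 or MAF < 0.05, both computed on
non-missing entries only (never imputed for QC). Scanning mean-imputes
missing dosages per SNP for testing only. The two methods are marginal
simple regression (Wald t on n−2 df) and PC-adjusted regression (the
same test after residualising trait and dosages on the top k = 3
genotype principal components, n−2−k df). PC adjustment is an
approximation to a kinship mixed model — adequate for discrete
stratification, weaker for fine-grained relatedness; this bound is
intentional, as the multi-locus mixed-model machinery itself is outside
this package's scope. Monomorphic SNPs get p = 1 and a flag. The
default threshold is `1/N`; a fixed secondary threshold (such as 2×10⁻⁴)
can be passed instead. Consensus hits are the intersection across all
methods. Gene annotation assigns a gene to a SNP when the position lies
in `[start − flank, end + flank]`, 1-based inclusive; flank defaults to
0 (SNP-in-gene) and annotation is monotone in flank. Unique genes are
those with bipartite degree 1 in the trait–gene network, shared genes
degree ≥ 2; the network is exported as an edge table. Enrichment is the
upper-tail hypergeometric probability of the observed overlap.

## Problem sizes in the recovery studies

The shipped recovery studies use 20–50 synthetic sections (180 bundles
each), 200 simulated panels of 200 lines × 2 environments × 3
replicates, 10,000 SNPs for null calibration and 200 replicates of a
5,000-SNP scan for power — sizes chosen so the full suite runs in a few
minutes on one CPU while keeping Monte-Carlo error well below the
tolerances being checked.

## Known limitations

* Classical threshold segmentation stands in for a trained semantic
  segmentation model; it requires the three-band contrast the generator
  produces and would need re-tuning for raw CT data.
* Fused bundles are rejected, not split, so the detector undercounts
  when real bundles touch at the imaging resolution.
* Radial zone thickness assumes the centroid sees each boundary roughly
  once per ray; deeply concave sections (extreme crescents) violate this
  and IZ_T becomes a rays-that-cross average.
* The EM-REML fit handles one trait at a time; there is no multi-trait
  REML and no pedigree/kinship covariance on the line effects.
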