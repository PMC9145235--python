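# shankvb

Zone-based phenotyping of maize shank cross-sections and the quantitative
genetics that follows from it.

The shank is the short branch stem that connects a maize stalk to its ear;
its vascular bundles are the pipeline through which assimilates reach the
grain. In stained micro-CT slices of the shank, bundles appear as bright
discrete regions inside the tissue, and the section naturally divides
into three functional zones: a thin **epidermis (EZ)**, a bundle-dense
**periphery (PZ)** and a sparser **inner zone (IZ)** whose bundles are
individually larger. `shankvb` implements the full analysis chain for
this kind of data:

1. **Imaging** — segment the section from an 8-bit grayscale image,
   detect and validate vascular-bundle candidate regions (area window +
   solidity filter; fused blobs are rejected, not split), and partition
   the tissue into EZ/PZ/IZ from the distance to the section contour.
2. **Traits** — compute 36 named traits per section (cross-section,
   epidermis, periphery, inner-zone and bundle descriptors) in physical
   units: areas, convex areas `CA`, minimal-enclosing-circle areas `CCA`,
   perimeters, moment-ellipse axes, zone thicknesses, counts, densities
   `D = N / area`, the convex-area ratio `CAR = A / CA`, and so on.
3. **Population statistics** — per-trait variation summaries
   (median/min/max and max-to-min fold), Spearman correlation of traits
   with average-linkage clustering on `1 − ρ`, and one-way ANOVA with
   Duncan's multiple range test and compact letter display across
   subpopulation groups.
4. **Quantitative genetics** — for a line × environment × replicate panel
   `y = μ + f_i + e_j + (fe)_ij + ε`, REML estimation of the variance
   components (`Vg`, `Vgl`, `Ve`; EM-REML with a closed-form fast path
   for balanced panels), per-line BLUPs, and broad-sense heritability
   `H² = Vg / (Vg + Vgl/L + Ve/(LR))`.
5. **Association** — marker QC (MAF ≥ 0.05, call rate ≥ 0.9), per-SNP
   scans with two methods (marginal regression and PC-adjusted
   regression), the `p ≤ 1/N` genome-wide threshold, intersection of hits
   across methods, SNP→gene annotation from GFF3 intervals, unique/shared
   gene tabulation with a trait–gene edge table, and a hypergeometric
   enrichment utility.

Because real CT stacks and the reference genotype panel are not shipped,
the package includes first-class **synthetic generators** with exact
ground truth: cross-section images in the five observed section shapes
with the peripheral/inner bundle-density gradient, phenotype panels with
known variance components, and genotype matrices with planted QTL.

## Worked example

```python
from shankvb.synthetic import SectionShapeSpec, BundleSpec, generate_cross_section
from shankvb.imaging import analyze_section
from shankvb.traits import compute_trait_vector

img, truth = generate_cross_section(SectionShapeSpec(), BundleSpec(), seed=1)
mask, partition, detection = analyze_section(img)
tv = compute_trait_vector(mask, partition, detection.bundles)
print(tv.to_series().round(3).head(12))
```

prints

```
SZ_SA       14.001
SZ_P        43.947
SZ_LWR       1.000
SZ_LA       14.001
SZ_CCA     154.354
SZ_CA      154.263
SZ_A       153.951
EZ_T         0.075
EZ_A         3.334
PZ_VB_N    100.000
PZ_VB_D      2.497
PZ_VB_CAR    0.947
```

— a 7 mm round section of 153.95 mm², an epidermis 0.075 mm thick, and
all 100 planted periphery bundles found at a density of 2.5 bundles/mm².
The detector recovers all 180 planted bundles (recall and precision 1.0
by centroid matching), and the recovered PZ/IZ boundary depth (1.07 mm
here) sits within a tenth of a millimetre of the planted 1.08 mm.

Downstream, the same objects feed `quantgen.fit_variance_components` /
`blup` / `heritability` for simulated panels and `assoc.run_association`
for simulated genotypes; see `docs/methods.md` for models, parameter
defaults and numerical choices.

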