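# Methods

This note documents the models, estimators and numerical choices behind
`chondroscreen`, and what the synthetic validation does and does not
establish about real data.

## Measurement model

A well is a ~500 µm hydrogel column with cells seeded at the floor (plane
0; stacks are acquired from the bottom, so depth = plane index × z-step).
Two acquisition geometries are modelled: a morphology setup (8 planes, 2 µm
step, 40x) and a migration setup (nuclei channel only, 102 planes, 5 µm
step, 20x).  The lateral calibration (µm/px) is deliberately a required
input with no default — it must come from the instrument — and the
synthetic layer declares its own (0.30 µm/px morphology, 0.60 µm/px
migration, realistic for those objectives).

The phenotype of interest is the chondroprogenitor shift: versus basal
medium (small rounded cells, ~230 µm², roundness ~0.78), chondrogenic
medium produces large elongated cells (~694 µm², roundness ~0.64), reduced
upward migration, and reorganized actin.  Hit calling asks whether a
compound reproduces that shift.

## Synthetic data generator

The generator is the package's ground-truth instrument.  It has two layers.

**Rendering layer.**  Latent cells carry position, footprint area (µm²),
aspect ratio, z-plane, texture class and brightness.  Nuclei render as 3D
Gaussians (σ_xy = 4 px, σ_z = 1 plane — chosen to match the blob detector's
assumptions and keep oracles analytic); cytoplasm as a 2D anisotropic
Gaussian at the cell's plane whose **half-maximum ellipse** has exactly the
nominal area (area = 2π ln2 σ_x σ_y) and axis ratio; actin as scattered
peaks (spot), oriented fibres with Gaussian cross-section (ridge), both
(mixed) or a constant fill (flat).  Noise is additive Gaussian, clipped at
zero.  Whole-well cell counts (~3×10⁴, SD 3×10³) are thinned to one field
of view by a Binomial(n, field area / well area) draw, so a 512×512 field
at 0.6 µm/px holds ~90 cells.  Per-well RNG substreams are keyed by
(seed, row, col): identical inputs give byte-identical stacks regardless of
iteration order.

**Aggregate layer.**  Plate statistics operate on per-well summaries, and
at 3×10⁴ cells/well the cell-sampling error of a well mean is negligible;
what matters is well-to-well variation.  Effect models therefore carry
multiplicative well-level CVs alongside cell-level SDs.  Defaults for the
controls use the assay's observed reproducibility (area CV 11% basal / 18%
chondro; roundness 2.7% / 3.1%).  Per-cell SDs and compound-model CVs are
free parameters chosen for testability — the source material reports only
condition means.  Roundness is derived from the planted aspect ratio
through the closed-form ellipse circularity (Ramanujan perimeter), so
aspect 2.35 ↔ roundness 0.78 and aspect 3.2 ↔ 0.63.

Migration depth is a two-component mixture: floor (planes 0–5) and a
migrating fraction uniform over planes 10–100.  Basal cells migrate more
(fraction 0.25) than chondrogenic ones (0.10), matching the assay's
qualitative finding.  Actin direction is a modeling choice the source does
not fix: basal cells default ridge-dominant (spread cells with stress
fibres), chondrogenic cells spot-dominant (depolymerised cytoskeleton); no
validation quantity depends on the direction, only on class separability.

`benchmark_effects()` is a separate parameter set for validating the *hit
rule*: the printed condition means with uniform modest well CVs (8% area,
2% roundness).  Uniform CVs matter because the decision rule pools one
ANOVA variance; grossly unequal condition CVs test heteroscedasticity
robustness, not the rule.

**Not modelled:** optical PSF, photobleaching, gel light scattering,
Poisson shot noise, cell-cell contact geometry, field-position effects.
Passing tests therefore demonstrate algorithmic correctness against the
stated object model, not instrument-level fidelity.

## Nucleus detection

Multiscale scale-normalized LoG in 3D: response = −σ²·∇²(G_σ∗I) at four
geometrically spaced lateral scales (default 3–6 px), axial sigma =
lateral × anisotropy (default 0.25 = 1 plane / 4 px).  Local maxima over a
3×5×5 neighbourhood, thresholded at a **fraction of the maximum response**
(default 0.15) so detection counts are invariant to global intensity
scaling, then greedy non-maximum suppression within a max-sigma radius in
anisotropy-normalized space.  Maxima within 4 px of the lateral image
border are discarded (partially imaged objects and filter edge artifacts);
the z borders stay live because the gel floor is a real cell location.  At
SNR 10 with > 6σ separation this recovers planted nuclei with
precision = recall = 1.00 on the validation battery (the stated guarantee
is ≥ 0.98).

## Segmentation and morphometry

Footprints are segmented on the cytoplasm max projection: Otsu foreground,
watershed from nucleus seeds (8-connected), components < 50 px dropped.
Because the Otsu cut depends on the field's brightness mix, measured labels
are then refined per cell to pixels above half that cell's own maximum —
the contour on which the area calibration is defined.  Isolated noise-free
cells recover nominal area within < 1% (tolerance ±5%).

Roundness is circularity 4πA/P² clamped to ≤ 1.  The perimeter estimator
is the marching-squares contour simplified by Douglas-Peucker with
tolerance max(1 px, 0.025·√A).  Rationale: naive pixel-edge length biases a
disk to ~0.92; Crofton multi-directional estimates fix disks but bias
axis-aligned squares to ~0.88; contour simplification removes raster
staircases without rounding true corners, giving disk ≥ 0.99, square
0.793 (π/4 = 0.785), 3:1 ellipse 0.664 (Ramanujan oracle 0.663), and the
area-scaled tolerance makes the estimate stable (< 2%) under integer
upsampling.  The commercial software's roundness formula is unpublished;
only orderings (elongated < round) and the closed-form oracles are relied
on, never absolute parity with the original instrument.

The large-cell flag is strict: area > 500 µm².

## Migration statistics

Each nucleus belongs to exactly one plane (nearest plane of its centroid),
so plane counts are disjoint and sum to the detection count.  The
migration statistic is the sum over the five assessment planes
{20, 40, 60, 80, 100}; it is a *sampling* of migrated cells at fixed
depths, not a census — nuclei at, say, plane 30 are migrated but uncounted,
by construction.  Wells with counts strictly above 200 are selected.  Both
the planes and the threshold are configuration values, reusable for other
gel heights.

## Actin texture (SER-style)

The commercial SER operators are proprietary; the implementation is a
functional equivalent on the Hessian of the (optionally kernel-normalized)
image at σ = 3 px, computed by Gaussian-derivative convolution.  With
eigenvalues λ₁ ≥ λ₂: spot = −(λ₁+λ₂) where both are negative; ridge =
−λ₂·(1 − |λ₁|/|λ₂|) where λ₂ < 0 dominates.  Dark-feature duals (hole,
valley) are provided but unused.  Kernel normalization divides by the
Gaussian local mean at the same σ, which cancels global intensity exactly
(the invariance holds to machine precision, not just 10⁻⁶).  Two numerical
details: scipy's truncated second-derivative kernels do not sum exactly to
zero, so the kernel-sum bias times the smoothed image is subtracted —
making a constant image yield exactly zero curvature; and eigenvalues below
10⁻¹² of the mean image magnitude are treated as flat.  Whether the
original "scale 3 px" means σ or half-width is unknowable; σ = 3 px is
adopted and configurable.  Per-cell values are means over the label's
pixels.  Only orderings and invariances are guaranteed (spot-class cells
score ser_spot > ser_ridge and vice versa, 100/100 on the validation
battery); absolute SER values are implementation-specific.

## Plate statistics

The well is the replication unit everywhere; cells within a well are
pseudo-replicates and never enter a test directly.

- **CV gate**: sample SD (n−1) / mean × 100, strict < 20%.  n−1 is chosen
  because replicate counts are small; the formula's source does not
  specify the denominator.
- **ANOVA + Tukey HSD**: one family per parameter spanning all conditions
  on the plate (scipy's `f_oneway`/`tukey_hsd`; cross-checked against
  statsmodels to 10⁻⁸ in the tests).  Degenerate designs (no between-group
  separation, or zero within-group variance) are reported explicitly
  rather than as NaN.  **Areas are compared on the log scale**: well
  effects are multiplicative, and pooling one variance across ~230 µm² and
  ~690 µm² cells is only tenable after the transform.  Reported means stay
  in µm².
- **Hit rule** (each arm independently configurable): significantly
  different from basal on area *and* roundness (Tukey-adjusted p < 0.05),
  *not* significantly different from chondro on either, mean area >
  500 µm².  The chondro arm is absence of evidence, not equivalence; a
  TOST option exists but is off by default because no equivalence margin
  is given by the assay.  α defaults to 0.05.
- **Dose-response**: per-concentration mean ± SD plus the same Tukey
  comparisons, eight semi-log concentrations (0–1000 nM), four replicates;
  missing levels are summarized with a warning.
- **Unpaired t** (pooled variance, two-sided) is provided for gene-
  expression comparisons.

## Marker assays

Percent-positive = share of nucleus labels whose mean marker intensity
strictly exceeds a threshold; the threshold is a required input with an
Otsu-on-per-nucleus-means default, since no absolute cutoff is portable
across stains.  Collagen-type signals are per-cell means aggregated per
well.  ΔΔCt uses group-mean ΔCt (treated − control) with fold = 2^(−ΔΔCt);
per-pair ΔΔCt is available via `paired=True`.  No amplification-efficiency
correction is applied.

## Problem sizes in the validation battery

Chosen as the smallest sizes at which the guarantees are meaningful:
50 wells (9 cells each, 128×128×102 voxels) for migration exactness and
for detection precision/recall at SNR 10; 16 isolated cells for area
recovery; 100 single-cell fields for texture-class separation; 1000 null
datasets for type-I calibration; 100 plates (two compounds × 4 replicate
wells + 8 control wells) for end-to-end hit calling, plus 100 all-basal
null plates.

## Known limitations

- Touching or overlapping footprints merge or split at the watershed's
  discretion; the ±5% area guarantee holds for isolated cells only.
- The migration statistic undercounts migrated cells by design (five fixed
  depths out of 91 migrating planes).
- Absolute roundness and SER values are estimator-specific; cross-study
  comparisons should use within-study orderings.
- The hit rule's "indistinguishable from chondro" arm rewards low power;
  with very many replicates a genuinely chondro-like compound with a small
  real offset will eventually fail that arm.  This is a property of the
  codified rule, documented rather than hidden.
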