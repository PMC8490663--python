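# Methods notes

## Pipeline model and assumptions

The analysis treats a patient's tumor as a binary set of template-space
voxels and every "eloquent region" as a fixed template-space mask. All
spatial reasoning happens on one grid (the template's), in physical units:
a voxel contributes `|det A₃ₓ₃|` mm³, an overlap is an intersection count
times that, and the proximity judgment is a threshold on that physical
volume. This deliberately reduces eloquence to a binary, atlas-normative
statement — no patient-specific functional localization (fMRI/DTI/TMS) is
modeled, and no graded lesion-severity score is attempted; the overlap
volume is exported so users can study dose–response themselves.

Assumptions worth keeping in mind:

- segmentations are trusted as given; the package never re-segments or
  morphologically cleans them. Multifocal masks are used whole — the
  largest-component rule used for lobe taxonomy does not apply to voxel
  scoring — and masks with more than one connected component are logged;
- affine (12-parameter) registration into template space is adequate for
  group-level location statements in tumors without major mass effect
  (lower-grade gliomas rarely carry significant edema). The registration
  *estimate* is external input; this package only guarantees its correct
  application;
- atlas masks are normative: a tract probability above the threshold means
  "the tract is usually here", not "this patient's tract is here".

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `overlap_threshold_mm3` | 1 (10 as sensitivity setting) | mm³ | minimum tumor∩region volume counted as proximity; inclusive (≥) |
| `tract_probability_threshold` | 0.5 | fraction | strict lower bound (>) for tract presence in a voxel |
| `alpha` | 0.002 | — | multiplicity-adjusted significance level; inclusive (p ≤ α) |
| `kps_cutoff` | 90 | KPS points | scores strictly below are "impaired performance status" |

Reading conventions that were genuinely open and are fixed here, each with a
dedicated edge-case test: "minimum overlap" is inclusive (on a 1 mm
isotropic grid ≥1 mm³ and >0 mm³ select the same voxel sets, so the choice
is cosmetic there but matters on anisotropic grids); "likelihood above 50%"
is strict, so a map identically 0.5 yields an empty mask; the significance
rule is inclusive at the boundary (p = 0.002 is significant) and
configurable, since descriptions of the same analysis can be found with
both readings; KPS = 90 is *not* impaired.

## Geometry conventions

All volumes are reoriented to RAS+ on read (data and affine jointly), so
"left hemisphere" means negative world x everywhere downstream — but
hemisphere assignment for parcellation labels comes from the atlas's own
label table, never from the coordinate sign; a validation pass cross-checks
each label's centroid against its annotation and warns on disagreement.
Affine precedence on read is sform when coded, else qform, else the
pixdim fallback (the dominant community convention; source headers that
disagree between the two are resolved the same way for every input, and the
choice is logged). Voxel indices are 0-based and refer to voxel centers.
Binary masks are stored as unsigned 8-bit so round trips are bit-exact.

FLIRT matrices operate on "scaled-voxel" coordinates: voxel index times
voxel edge length, composed with an x-index flip when the image's
voxel→world determinant is positive. The conversion to world coordinates,
`W = A_t·S_t⁻¹·M·S_s·A_s⁻¹`, is tested against hand-composed landmark
oracles for both handedness cases, because this flip is historically the
most common source of silent left/right errors. Masks and label volumes are
resampled nearest-neighbour only (keeps them binary/label-valued with no
re-binarization threshold); trilinear is available for intensity images.
When the two-stage matrices (structural→template and segmentation-grid→
structural) exist separately, sequential application is the default and a
pre-composed matrix is accepted.

## The eloquence panel

Nine parcellation structures and five tracts yield 21 analyzed regions: 14
as bilateral pairs (precentral, postcentral, pericalcarine, hippocampus,
parahippocampal, corticospinal tract, optic radiations) and 7 left-only
(supramarginal, pars triangularis, pars opercularis, inferior parietal,
SLF, AF, IFOF) on the rationale that language function is most often
left-lateralized. The mapping from clinical region names to concrete atlas
label ids is *editorial*: it ships as an editable panel file resolved by
structure name against the bundle's own label table (CerebrA-style naming
by default), rather than hard-coded ids that would silently break across
atlas releases. Which labels realize a clinical name (e.g. whether
"inferior parietal" includes an angular-gyrus label) is a user decision the
panel file makes visible. Real published atlases are supported but never
required; the whole test surface runs on the synthetic bundle.

## Statistics

Exact tests use the point-probability two-sided criterion — sum the
probabilities of all margin-fixed tables no more probable than the observed
one, with a 1+1e-7 relative tie tolerance — which reproduces published
three-decimal p-values and is stable under floating-point ties. The r×c
Freeman–Halton generalization enumerates tables recursively with a 10⁷
candidate-table guard; beyond it, a seeded Monte-Carlo estimate over the
conditional null (Patefield sampling) is available explicitly, never
silently.

For a binary predictor the univariable logistic MLE has the closed form
`β̂ = ln(ad/bc)`, `SE = √(Σ 1/cell)`; the package uses it directly and the
test suite asserts 1e-6 agreement with an iterative fit on a thousand
random tables. Wald intervals use z = 1.96 — the reporting convention the
published intervals follow, asserted to three decimals in tests. Zero
cells receive the Haldane–Anscombe +0.5 correction with a mandatory flag in
the result record; complete separation and constant predictors are flagged,
not silently numbered. Group comparisons dispatch on a caller-declared
variable kind (t-test/ANOVA, Mann–Whitney/Kruskal–Wallis,
Fisher/Freeman–Halton); normality is never auto-tested because "when
appropriate" is not an algorithm, and auto-selection would invent one. The
"consecutive univariable" design is reproduced as-is — one fit per
predictor, no correction beyond the global α.

Table 3-style agreement between clinician-presumed and voxel-based
eloquence is summarized by Cohen's κ; both the κ statistic and a Fisher
test of the same 2×2 can be computed, since printed significance bounds for
agreement tables are ambiguous between the two.

## Heatmaps and slices

A cohort heatmap is the voxelwise segmentation count divided by group size,
so values live on {0, 1/n, …, 1}; the conservation identity
Σvoxels·v·n = Σ mask volumes is asserted to 1e-6. Report slices are chosen
by world coordinate (axial = z, coronal = y); a coordinate midway between
plane centers resolves to the lower voxel index, deterministically.
Rendering is intentionally out of scope: the tested artifacts are the
volume, its n-recording sidecar, and plot-ready CSV tables (including the
circular-bar-chart export with the standard short labels).

## Synthetic universe

The phantom emulates the structure of the real inputs, not their scale: a
64³ voxel, 1 mm RAS+ grid centered on the origin; mirrored 8×8×8-voxel
cuboid parcels for the nine structures (left at negative x); Gaussian
tract blobs (σ = 4 mm, peak 1.0) whose p > 0.5 set is an analytic ball of
radius σ√(2 ln 2); ellipsoid tumors digitized on voxel centers with radii
5–12 mm. Cohort defaults emulate the reference study population: group
sizes 82/67/73/55 across the three molecular subgroups plus an
uncharacterized group, a biopsy model P(biopsy) = expit(−2.6 + 1.4·eloquent)
giving ≈20% biopsies, per-group KPS distributions with P(KPS<90) ≈
0.49/0.33/0.29/0.35, and location biases giving the wild-type group the
highest eloquent involvement. Ground-truth proximity flags are computed
from the generating geometry independently of the overlap engine, which is
what makes the end-to-end oracle test meaningful.

What the phantom does **not** model: real brain geometry and parcel shapes,
registration error, segmentation noise, MR intensities, edema or
infiltration gradients, and realistic absolute tumor volumes (the phantom
head is ~64 mm across, so volumes are a scaled-down analogue). Passing
tests therefore demonstrate correctness of the *computations* —
geometry, thresholds, counting, statistics — not clinical validity on any
real cohort. Cohort-level counts tied to the original patient images are
not reproducible from this repository (those data are not public); they
are covered by format/shape checks on the exported tables and by the
synthetic end-to-end run.

## Numerical and degenerate-input choices

- Grid congruence tolerance: affines equal within 1e-4 mm; violations are
  hard errors, never warnings.
- Percent formatting rounds half away from zero to one decimal, matching
  the published table style ("108 (39.0)").
- An ellipsoid missing every voxel center returns an empty mask with a
  warning (not an error), since sub-voxel tumors are legitimate edge cases
  of random cohorts.
- κ is refused (undefined-statistic error) when expected agreement is 1.
- Problem sizes in the test suite are desk-scale by design: the exhaustive
  Fisher sweep covers all 2×2 tables with n ≤ 30, the overlap oracle runs
  100 random ellipsoid/parcel pairs on the 64³ phantom, and the Wald
  coverage simulation uses 2,000 replicates at n = 400, chosen as the
  smallest sizes at which the checked properties are sharp.

## Known limitations

Binary proximity says nothing about displacement versus infiltration of a
tract; the same overlap can mean very different surgical realities. The
left-only rule is a population-level simplification that misclassifies
right-lateralized language. Affine registration limits anatomical fidelity
in individual patients even when group-level statistics are robust. And the
panel, while editable, remains a normative committee of regions — users
studying a specific system (motor, language, memory) should replace it with
their own a-priori selection, which the panel file makes a one-line change.
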