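# Methods

## The assay and what the package measures

Neuroblasts dissected from the rostral migratory stream self-assemble into
spheroids in round-bottom ultra-low-adhesion wells. Plated in matrix, cells
emigrate radially; the readout of migration is what that emigration looks
like after 24–48 h in a single imaged field per well:

* **halo area** — the area of the whole connected segmented object (core
  plus attached halo of collective/chain migration) minus the area of the
  compact spheroid core, in μm². This is the primary screen statistic.
* **zone counts** — numbers of individually resolved (Hoechst-positive)
  cells per annulus of increasing radius from the core boundary.
* **live/dead composition** — Hoechst stains every nucleus; propidium
  iodide (PI) only enters membrane-compromised cells, so the PI-positive
  subset of detections is dead. Used to triage toxic compounds.
* **manual-mode emulations** — the area of the smallest circle centred on
  the spheroid intersecting at least six migrated cells (after discarding
  stray far-flung single cells), and the mean of the top 8 of the 10
  largest migration distances.

Wells are acquired as z-stacks: nine optical sections 25 μm apart
(total depth `(9 − 1) × 25 = 200 μm`), per channel.

## Image-analysis pipeline

1. **Extended-focus projection.** Each stack is collapsed to an
   all-in-focus 2D composite by selecting, per pixel, the slice with the
   largest intensity variance in a 9×9 neighbourhood. Every output value
   is copied from the input stack. (Commercial software ships proprietary
   extended-focus algorithms; local-variance selection is a standard focus
   -stacking surrogate with a testable definition.)
2. **Brightfield macro** (collective migration):
   `Smooth → Find Edges → Binarize → Dilation → Fill Holes → Erosion →
   Label → Sieve`. Operators: Gaussian smoothing σ = 2 px; Sobel gradient
   magnitude; Otsu threshold on the edge image (binarization is placed
   where the binary morphology needs it); isotropic dilation radius 2 px;
   hole filling; isotropic erosion radius 7 px; 8-connected labelling;
   sieve at 2,000 μm². A guard returns an empty mask when the thresholded
   edge image covers more than 25 % of the field — that only happens when
   Otsu splits pure noise (an empty well has no edges to find).
3. **Core/halo separation.** The contiguous object is the largest
   component; its *core* is the largest connected remnant of a
   morphological opening (disk radius 35 px). The opening erases
   strand-like halo structure while preserving the compact body, so
   `core ⊆ contiguous` by construction and
   `halo = contiguous − core` exactly, in pixels, before calibration.
   The spheroid count is the number of connected components of the opened
   foreground exceeding the sieve area — the opening severs thin bridges,
   so two bodies fused by a halo strand or a debris contact still count
   as two; the count feeds QC.
4. **Fluorescence macro** (`Binarize → Fill Holes → Sieve` at 20 μm²),
   one detection per component with centroid and area. Detections whose
   centroid falls inside the core are flagged `in_core` and excluded from
   migration counts — nuclei inside the dense core are not individually
   resolvable, in synthetic renders as in the real assay.
5. **Live/dead comparison.** Each Hoechst detection's mean PI intensity is
   compared against a threshold: Otsu over the per-detection means when
   the Otsu split exposes a genuinely PI-negative class (lower-class mean
   below an absolute floor of 0.10), otherwise the floor alone. The guard
   matters for unimodal wells: plain Otsu would split an all-dead (toxic)
   well down the middle. Classification uses the raw PI projection —
   a contrast stretch would inflate a pure-noise PI background into fake
   signal on healthy wells.
6. **Distances** are measured with a Euclidean distance transform of the
   core complement, i.e. distance to the nearest core-boundary pixel
   (a centroid-based mode exists behind a flag). Zone counts use
   half-open 50 μm annuli, six zones plus an overflow bin, so the bins
   always sum to the number of non-core detections.

### Calibrated operator defaults

The edge-based binarization marks a band straddling the true object
boundary, so a macro with symmetric dilation/erosion systematically
over-segments the core. The erosion radius (7 px against dilation 2 px)
and the core-opening radius (35 px) were calibrated on synthetic wells
with known core areas — a grid search minimising the mean core-area error,
frozen at bias −0.0 % ± 0.3 % (per-well SD 1.5 %) over 32 default wells.
All operator sizes remain configurable (`BrightfieldParams`,
`NucleiParams`); the defaults assume structures at the default scale
(cores ≳ 50 px radius, cells ~6 μm at 1 μm/px). Wells whose content is
much smaller need proportionally smaller operators.

## Shape statistics

* **Circularity** `4πA/P²` uses a stated perimeter estimator:
  marching-squares contours simplified by Douglas–Peucker at 0.75 px
  before summing segment lengths. The simplification removes staircase
  inflation on smooth boundaries (digital disk → ≈ 2πR, circularity
  → 1 with radius) while keeping true corners (digital square side a →
  ≈ 4a, circularity ≈ π/4; a 1×N bar → ≈ 2N + 2). The manual-mode
  round-spheroid criterion (> 0.8) is applied on this estimator.
* **Weighted moment of inertia** — `(Σ w·d²/Σ w) / (A/2π)` with d the
  pixel distance from the weighted centroid: exactly 1 for a uniform disk
  in the continuum (`Σd²/N = R²/2 = A/2π`), monotonically larger with
  elongation (a 1×N bar scores ≈ πN/6), invariant to scaling the weights.
  Well QC computes it on the extracted **core** mask: the spheroid body is
  what a fiber misshapes, and measuring the core keeps the (highly
  variable) chain halo out of the statistic.

## Well exclusion (QC)

Two main rules, applied per plate:

1. wells with zero, two or more detected spheroids are excluded;
2. single-spheroid wells whose core roundness exceeds the **upper
   adjacent value** — the largest observation within `Q3 + 1.5·IQR`
   (linear-interpolation quartiles; the boxplot upper-whisker datum) — of
   the plate's single-spheroid roundness values are excluded as misshapen.

A third rule catches gross segmentation failures: core area below 25 % of
the plate's median single-spheroid core area. The fence population is the
current plate (configurable); recomputing exclusions on the survivors
flags nothing new because the fence is applied once, on the full plate.
The same Tukey fence convention rejects stray single cells in the
manual-mode circle fit.

## Screen statistics

Per plate, compound wells are normalized to fold = migration area / mean
migration area of that plate's non-excluded DMSO control wells (control folds
average exactly 1 per plate). Hits are called per compound from the
replicate-mean fold against cutoffs `control fold mean ± k·SD`, k = 4,
where the SD is taken over *individual* control wells pooled across
plates — the conservative reading when the choice between well-level and
replicate-mean SD is open; both are configurable. A low-cutoff candidate
whose mean dead fraction exceeds 0.5 is classed **toxic** rather than
low-migration (the real triage was a qualitative live/dead evaluation; a
documented quantitative surrogate is required here). Compounds with all
replicates excluded are classed **excluded**.

Dose-response confirmation: per concentration, a Welch two-sample t test
of the compound's replicate folds against the same plates' control folds
at α = 0.05, uncorrected (per-concentration significance reporting); a
Holm-corrected mode is available for screen-wide use. The peak is the
concentration of maximal mean fold, ties resolving to the highest
concentration. No sigmoidal fit is performed — the confirmation question
is which concentration produces the largest migration phenotype, which
the peak rule answers directly.

## Synthetic-microscopy generator

The generator draws everything stochastic about a well first (core area
~ Normal(27,437, 1,073²) μm², truncated positive; halo-cell distances from
a configurable distribution, default Gamma(k = 2, θ = 40 μm); dead labels
i.i.d. with the configured dead fraction; artifact flags), then renders:

* brightfield: bright background (0.80) with a dark (0.35), speckled,
  soft-edged core disk; dark Gaussian-blob cells (radius 6 μm);
  **migration chains** — radial strands rooted at the core boundary at
  stratified angles (default 20), lengths drawn from the migration
  distribution — so the contiguous object grows with migration the way
  collective/chain migration does;
* Hoechst: every nucleus as a bright blob (the core renders as one merged
  bright disk — nuclei inside it are unresolvable), nucleus σ smaller than
  the brightfield cell body;
* PI: exactly the dead subset, slightly wider and brighter than the
  Hoechst nucleus.

Each object has a focal slice; neighbouring slices render it dimmer and
wider, giving the extended-focus projection something real to select.
Gaussian read noise (SD 0.02) is added per channel from an independent
stream, so a brightfield-only render is bitwise-reproducible against the
full three-channel render of the same seed. Artifacts: empty wells (no
spheroid), two spheroids (second, smaller core placed apart), a dark
fiber crossing the core with the core stretched into an equal-area
ellipse (aspect 2.2–2.8) along the fiber axis, and debris — a compact
dark clump placed clear of the spheroid, sized so the spheroid-count rule
must catch it. Per-well
seeds derive from the master seed by a counter-based scheme
(`SeedSequence(master, spawn_key=(well_index,))`, wells in sorted order).

Defaults are the study conditions: 1024×1024 px at 1 μm/px (areas in μm²
equal pixel counts), nine slices at 25 μm, core areas 27,437 ± 1,073 μm²,
150 halo cells. The seeded cell count per well is a free parameter — the
generator renders emigrated cells, not the plated suspension.

The numbers-only screen generator skips images: control wells draw
migration areas around a base area with multiplicative noise
(fold SD 0.08), compound wells around base × planted fold. The validation
-screen configuration plants 24 high compounds (folds uniform in
1.7–3.0×) and 36 viable low compounds (0.17–0.35×) among 1,012 compounds
in triplicate, 16 controls per 96-well plate — separations of ≥ 3.7 control
SDs beyond the ±4-SD cutoffs, so recovery is near-deterministic.

### What the generator does and does not emulate

It reproduces the *geometry and bookkeeping* of the assay — object sizes,
radial migration, stain logic, artifact classes, plate structure — with
exact ground truth, which is what the segmentation, QC and statistics
layers need for validation. It does not model optics (no PSF, no shot
noise), cell morphology beyond Gaussian blobs, halo texture of real
chain migration, or focus drift. Passing tests therefore demonstrate
correctness of the measurement and decision logic under known truth, not
segmentation performance on real microscope images; operator defaults
would need re-tuning on real data.

## Numerical and degenerate-input conventions

* 8-connectivity everywhere; 0-based (row, col) coordinates, origin
  top-left.
* Constant images binarize to all-background; flooded edge maps (> 25 %
  foreground) are treated as featureless.
* An empty segmentation yields `n_spheroids = 0` with empty masks — a QC
  signal, never an exception; `compute_well_metrics` raises only for a
  missing brightfield channel.
* The manual circle fit returns an "insufficient migration" signal
  (`None`) when fewer than six cells survive outlier rejection *or* when
  no circle intersects six cells within ± one cell radius.
* Replicate SD uses the n−1 denominator; a single replicate reports
  SD 0 by documented convention.
* The manual-mode circle area includes the spheroid core (the drawn
  outline encircles everything).

## Problem sizes in the bundled checks

The acceptance script measures 200 default-scale wells for the core-area
calibration (~6–8 min single-threaded) and one full 1,012-compound
triplicate screen (~seconds). Unit and property tests run on reduced
wells (384² px, ~12,000 μm² cores, 50 cells) chosen to preserve the
size relations the operators assume while keeping the suite fast.

## Known limitations

* Halo area is defined by the same closing policy that segments it; it is
  validated against a pixel-count oracle under that policy, not against
  an optics-level ground truth.
* No tracking: migration speed, directionality and persistence are out of
  scope by design.
* The 4-SD caller assumes control folds are roughly Gaussian; heavy-tailed
  control noise would inflate the false-positive rate.
* The upper-adjacent-value fence adapts to each plate; a plate where most
  wells are misshapen will mask its own artifacts.
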