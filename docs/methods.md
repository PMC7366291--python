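# Methods

## The measurement model

Each embryo's pronephros is summarised by ten geometric parameters measured
on a dorsal maximum-projection thumbnail through 16 named reference points,
eight per side: the angle vertex (neck-segment / proximal-convoluted-tubule
junction), a neck-ray point, a tubule-ray point on the medial tubule edge,
the lateral tubule edge, and the four glomerular poles (anterior, posterior,
medial, lateral). The wiring is:

| parameter | definition |
|---|---|
| angleL, angleR | interior angle at the vertex between the neck-ray and tubule-ray directions (degrees, (0, 180]) |
| tubDiamL, tubDiamR | distance tubule-ray → lateral tubule edge |
| tubDist | distance between the two lateral tubule edges |
| glomHeightL/R | anterior → posterior pole distance |
| glomWidthL/R | medial → lateral pole distance |
| glomSep | distance between the two medial glomerular poles |

A 16-point budget forces point reuse (the tubule-ray point doubles as the
medial diameter edge; the lateral edges serve both tubDiam and tubDist; the
medial glomerular poles serve both glomWidth and glomSep); this schema
reproduces all ten parameters from exactly 16 points. Glomerular "height"
is taken as the anterior–posterior extent in the projection plane. Angles
are reported in degrees; lengths in pixels by default (a µm-per-pixel
calibration may be supplied, but it cancels in the control-normalized fold
changes, so the default of 1.0 is harmless). All features are invariant
under rigid motion of the landmark set, equivariant under scaling, and
mirror-symmetric (reflection swaps L/R and fixes tubDist, glomSep); the
test suite asserts these to 1e-9 relative tolerance.

Landmarks enter the pipeline as CSV (`plate, well, embryo, point_name, x,
y`) from any annotation tool; coordinates are 0-based (x = column,
y = row), origin top-left.

## Image pre-processing

Z-stacks are collapsed by per-pixel maximum. The kidney is located as the
unweighted centroid of the foreground mask after thresholding; the default
threshold is Otsu's method (parameter-free and robust on the strongly
bimodal fluorescence histograms), with a fixed-percentile alternative and
an intensity-weighted centroid exposed as options. Thumbnails are 257 × 257
crops centred on the detected ROI, zero-padded at the frame borders —
zero padding preserves the photometric meaning of background, unlike
reflection. A uniform or empty-foreground image raises a "no signal" error
so the well can be recorded as empty rather than silently mis-centred.

## Normalization chain

1. **Outlier exclusion.** Per feature within each treatment group, points
   with |x − mean| > k·SD (k = 2, sample SD) are removed in a single pass.
   The filter's purpose is removal of embryo-level artefacts (damaged,
   misaligned, severely malformed specimens), hence the within-group scope;
   a screen-wide scope is available as an option. Groups smaller than three
   are passed through with a warning flag. On 100,000 standard-normal draws
   the filter removes ≈ 4.55% (2·(1 − Φ(2))), which the suite checks.
2. **Fold change.** Every surviving measurement is divided by the mean of
   the same experimental day's surviving DMSO-control measurements for that
   feature; the per-treatment fold change is the mean of its per-embryo
   fold changes (the ratio-of-means alternative is exposed as an option).
   Controls therefore average to exactly 1 per day and feature. One plate
   is one experimental day, with its own control row (row H).
3. **z-scores.** Per feature, fold changes are standardized across all
   treatments in the screen (sample SD), since the purpose is
   cross-compound comparison; constant columns map to zero with a warning.
4. **Ratios.** Qualitative categories become per-treatment ratios of
   annotated embryos carrying each tag (multi-tagged embryos count toward
   each tag, empty embryos stay in the denominator); gross-morphology
   counts become ratios of the embryos exposed (20 by default).

The assembled record carries 26 scored parameters — 10 fold changes, 10
category ratios, 6 gross ratios (edema mild, edema severe, curved
back/tail, heartbeat alteration, somite malformation, yolk necrosis) — with
mortality and the derived z-scores alongside but not counted among the 26.

**Abnormality flag.** Hit calling in screens of this kind is ultimately an
expert judgement; the package replaces it with an explicit, configurable
rule and does not claim to reproduce any particular expert's calls. The
default: abnormal if the normal-kidney ratio < 0.5, or any abnormality
category ratio ≥ 0.5, or any quantitative |z| ≥ 2. Hit classes are ATC
D-level groups (first five code characters; unassigned compounds form an
"N/A" pool that is never a class) with ≥ 4 members of which ≥ 50% are
flagged.

## Screen-level analysis

PCA uses the SVD of the column-centred z-score matrix without re-scaling
(the features are already variance-standardized); rows with missing
quantitative data are excluded and reported, and component signs are fixed
so each component's largest-magnitude loading is positive. Nearest
neighbours are Euclidean in z-space by default (cosine available), ties
broken by treatment ID. The edema-renal check is a Spearman rank
correlation between the edema ratio (mild + severe) and 1 − normal-kidney
ratio. Heat maps clip the display scale at |z| = 3 (data unclipped in all
exports); parallel-coordinate lines are coloured magenta (0% normal) to
green (100% normal). The HTML report is static and self-contained
(matplotlib SVG plus a small table filter), standing in for a hosted
dashboard.

## The synthetic screen

The generator defines the conditions under which the pipeline is validated:

* **Layout.** 96-well plates, rows A–G one compound each, row H the DMSO
  control, one embryo per well in columns 1..n; 8 embryos per treatment by
  default (assays of this kind image 7–12 per treatment depending on
  lethality); one plate = one day. Wells are empty with probability 0.1.
* **Parameters.** Baseline geometry (pixels/degrees): angles 120°, tubDist
  150, glomHeight 45, glomWidth 40, glomSep 35, tubDiam 18 — sized so the
  kidney fits a 257-px thumbnail at the assay's field of view. Each embryo
  draws `baseline × effect × LogNormal(mean 1, CV)` per parameter, CV 0.1
  by default; the lognormal keeps parameters positive and its σ² = ln(1 +
  CV²), µ = −σ²/2 parametrisation makes the mean exactly the target.
  Bilateral pairs share an embryo-level log-factor (correlation 0.5) plus
  independent side noise, as in a real embryo. Angles are capped at 180°.
* **Effects.** "Strong" compounds (10% by default) shift all ten
  parameters: angles reduced 1.5-fold, each length moved 1.5-fold up or
  down — the multi-feature fingerprint treated compound classes display.
  This also keeps the z-scores meaningful: a feature nobody perturbs would
  reduce to a unit-normal column and the |z| ≥ 2 clause would fire on
  ~4.5% of nulls per feature. Strong compounds are concentrated in three
  planted ATC classes (75% of members) plus a couple of singletons; 15% of
  compounds carry no ATC mapping.
* **Categories.** Annotation is emulated by thresholding the true
  parameters: glomerular-separation and reduced-angle tags at 1.2× / 1.35×
  / 1.5× fold of baseline (most severe tag only), glom_malform when any
  glomerular width/height deviates 1.35-fold either way, normal_kidney when
  nothing fires. The minor cut-off sits near 2 SD of the default biological
  variation — an annotator does not tag ordinary variation as a phenotype.
* **Gross morphology.** Per-treatment binomial counts at fixed per-embryo
  rates (edema mild 8%, severe 2%, curved back/tail 5%, heartbeat subtypes
  2/2/1%, somites 3%, yolk necrosis 2%), independent of the renal effects:
  extrarenal toxicity is modelled as a separate axis, so the edema-renal
  correlation is ≈ 0 by construction.
* **Images.** 16-bit stacks, background 100 counts, structure amplitude
  10,000 (sCMOS-like, without claiming any instrument's calibration); two
  filled glomerular ellipses and two tubule arms drawn from the closed-form
  landmark construction, so morphometry on the ground-truth landmarks
  recovers the generating parameters to floating-point precision. Ten
  slices at 15 µm spacing; the central slice is in focus, others blurred by
  a Gaussian growing 2 px/slice of defocus, plus Poisson shot noise and
  Gaussian read noise (SD 5). The default frame is 2048² (the tests and the
  acceptance script render 400–512 px frames to keep runtimes in seconds;
  the geometry is frame-size independent).
* **Determinism.** Randomness is split hierarchically
  (screen → plate → well) via `numpy.random.SeedSequence`, so identical
  (config, seed) reproduce tables and images bit for bit and one plate can
  be regenerated without consuming another's draws.

What the generator does *not* emulate: photorealistic anatomy, brightfield
content, pancreas signal (recorded only as a boolean annotation),
autofluorescence, mounting variation beyond XY jitter, or annotator error.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the analysis chain under its stated assumptions — not
performance on real micrographs, where landmarks remain manually set.

## Numerical choices and degenerate inputs

Sample SD (ddof = 1) everywhere — material at n = 7–12. Angle computation
uses atan2 of |cross| and dot (stable near 0° and 180°); coincident points
raise a degenerate-geometry error. Fold changes require a positive control
mean and at least one surviving control per day/feature, else a
normalization error naming the day and feature. z-scoring a constant column
warns and returns zeros; a single-row matrix is an error. Results workbooks
are written with pinned timestamps and sorted, fixed-date zip entries so
identical runs are byte-identical. The 2-SD filter recomputes mean/SD once
(single pass), not iteratively.

## Scope and limitations

The per-treatment record reports profiles, not significance tests, and the
design is single-concentration (no dose–response modelling). Automatic
landmark detection on real images is out of scope; the landmark proposer
that exists serves only synthetic data, where the ground truth is known.
The PCA explained variance of the three components on synthetic screens is
data-dependent (typically 50–60% under the default conditions, where ten
partially independent parameters are perturbed jointly) and is reported,
not asserted.
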