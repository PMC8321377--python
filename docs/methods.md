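# Methods

This note records how `skinpost` implements the class-driven postprocessing
pipeline: the model and its assumptions, the parameters that matter, what
the synthetic data does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Tri-level thresholding

The SPM is partitioned by two thresholds (t_low, t_high) maximizing the
three-class between-class variance of its 256-bin histogram — the
multilevel generalization of Otsu's discriminant criterion. The search is
exhaustive over all ordered pairs (vectorized, ~32k candidates), so the
optimum is exact; ties are broken toward the lexicographically smallest
pair, making results platform-independent. *High* pixels (strictly above
t_high by default; the non-strict variant is a flag) are the detected skin.

Degenerate inputs: a constant SPM has no histogram structure, so all pixels
go to a single set — *low* for constant 0, *high* otherwise — with a logged
warning. For a constant value of 1 the stored t_low is −1, the only way the
"value ≤ t_low" labeling rule can express an empty low set at the bottom of
the intensity range.

A practical consequence of always-on discriminant thresholding: any noisy
no-skin SPM still produces a nonempty high set (Otsu always finds a split),
so the class-H route (component count 0) is reached only by genuinely flat
maps. This mirrors what happens when the method runs behind a real detector
and is why class H's postprocessor is a no-op rather than a mask reset
(configurable via `empty_mask_for_no_skin`).

## Features and the decision tree

Five scalars drive classification: SR (skin fraction), CC (region count),
BSR (skin fraction of the top/left/right 1-pixel border — the bottom row is
excluded because subjects typically exit the frame there; corners are
counted once, giving w + 2(h−1) border pixels), SR2 (largest region ÷ skin
pixels; 0 for an empty mask so the tree stays total), and LRR (largest
region ÷ image pixels, measured after single-pixel regions are removed).
Labeling connectivity defaults to 8, matching the MATLAB labeling functions
the morphological operator set originates from; it is configurable
throughout.

The tree itself is implemented exactly as specified by its pseudocode, with
three documented resolutions where the pseudocode underdetermines behavior:

* **Border test.** The learned border threshold is TB1 = 1 while BSR ≤ 1 by
  construction, so a strict "BSR > TB1" could never fire and class G
  (background bleed) would be dead code. The test is therefore non-strict
  (BSR ≥ TB1), which matches G's meaning — a border fully labeled as skin.
  The strict reading remains available (`border_inclusive=False`).
* **Low-skin branch.** "CC < 4 → B; CC < 6 → D; else F" is an
  if/elif/else chain: sequential independent ifs would overwrite B with D
  for every small CC, collapsing two classes that are defined as distinct.
* **Unrouted skin ratios.** TS2 = TS3 = 0.1685 leaves SR exactly 0.1685 in
  neither the high- nor the low-skin branch; such an image keeps the
  initial label H. This is documented, not "fixed": the learned thresholds
  are taken as given.

Interval membership ([TL1, TL2], [TR1, TR2], …) is inclusive at both ends.

With LRR defined as area/(h·w), the learned interval [3.5e−6, 86.3e−6]
cannot contain the LRR of any image that also satisfies SR > 0.1685 with
CC = 1 (a single region then has LRR ≈ SR). The CC = 1 route to class I is
therefore unreachable at the default thresholds; class I remains reachable
through the CC = 2 and CC = 3 dominant-ratio routes, which is also how the
synthetic I-scenario is built. The LRR denominator may plausibly have been
meant on another scale; the implementation keeps the dimensionless
area/(h·w) reading and does not silently rescale.

### Threshold tuner

The procedure that originally produced TS1…TR8 is not documented anywhere,
so `tune_thresholds` is this package's own facility: a greedy
coordinate-wise grid search initialized at the default thresholds, sweeping
thresholds in declaration order and accepting a candidate only on a strict
improvement of pooled F1 over the training pairs, repeated until a full
pass changes nothing. It is deterministic given its inputs and is validated
on synthetic data only; it makes no claim to reproduce the original
ECU-trained values.

## Morphological sequences

The five operators are standard binary morphology (scipy.ndimage /
scikit-image) with a discrete Euclidean disk {(dr, dc) : dr² + dc² ≤ r²} as
structuring element — chosen over MATLAB's decomposed 'disk' approximation
for cross-platform determinism. Out-of-image pixels count as background for
both erosion and dilation. The multiplication operand is always the
pre-refinement Otsu mask: multiplying after dilation clips regrowth back to
originally detected pixels, which is the only reading under which the
sequence is meaningful.

The disk radii and the area-opening floor P are printed nowhere, only that
Set#1 and Set#2 differ in structuring-element size. The package's
calibration:

* `disk_radius_set1 = 3` (near scenes, large regions),
* `disk_radius_set2 = 2` (far scenes — Set#2 serves classes D and F, whose
  skin regions are small; a larger disk would erode away exactly the
  regions the sequence is supposed to refine),
* `disk_radius_set3 = 3` (border-frame removal; a typical bleed frame a few
  pixels wide, touching the image edge, erodes to nothing at this radius),
* `area_open_P = 50`: the opening runs *after* erosion, so it is a speck
  scale for fragments the erosion left, not a region-size prior. A genuine
  far-scene region of radius ~10 px keeps well over 50 px after Set#2's
  erosion, while leftover noise fragments do not. (The 300-px floor used by
  the homogeneity refinement is a different quantity — a pre-check region
  floor on unthresholded candidates — and reusing it here would delete true
  far-group regions wholesale.)

All four values are configuration, not constants.

## Homogeneity refinement

The refinement thresholds the normalized SPM at T (initially 0.2, skin iff
value > T strictly), removes regions under 300 px, and accepts the mask iff
every surviving region satisfies

    σ < 45  AND  (Ne/Nd ≤ 3.5  OR  Ne/Ns ≤ 0.02)

else multiplies T by 1.1 ("increased by 10%" read multiplicatively) and
repeats. Geometric growth of T guarantees termination: once T ≥ 1 no pixel
passes and acceptance is vacuous on the empty mask. Masks shrink
monotonically across iterations (the threshold only rises, and a surviving
region's parent at the previous threshold was at least as large).

Numerical choices:

* σ is the population standard deviation of the SPM values (8-bit scale) at
  the region's pixels. The 45 cutoff only makes sense against 8-bit
  intensities; the SPM is this pipeline's only per-pixel signal, though an
  auxiliary grayscale image can be substituted by calling `region_stats`
  directly.
* Ne counts region pixels whose Sobel gradient magnitude (computed on the
  normalized SPM, rescaled by 255) exceeds 128. No cutoff is prescribed
  anywhere; 128 flags pixels whose 3×3 window substantially crosses a
  strong mask edge (a full step of ≈0.86 in normalized units registers
  ≈220) while a corner-only contact (≈78) and interior noise do not, so Ne
  approximates the one-pixel digital perimeter. That calibration makes the
  two ratio tests read naturally: Ne/Nd ≈ perimeter/diameter ≈ π for a
  disk and 4 for a square — the 3.5 constant admits compact round regions —
  and Ne/Ns ≈ perimeter/area accepts any sufficiently large region.
  Empirically a digital disk of radius 40–100 px under mild noise measures
  Ne/Nd ≈ 2.1.
* Edge pixels are counted *inside* the region (not on a surrounding ring):
  the Sobel response of a boundary sits on the inner pixels of the step.
* Operator precedence is σ AND (ratio OR ratio), the typeset grouping; the
  alternative ((σ AND ratio) OR ratio) is a flag for sensitivity analysis.
* The refinement always re-thresholds the SPM itself rather than reusing
  the Otsu mask: the procedure is defined by its own threshold schedule,
  and T's growth is what lets an inhomogeneous region shed its
  low-confidence fringe.

## Evaluation

F1 is computed from pooled pixel counts; `pooled_f1` is invariant to how
pixels are split into images (only the sums matter), which is the point of
pixel-level averaging — per-image macro-averaging is available separately
(`macro_f1`) for comparison. The degenerate all-negative case (tp = fp =
fn = 0) scores 1.0 by convention, logged. Report tables carry full
precision with 3-decimal display rounding.

The signed-rank comparison drops zero differences and, for n ≤ 25, computes
the exact p-value by enumerating the 2ⁿ sign assignments (implemented as a
dynamic program over ranks doubled to stay integral, which also handles
tied magnitudes exactly — the reason this is hand-built rather than
delegated to `scipy.stats.wilcoxon`, whose exact path rejects ties; scipy
is the cross-check oracle in the tests). Beyond n = 25 the normal
approximation with tie correction applies.

## Synthetic scenarios

The generator emulates the *geometry* the pipeline consumes, not the
photographs: non-overlapping elliptical blobs (rejection-sampled with a
spacing margin, whole-layout restarts if an early blob blocks placement) at
a high foreground score (default 230) on a low background (default 10) with
clipped Gaussian noise (default σ = 5), plus two detector-artifact options
written into the SPM only — a high-score border frame (the class-G
situation) and isolated high-score speckle pixels. Defaults place the
foreground/background modes far apart relative to the noise, emulating a
confident detector; the suite's skin fractions (≈0.05–0.35) keep the
background the majority class so the discriminant threshold lands between
the modes.

`class_suite` returns one scenario per class plus two speckled variants.
Dominant-region scenarios (I, K, L) differ from their A/C/E counterparts
only by making one blob's area dominate so SR2 falls inside the learned
intervals — targeting is by construction of areas, then verified by running
the classifier, never by editing features. Speckle variants attach to
classes E and F only, because salt pixels inflate CC and those are the
classes whose CC branch tolerates it; that sensitivity is a property of the
decision tree itself, not of the generator. The H scenario is the flat
zero map (see the thresholding section for why noisy no-skin maps cannot
reach H).

What passing on this data does *not* show: robustness to soft or
miscalibrated probability maps (real CNN scores hug neither 10 nor 230),
to ground-truth noise, to skin-like background texture, or to the
person-shaped (non-elliptical) regions of real imagery. The suite validates
the pipeline's logic and the direction of its benefit, not benchmark-level
performance.

Problem sizes used by the default test run and the acceptance script:
256×256 to 320×320 images, a 13-scenario suite, 10,000 random feature
vectors for the tree-equivalence check, 200 random 40×40 SPMs for the
refinement property checks, and brute-force morphology oracles on 16×16
masks — sizes at which the exhaustive oracles are exact yet the whole suite
runs in seconds.

## Known limitations

* The learned thresholds are consumed as given; the tuner cannot re-derive
  them without the original training data.
* The CC = 1 route to class I is unreachable at the default thresholds
  (LRR scale, above).
* Morphological radii and the area-opening floor are this package's
  calibration, not learned values.
* The exact signed-rank test is exact only in its p-value; with heavy ties
  the two-sided doubling convention can differ from other software's
  conventions.
* The pipeline never sees the RGB image; refinements relying on color or
  texture are out of scope by design.
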