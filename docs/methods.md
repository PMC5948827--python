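# Methods

## Model and assumptions

A crop-field RGB image is assumed to contain two color populations:
background soil (hue roughly 20–60°) and green vegetation (hue roughly
60–180°), of which at least the dominant one is approximately Gaussian
in hue. Hue is taken from the standard HSV decomposition computed on
channels normalised to [0, 1]: H from the chroma branches (achromatic
pixels, C = 0, are pinned to H = 0 and therefore always count as
non-vegetation — documented behaviour, not an error), S = C/M, V = M.
Hue is kept in degrees [0, 360) as floating point and binned at 1°
because every threshold this method produces is naturally expressed in
integer degrees; hue is treated linearly without wraparound, which is
safe because both classes live well inside [0°, 180°].

The segmentation threshold is sought just past the border of the
dominant population, walking from its center toward the other class:
upward in hue when soil dominates, downward when vegetation dominates.
The 60° yellow/green boundary classifies the dominant centroid (the
boundary itself is assigned to vegetation, since green starts at 60°);
it is a classifier for the *dominant mode only*, never a per-pixel rule.

## Histogram filtering

Bins holding strictly less than `filter_fraction` (default 1e-5, i.e.
0.001 %) of the image's pixels are removed from the bin sequence — not
zeroed — so the valley/peak walks operate on consecutive *surviving*
bins. The strict-inequality boundary is protected against float
representation error in `fraction × total` by a 1e-9 relative epsilon.
The default fraction is deliberately tiny (≈ a few pixels on small
frames, ~100 on a 10 MP frame); it is configurable for users who want a
stronger outlier filter (e.g. 1e-3).

## Gaussian fitting

The model is y(x) = Σ aᵢ exp(−((x−bᵢ)/cᵢ)²) with at most two terms,
fitted by Levenberg–Marquardt least squares. The exponent carries no
factor ½, so c = √2·σ; every confidence interval uses σ = c/√2. A
config switch (`halved_exponent`) selects the conventional ½ form for
users who prefer c = σ.

Initialisation is data-driven: b₁ at the highest-count bin, b₂ at the
highest-count bin at least 30° away (when one exists), amplitudes from
the corresponding counts, widths 10°; up to `n_restarts` (5) jittered
restarts drawn from a generator seeded by `Config.seed` keep runs
bit-reproducible.

Peak-count selection: the two-term solution is kept only when

* it is substantially better than the one-term fit — SSE at most
  `two_term_sse_ratio` (0.5) of the one-term SSE — and
* the secondary component is plausible: amplitude ≥ 5 % of the
  dominant one, centroid inside [0°, 360°), width ≤ 120°.

The amplitude/plausibility screen alone cannot catch the degenerate
case where a two-term optimiser splits one true Gaussian into two
overlapping halves of similar amplitude; the SSE comparison is this
package's resolution of that ambiguity, and both cutoffs are exposed in
`Config`. If the optimiser fails outright even after restarts, the fit
is marked non-converged, the peak count falls back to raw-histogram
peak picking (local maxima ≥ 5 % of the global maximum, ≥ 30° apart)
and the dominant center falls back to the main-hue bin; th₁/th₂ are
then absent.

## Candidate thresholds

* **th₁** — mean_dominant ± k·σ with k the largest of {3, 2, 1}
  satisfying k·σ < S2 strictly; the sign follows the search direction.
  S2 is measured from the dominant centroid to the last surviving
  histogram bin on the side *opposite* the search (the fitted curve has
  no finite end, so the histogram support end stands in for it; a
  config switch uses mean ± 3c of the fit instead). Each multiple is
  evaluated independently — the largest admissible k wins even when a
  larger one was rejected. No admissible k ⇒ absent.
* **th₂** — only when two components exist and the non-dominant
  centroid lies in the search direction (the gate is label-free so
  relabeling the two components cannot change the outcome): the
  minimum of the fitted curve on the closed inter-centroid interval,
  located by a 0.1° grid scan plus bounded local refinement (xatol
  1e-6).
* **th₃/th₄/th₅** — walks over surviving bins starting at the
  main-hue bin (configurable to the fitted centroid) in the search
  direction. A valley/peak is a bin strictly below/above both
  neighbours in the surviving sequence; equal-count runs are compared
  as a unit and contribute their first bin in walk order. th₃ stops at
  every valley lower than the following valley; th₄ at every valley
  followed by two successive strictly-rising bins (counted from the end
  of the valley's run); th₅, for every peak lower than the following
  peak, at the lower of its two flanking valleys (the earlier one on a
  tie; peaks missing either flanking valley are skipped). All
  qualifying stops are enumerated — not just the first — then filtered
  to the 30–70° admissibility window and averaged. The window applies
  to the local-minima detectors only; `bounds_on_all_candidates`
  extends it to th₁/th₂.

The final threshold is the unweighted mean of the detected candidates.
If none is detected the run raises a detection failure (or falls back
to Otsu on hue when `fallback_otsu` is set). Binarization keeps the
threshold-equal pixel with the dominant side (strict inequality toward
the non-dominant class) and caps vegetation at `veg_hue_max` (180°), so
magenta/red hues never count as vegetation.

## Baselines

Color indices are evaluated on chromatic coordinates r = R/(R+G+B) etc.
(the dominant convention for the ExG family; `chromatic_coords=False`
switches to raw channels), except CIVE, whose additive constant
18.78745 presumes raw 8-bit channels. ExR uses coefficient 1.3
(configurable; some literature uses 1.4). COM1 is implemented as the
plain unweighted sum ExG + CIVE + ExGR + VEG. NGRDI = (G−R)/(G+R) and
VEG = g/(r^0.667·b^0.333) follow their standard external definitions
(VEG's denominator is ε-guarded). Division-by-zero cases are guarded:
NDI and NGRDI return their symmetry value on black pixels.

Otsu's threshold is computed on the image quantized to 256 levels over
its finite range (360 levels for hue), maximizing between-class
variance with ties resolved to the lowest level; a constant image is a
degenerate error. Vegetation lies on the high-index side except for
CIVE and ExR, whose polarity is inverted.

## Evaluation

The headline measure is overall pixel agreement in percent, the
standard for threshold-method comparisons; it is class-imbalance
sensitive, so IoU, precision and recall of the vegetation class ride
along as supplementary columns. Summaries report per-method mean and
sample standard deviation (ddof = 1; population std by flag — a single
record then reports NaN vs 0 respectively).

## Synthetic scenes

The generator emulates the hue structure the method assumes — not
photorealistic fields. Defaults: soil hue N(40°, 8°), vegetation hue
N(110°, 12°), S ∈ [0.3, 0.9], V ∈ [0.3, 0.95], a soil peak left of 60°
and canopy mass inside 60–180°. The vegetation support is drawn as
rows (spacing 32 px), smoothed-noise patches, or scattered plants, by
ranking a layout field and taking exactly round(f·N) pixels, so the
truth mask is exact by construction and the target fraction is met to
integer rounding. Sampled hues are clipped (not wrapped) at [0°, 360°):
class means sit far from the boundary, so clipping bias is negligible.
The illumination gradient dims V linearly across the width (amplitude
1 halves V at the right edge, floor 0.05) at fixed hue, so two scenes
differing only in gradient share an identical truth mask. An
`irrigated_preset` pushes soil hue to N(70°, 10°) to reproduce the
wet-soil regime where the soil mode crosses the 60° boundary and hue
separation collapses — a deliberate stress case.

What passing tests on these scenes show: correct mechanics of the
detectors, threshold placement between well-separated hue modes, and
insensitivity to pure-brightness variation. What they do not show:
behaviour under mixed pixels at low ground resolution, shadows,
specularities, non-Gaussian soil color, or annotation noise — real
ground truth is hand-made and imperfect, synthetic truth is exact.

## Problem sizes and numerical choices

Acceptance-style checks run on 512×512 scenes (5 growth stages),
256×256 for illumination and degenerate checks; unit tests use 96–256
px scenes and 50–100 seeded random histograms per oracle comparison —
sizes chosen so the whole suite runs in seconds while leaving the
statistics far from their tolerance margins. All randomness flows
through `numpy.random.default_rng` seeded from `FieldSpec.seed` /
`Config.seed`; growth-series members derive child seeds
deterministically from the base seed, so every artifact is
bit-reproducible.

## Known limitations

* Achromatic and near-achromatic pixels carry unstable hue; the method
  relies on the small-presence filter to drop them and performs poorly
  on heavily desaturated imagery.
* One global threshold per image, as designed; scenes with spatially
  varying soil color would need per-region treatment that is
  explicitly out of scope.
* When the soil hue population crosses 60° (irrigated preset), the
  dominant-class rule can misclassify the dominant class and the
  threshold degrades — inherent to the 60° green-boundary assumption.
* Hue is treated linearly; imagery whose classes straddle 0°/360°
  (not the case for soil/vegetation) would break the walk logic.
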