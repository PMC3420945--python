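# Methods

This note documents the models, estimators and numerical choices behind
`poletrack`, in the order data flows through the pipeline.

## Synthetic movie model (`poletrack.scenes`)

Each cell is a spherocylinder (rectangle capped by half-disks) of length
4 µm and width 0.7 µm at 0.1 µm/px (40 × 7 px), rendered as a uniform
cytoplasmic ("diffuse") intensity plus two Gaussian spots representing the
polar protein clusters, blurred by an isotropic Gaussian PSF of σ = 1.5 px —
the diffraction-limited appearance of a widefield system at this
magnification — then offset by a constant camera bias, degraded by Poisson
shot noise and Gaussian read noise, and quantized to 16-bit with clipping
(the clipped fraction is logged in the run manifest).

Motion is along the body axis at constant speed (default 2 µm/min, a
typical adventurous-gliding speed); a reversal is an instantaneous sign
flip of the velocity. Sub-frame reversal kinetics are not modelled: at 30 s
sampling a pause of ~30 s is unresolvable, so point events are the
appropriate idealization. Reversal times come either from a fixed schedule
shared by all cells or from a memoryless (Poisson) process with a
configurable mean interval (default 8 min, giving ≈2.5 reversals per 20-min
movie). Cells are laid out in disjoint horizontal lanes and never collide
or divide; trajectories are validated to stay at least one cell length
inside the image, and a configuration whose trajectory cannot fit raises an
error naming the offending cell.

Fluorescence polarity: the bright cluster (default peak amplitude 6000 au
over a 300 au cytoplasm) sits at the leading pole; the opposite pole
carries a dim cluster (default 1800 au) or none, depending on the cell's
localization pattern (`pattern_mix` draws diffuse / unipolar /
bipolar-symmetric / bipolar-asymmetric cells in given fractions). After
each reversal the bright cluster relocates to the new leading pole with a
per-cell lag of `switch_lag_frames` frames (an integer, or a set to draw
from per cell); the relocation is instantaneous at the switch frame, where
the new pole's intensity is maximal, followed by a slow linear decay
(5 %/frame, floored at 40 %) applied to both poles so that the scored
"maximum fluorescence at the new leading pole" is a well-defined, noise-
robust extremum and symmetric cells stay symmetric. Spots are compact
(σ = 1.0 px) and centred 1.5 px inside the pole tip, i.e. within the cell
body at the pole cap.

The amplitude ratio of 6000:1800 (≈3.3) was chosen so that, after the
measurement chain compresses contrast (band-averaging across the cell
width plus the ~250 au cytoplasmic base in every segment), asymmetric
cells yield measured terminal-segment ratios of ~1.7–2.0, clearly across
the 1.5 symmetric/asymmetric cutoff, while the dim cluster still clears
the cluster-call threshold by ≥5 robust SD. The camera offset (100
counts) keeps background pixels clear of the zero-clipping boundary so
read noise stays symmetric. The paper trail for all of these is synthetic:
no quantitative fluorescence levels exist to match, so they are free
parameters fixed once as plausible imaging conditions.

What the generator does **not** emulate: optics beyond a Gaussian PSF
(no aberrations, no depth dependence), cell growth/division, curvature and
flexing of cells, cell–cell contact and group motility, photobleaching,
and focus drift. Consequently, passing recovery tests on these movies
demonstrates the correctness of the measurement chain under its stated
model, not robustness to every artefact of real acquisitions.

Determinism: one `numpy` generator seeded from the scene seed drives all
draws in a fixed order; identical configurations produce bit-identical
movies and truth tables.

## Segmentation and the axial coordinate (`poletrack.quant`)

Cell boundaries are defined by one global intensity threshold per frame.
The default rule ("halfmax") iterates `thr ← (median(image) +
median(image > thr))/2` from a noise-floor start: for a PSF-blurred binary
footprint the half-maximum contour is the true boundary, and the iteration
is insensitive both to how many cells the frame contains and to how bright
their polar clusters are. Otsu's method is available but is documented to
fail in two regimes here: with very few cells the foreground class is too
small and the threshold collapses into the background noise; with bright
polar foci the intensity histogram is trimodal and Otsu splits cytoplasm
from clusters instead of background from cells. An absolute level can be
supplied instead of either rule.

The centerline is the longest geodesic path through the skeleton of the
mask (ties broken lexicographically by endpoint coordinates), extended to
the boundary along the end tangents; tips are ordered lexicographically so
extraction is deterministic. The profile value at each centerline point is
the mean background-subtracted intensity of the mask pixels nearest that
point (a band average across the cell width — more noise-robust than a
single-pixel line sample), floored at zero; the background is the median
intensity outside all cell masks in the frame.

The profile's arc domain is trimmed by 2 px (≈1 PSF σ) at each end before
splicing. Rationale: a threshold mask overshoots the true cell tip by the
blur halo, and the overshoot grows with polar cluster brightness, so the
untrimmed terminal coordinate tracks the halo rather than the pole and
pushes cluster mass out of the terminal segment.

Splicing treats the profile as piecewise-constant on midpoint cells and
integrates it over 15 equal arc-length segments, so samples straddling a
segment boundary contribute fractionally and the integrated intensity is
conserved exactly (property-tested to 1e-6 relative). With σ_PSF = 1.5 px
and segments of ~2.9 px, a pole cluster's measured mass inherently spans
up to two segments; cluster calls on realistic scenes are therefore
confined to the outermost two segments per pole rather than strictly the
terminal one, and the classification rules read only the terminal flags,
which remain correct.

Cluster calls use a single global threshold for the whole dataset.
Besides absolute values and pooled quantiles, the default rule
("robust:5") sets the threshold at the pooled segment-value median plus
5 robust SDs (1.4826·MAD): it anchors on the cell-body level, so it does
not depend on what fraction of cells carry clusters — a pooled Otsu split
does, and lands between the dim and bright cluster modes when asymmetric
cells are present.

Classification: no terminal cluster → diffuse; exactly one of segments
{1, 15} → unipolar; both → bipolar, split symmetric/asymmetric by the
brighter:dimmer terminal intensity ratio against `sym_cutoff` (default
1.5; the underlying biology is depicted qualitatively, so the cutoff is a
reporting convention, not a fitted constant).

## Tracking and reversal scoring (`poletrack.tracking`)

Linking is greedy nearest-neighbour: candidate (track, detection) pairs
within `max_step` px per elapsed frame are sorted by (distance, track id,
position) and assigned first-come; gaps up to `max_gap` frames are
bridged. This is deliberately simple — the synthetic scenes (and the
intended use case, isolated cells) have inter-cell distances much larger
than per-frame displacements, so multi-hypothesis tracking would add
nothing testable.

Two distance statistics are computed over the first full 10-min window of
each track: the cumulated path length and the net start-to-end
displacement. The source description of this measurement is ambiguous
between the two readings ("sum of the traveled distance" vs "net distance
… back and forth movements are not accounted for"), so both are always
reported; `net_displacement_px` is the headline column.

Reversals: each inter-frame displacement is projected on the cell's axis
unit vector (sign-aligned across frames for continuity); intervals with
|projection| < `min_move` (default 1 px/frame — centroid jitter at 30 s
sampling must not flip the sign) neither establish nor change direction.
The direction is established at the first supra-threshold interval, and a
reversal is scored at the first frame whose displacement opposes it. On
ground truth where velocity flips at frame r, the first opposite
displacement is observed at frame r+1, so scored times sit one frame after
truth — within the ±1-frame tolerance used throughout, which is the
temporal resolution the 30 s sampling supports. A track with no supra-
threshold interval is flagged non-motile rather than scored.

## Pole intensities, switching, and Rxy (`poletrack.dynamics`)

Pole intensity is the mean background-subtracted intensity in a disk of
radius `r_pole` (default half the cell width) clipped to the mask. The
disk is re-centred on the brightest pixel within `r_pole` of the nominal
pole point; this removes the sub-pixel asymmetry of tip placement between
the two poles (without it, symmetric cells show a systematic ~8 % pole
imbalance from discretization alone). Pole identity (physical end A/B) is
propagated by nearest-tip continuity across frames; the initial
leading/lagging labels come from the first supra-threshold movement.

Switching is scored per reversal: the new leading pole alternates starting
from the initial lagging pole, and the switch frame is the argmax of that
pole's intensity within the inter-reversal interval beginning at the
scored reversal (ties take the first frame and are flagged low-confidence).

Rxy: both event series are binarized on the frame grid (duplicate events
collapse). The implemented statistic is

    Rxy(m) = Σ_overlap (x_t − x̄)(y_{t+m} − ȳ) / (n σx σy)

with full-series means, population SDs and length n, no zero-padding. The
published form of this statistic could not be transcribed, so the
implementation is a declared stand-in pinned to its two known calibration
properties: Rxy = 1 exactly for identical non-constant series at m = 0
(guaranteed arithmetically by evaluating numerator and denominator through
the same n-normalized expressions), and |Rxy(m)| ≤ 1 at every delay (by
Cauchy–Schwarz, because the overlap sum is bounded by the full-series
norms). Normalizing by the overlap length instead — the other natural
choice — violates the second property for event pairs near the series
edge (e.g. 39/36 at n = 40, |m| = 4) and was rejected; the cost is an
attenuation of at most |m|/n (≤10 % over the 0–2-frame analysis window on
40-frame movies). The normalization lives in one function
(`cross_correlation`) so a different convention can be substituted in one
place. Constant series yield an undefined (NaN-flagged) curve, never 0.

Delay sign convention: positive m means the fluorescence switch follows
the reversal, so the 0–1 min coupling window is delays 0–2 frames at 30 s
sampling. Per-cell curves (cells with at least one reversal and one
switch) are averaged on a common delay grid — per-cell-then-average, with
a pooled mode deliberately left out of scope — and the aggregate is called
significant when the mean exceeds 0.4 anywhere in that window.

Because the generator relocates the cluster instantaneously and the
scoring rules lock both event times to the same frame, the aggregate Rxy
of a correlated synthetic population is typically ≈1 at zero delay; real
acquisitions, with gradual relocation and scoring noise, sit lower, which
is why the significance readout is a threshold (0.4), not an equality.

## Pipeline and validation (`poletrack.pipeline`)

`run_pipeline` chains simulate → segment → profile/classify → track →
dynamics → Rxy, writing every intermediate table as CSV with unit-suffixed
columns, a JSON manifest (version, seed, configuration, collected
warnings, clipping fraction) and a text summary. Snapshot quantification
(histogram, patterns) uses frame 0, one snapshot per cell. Reruns with the
same configuration and seed reproduce all outputs bit-identically;
per-stage timings go to the log only, so they cannot break
reproducibility. Warnings (ties, clipping, skipped short tracks,
non-motile cells) are accumulated into the manifest rather than silently
dropped.

`validate_against_truth` matches tracks to ground-truth cells by
first-frame centroid and reports reversal precision/recall at ±1-frame
tolerance, the switch-time error distribution, the localization-pattern
confusion table, and the terminal-bin error of the occurrence histogram.

## Problem sizes

The shipped analyses and tests use 30-cell, 40-frame movies (the
correlation study), a 100-cell snapshot (the histogram study), and 200-cell
truth-only draws for rate checks; these sizes give per-cell event counts
(~2.5 reversals) and population denominators (n = 30, n = 100) matching the
study design they emulate, and keep a full pipeline run under a minute on
one core.

## Known limitations

- Curved or flexing cells are outside the centerline model's design range
  (near-straight rods); the skeleton path remains correct but the
  cross-section band average degrades with curvature.
- Touching cells are not separated (no watershed); the generator never
  produces them, and on real data they would be dropped by area limits.
- The Rxy stand-in is one member of the family of normalized
  cross-correlations consistent with the stated calibration properties;
  absolute values at large delays are attenuated by design.
- Switching scoring assumes alternating leading poles between scored
  reversals; a missed reversal shifts the role assignment for the rest of
  the cell's record (visible as precision/recall in validation, not
  silently wrong).
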