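# Methods

## The measurement

`vesselperm` quantifies the wall permeability of microvessels grown and
perfused on a microfluidic chip. A fluorescent macromolecular tracer
(70 kDa RITC-dextran) is flowed into the self-assembled vascular network
and the chamber is imaged in widefield fluorescence every 10 s for up to
10 min. For a branch-free ("cylindrical") vessel segment of radius *r*,
the permeability coefficient is

    P = (1/ΔI) · (dI/dt) · (r/2)

where ΔI is the initial intensity increase of the segment's measurement
window when the dye front fills the lumen, and dI/dt is the subsequent
slow rise of the window mean as tracer crosses the vessel wall. With *r*
in µm and time in s, P is in µm/s (outputs also carry cm/s). The r/2
factor is the volume-to-surface ratio of a cylinder: for a thin-walled
tube, conservation of tracer gives d(C_out)/dt ∝ P·(2/r)·C_in, and
intensity is proportional to local tracer concentration in this regime.

The evaluation hierarchy follows the assay: five to seven segments are
evaluated per chip, chips average their segments, and each sample
(patient) averages its two to six chips. Group comparisons then run on
chip- or sample-level values: matched samples with the Wilcoxon
signed-rank test, everything else with Mann-Whitney; parametric t tests
and one-way ANOVA with the Newman-Keuls post hoc procedure are provided
for the companion readouts.

## Measurement-window convention

The window of a segment is its lumen plus a perivascular shell
(default 25 µm wide). ΔI is the window's fill step and dI/dt the
subsequent window slope ("total-window" convention). This is the
convention under which the r/2 factor of the formula is exact: the dye
that leaves the lumen accumulates in the shell, so the *window total*
grows at the transmural flux rate while the fill step normalizes for
lumen brightness and fractional window occupancy. An
extravascular-only window would measure the same flux against a
different normalizer and is deliberately not silently interchangeable;
the window construction is explicit in `VesselSegment.window_mask`.

Because both ΔI and dI/dt are window means over the *same* pixel set,
their ratio — and hence P — is invariant to the exact window size as
long as the window contains the lumen and the leak band. It is likewise
invariant to global intensity scaling (camera gain) and offset.

## Phantom model

The synthetic generator produces ground-truthed stacks that emulate the
chip protocol: a circular chamber of diameter 2.4 mm, frames every 10 s
for 10 min (61 frames), straight cylindrical segments with radii drawn
from a configurable range (default 10–30 µm), simultaneous dye arrival
(default 60 s), and additive Gaussian camera noise. Dye transport is
the analytic inverse of the estimator:

- lumen pixels ramp linearly from background to background + plateau
  over `fill_rise_s` (default 5 s — convective filling is fast relative
  to the frame interval) starting at the arrival time;
- after filling, tracer is deposited in a thin perivascular band
  (default 10 µm) at the constant total rate
  `P_true · (2/r) · plateau · n_lumen_px` per second, which makes the
  mean of any window containing lumen + band rise with slope
  `P_true · ΔI_window · 2/r` exactly;
- optional global mono-exponential bleaching and Gaussian halo blur of
  the leak field; both default off so the window trace stays piecewise
  exact (flat baseline → linear ramp of height ΔI → linear leak).

The generator refuses configurations whose leaked intensity would
exceed the 16-bit camera ceiling. Geometry placement is rejection
sampling with capsule-distance separation `r_i + r_j + 2·shell`, so all
measurement windows are disjoint by construction; an over-dense request
fails with an explicit error. Everything is deterministic given the
config seed (separate substreams for geometry and noise).

What the phantom does **not** emulate: branching and curved vessels
(the formula is defined per cylindrical segment, so branching adds no
testable content), pressure-driven flow and washout of leaked dye,
Poisson shot noise (camera-offset-dominated widefield imaging is
approximately Gaussian; heavier tails can be emulated through
`noise_sd`), uneven illumination, focus drift, and transit-time
differences between segments (per-segment arrival offsets exist but
default to 0). Passing recovery tests therefore demonstrates
correctness of the estimation chain, not robustness to every real-world
artifact.

The microscope's pixel size is not part of the recorded protocol; the
package default is 2 µm/px, a low-magnification widefield objective
with binning that resolves the full 2.4 mm chamber.

## Segmentation

The perfused lumen is thresholded (Otsu) on the median of reference
frames chosen just after dye arrival — `choose_reference_frames` picks
the frame after the largest jump of the global mean-intensity trace,
because at high permeability the perivascular band brightens within a
frame or two and would otherwise be absorbed into the lumen mask. Two
guards reject degenerate inputs: a blank or noise-only image (threshold
separation below 4 background SDs) and a flooded field (foreground over
half the chamber). Small objects (< 64 px) are removed with
4-connectivity labelling, which also prevents percolating noise from
forming one giant pseudo-object.

The mask skeleton is cut at branch points and each surviving branch
becomes a candidate segment. Junctions are detected by the crossing
number (runs of occupied neighbours around the 8-neighbourhood ring)
rather than the raw neighbour count, which would misclassify sharp
corners. Short leaf branches attached to junctions (length on the order
of the local radius) are pruned as skeletonization artifacts before
splitting. Branches shorter than `min_segment_length_um` (default
100 µm — slope estimation needs a window dominated by one cylinder) are
dropped. Retention is capped (default 7, longest first, mirroring the
assay's five-to-seven) and overlapping windows are resolved by keeping
the longer segment. The original assay's operators chose segments by
eye; this automated selection is a stand-in for that step.

**Radius.** The radius is the median Euclidean distance transform along
the branch centerline, sampled on the local 3×3 EDT ridge (the skeleton
can sit half a pixel off the true axis), minus half a pixel. The EDT
measures to the nearest *background pixel center* and overshoots the
true wall by 0–1 px depending on tube orientation (≈0 for generic
angles, 1 for lattice-aligned); the half-pixel correction centers that
error, bounding the bias by half a pixel across orientations. At the
default 2 µm/px and r = 20 µm this contributes at most ±5% to P.

Pixel coordinates are 0-based (row, col); masks are boolean grids over
the full frame.

## Trace analysis

- **Baseline**: mean of the first 3 frames (configurable).
- **Arrival**: first frame whose window mean exceeds
  baseline + 5·SD(baseline frames) *and stays above it for the rest of
  the recording*. The sustained-crossing requirement exists because the
  3-frame noise estimate has only 2 degrees of freedom and occasionally
  collapses toward zero; a transient noise excursion then crosses the
  threshold, whereas dye that has filled a lumen does not leave. A
  transient spike is reported as "no perfusion".
- **Plateau (fill complete)**: first frame after arrival whose
  frame-to-frame increment, in excess of a robust tail-slope estimate
  (median of the later increments), falls below 10% of the largest
  excess increment. Measuring increments in excess of the tail slope
  keeps the rule valid at high permeability, where the leak slope per
  frame can itself exceed 10% of the fill step; with a flat tail it
  reduces to the plain fraction-of-maximum rule.
- **dI/dt**: ordinary least-squares slope of window mean vs time over
  the frames strictly after plateau + 2 settle frames (avoiding fill
  transient contamination); R² of the fit is reported. Optional bleach
  correction divides the trace by a mono-exponential fitted to a
  vessel-free background region.
- **ΔI**: mean of the first 3 frames after the plateau with the fitted
  leak slope removed, minus baseline. The slope removal extrapolates
  the post-plateau linear fit back to the midpoint between the last
  pre-arrival frame and the arrival frame — the leak is zero there, so
  ΔI reflects the fill step only. Anchoring at the plateau instead
  would include the leak accumulated between fill completion and
  plateau detection, biasing ΔI high (and P low by over 15% at
  P = 0.25 µm/s with 10 s frames); the arrival-midpoint anchor is
  unbiased whenever filling completes within about one frame interval,
  which the protocol's fast convective filling satisfies. This is the
  one place the estimator assumes a fast fill; slow-filling vessels
  (fill time ≫ frame interval) would need a different anchor.
- **P**: `slope/ΔI · r/2`. Segments with ΔI ≤ 0 are excluded and
  logged; negative P estimates (possible on zero-leak data under noise)
  are *retained* and flagged, not clipped, so group statistics stay
  unbiased.

Aggregation uses arithmetic means at both levels (unbiased under
additive noise; a median variant is available via `method="median"`).
Chips with fewer than 3 analyzable segments are flagged `low_n`.

## Statistics

All tests are two-sided; significance is conventionally assessed at
p < 0.05. Matched samples are compared with the Wilcoxon signed-rank
test and independent groups with Mann-Whitney (`compare_groups`
applies this rule automatically from the pairing column).

- **Student's t**: classical pooled-variance unpaired t by default
  (Welch behind a flag), paired t on aligned differences. Zero-variance
  degenerate inputs give p = 1 by convention, flagged.
- **Wilcoxon signed-rank**: zero differences dropped (count reported),
  average ranks for ties. Exact two-sided p by enumeration of all 2^n
  sign assignments for n ≤ 12; above that, a tie-corrected normal
  approximation with continuity correction. The two-sided exact p is
  the doubled smaller tail, capped at 1.
- **Mann-Whitney**: U₁ with half-credit ties; exact enumeration over
  all C(n₁+n₂, n₁) labelings for n₁+n₂ ≤ 14, tie-corrected continuity-
  corrected normal approximation above. The thresholds keep exact
  enumeration sub-second; the mode used is recorded on every result.
- **ANOVA + Newman-Keuls**: one-way ANOVA (identical groups give F = 0,
  p = 1 by convention); then the stepwise studentized-range procedure
  on ordered means, widest span first, with critical values from
  `scipy.stats.studentized_range` (arbitrary error dfs, no hard-coded
  tables) and the harmonic standard error for unequal n. Stepwise
  closure is enforced structurally: every pair inside a non-significant
  span is declared non-significant without being tested.

No multiple-testing correction beyond Newman-Keuls is applied,
matching the assay's analysis plan.

## Companion quantifications

- `mean_region_intensity`: arithmetic mean over an axis-aligned square
  region, default 1.5 mm × 1.5 mm, for on-chip immunofluorescence.
- `geometric_mfi`: exp(mean(ln x)) over events with positive intensity;
  non-positive events are excluded (FlowJo-compatible, not
  offset-shifted) and counted.
- `relative_expression`: 2^−ΔΔCT with the arithmetic mean of exactly 3
  reference-gene Cts per sample (equivalent to the geometric mean of
  their linear quantities — the standard multi-reference convention);
  replicates averaged first; the calibrator sample's RQ is identically
  1. Primer efficiency is assumed 100% (factor 2); an
  efficiency-corrected base is available but off by default. Samples
  missing a reference Ct yield null RQs with a logged reason.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use compact fields
that preserve the protocol's optics and timing while keeping a full
recovery study cheap: single-segment recovery phantoms run in a 600 µm
field at 2 µm/px, and six-segment chip phantoms in a 1600 µm field at
4 µm/px (the full 2.4 mm chamber at 2 µm/px works identically and is
the library default; it is simply more pixels). Recovery is assessed at
P_true ∈ {0.01, 0.05, 0.25} µm/s with r = 20 µm, 61 frames, noise of
1% of the lumen fill step, 20 seeded phantoms per level; the
chip-design study uses 8 "normal" chips at 0.05 µm/s vs 13 "tumor"
chips at 0.15 µm/s, 6 segments per chip, 20 repetitions.

## Known limitations

- The fill-time assumption behind the ΔI anchor (above).
- Radius estimation degrades below ~3 px of radius; choose the pixel
  size so the thinnest vessel of interest spans several pixels.
- Leaked dye is assumed to stay near its segment; strong perivascular
  flow or very long recordings with overlapping halos would violate
  window disjointness.
- Bleach correction requires a vessel-free background region supplied
  by the caller; it is not discovered automatically.
- The Newman-Keuls procedure does not control the familywise error
  rate in all configurations (a known property of the procedure); it
  is provided because it is the assay's stated post hoc method.
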