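# Methods

This note documents the models, defaults, and numerical choices behind
`isquant`, and what the synthetic-data validation does and does not show
about real microscopy.

## Coordinate and calibration conventions

Pixel coordinates are 0-based `(row, col)` with row 0 at the image top.
Spatial calibration (`pixel_size`, µm/px) and temporal calibration
(`frame_interval`, s) are mandatory on every `TimeLapseStack`; any
operation that would report a µm- or s-scaled quantity raises rather than
assuming defaults.  Stacks are stored as multi-page TIFF with a JSON
sidecar carrying calibration and channel names; integer and float32
round trips are lossless.

## Speckle-flow velocimetry

**Model.**  A fluorescent speckle advected by actin retrograde flow at
speed *v* crosses a sampling line and appears in the kymograph (distance
× time image along that line) as a tilted ridge with slope
*b = v · Δt / s* px/frame, where *s* is the pixel size and Δt the frame
interval.  The measurement chain is: temporal-sum projection (to expose
wakes and place lines) → kymograph with bilinear interpolation, averaged
over the line's perpendicular width band (default 3 px) → Otsu threshold
of the kymograph → connected-component labelling of above-threshold
pixels → ordinary least squares of distance on time per component (time
is the error-free axis) → calibration to µm/s.  Per cell, the mean of up
to 16 accepted fits (nominally from 4 sections) is reported, together
with the SD across fits.

**Sign convention.**  A fitted slope is positive for motion along the
line direction (start → end).  Reversing a line negates every slope; the
per-cell aggregate uses speeds (|v|), so the reported centripetal speed
is invariant to line orientation.

**Quality gate.**  The thresholding step admits both speckle ridges and
noise clusters, so accepted components must look like single, long-lived
ridges: time span ≥ 50% of the movie, ≥ 5 points with ≥ 1.5 points per
spanned frame, and residual RMS about the fitted line ≤ 2 px (fits with
RMS ≤ 4 px are tolerated when r² ≥ 0.8; above 4 px they are always
rejected).  RMS rather than r² is the primary straightness criterion for
two reasons: a perfectly straight ridge from a *stationary* speckle
explains no distance variance and has r² = 0 by construction, and two
parallel ridges merged by a noise bridge can reach r² > 0.8 with a
strongly biased slope.  All gate parameters are keyword arguments of
`measure_cell_flow`.

**Cross-check.**  An independent route to velocity
(`isquant.tracking`) detects spots per frame by thresholding + connected
components and links them by nearest-centroid matching; on noise-free
movies the two routes agree to well under 1%.

## d-SMAC ring morphometry

The ring is segmented on a median-filtered image (square window; the
default side of 20 px matches full-size spread T cells at ~0.1–0.2
µm/px — for structures thinner than the kernel a smaller window must be
chosen, since a median filter erases features narrower than about half
its side).  After Otsu thresholding the largest foreground component is
the ring; its filled outer contour is the external border, the largest
enclosed background hole the internal border.  Contours are traced at
the 0.5 level (sub-pixel, via marching squares).

**Radial width** is the mean over 360 one-degree angular bins of
(external radius − internal radius) about the external-border centroid;
bins missing either border are excluded, and negative widths in more
than 10% of bins indicate crossing borders and raise an error.  Fine
binning keeps the discretization bias below ~0.1 px on circular
phantoms.

**Width transfer.**  When only the external border is resolvable, the
internal border is constructed by a uniform inward radial offset of a
reference width (e.g. measured on well-formed wild-type cells): the
Euclidean distance transform of the filled footprint is thresholded at
`reference_width + 0.5` px.  The half-pixel term aligns the EDT depth
scale (outermost foreground pixel has depth 1) with the 0.5-level
contour convention used when the width was measured; without it the
transferred annulus is systematically one pixel thin.  This uniform
offset — rather than morphological erosion with a structuring element —
is the closest reading of "shrink so that the mean radial difference
equals the reference".

**Density ratio.**  MFI per area is total intensity over pixel count
(or µm² when calibrated).  "Outside" defaults to everything in the
analysis region off the annulus (interior disc plus exterior); the
`outside_region` flag restricts it to either side, since which
complement a given study intends is ambiguous.

## Manders colocalization

M1 is the fraction of channel-1 intensity on pixels where channel 2
exceeds its threshold, computed over an analysis domain that excludes
the supplied nuclear mask; M2 is symmetric.  Default thresholds are 0
(any positive signal); explicit per-channel values can be supplied.  The
median pre-filter is the same square-window filter as the ring routine
(default 3 px here).  The coefficients are invariant to rescaling a
channel when its threshold is rescaled with it, and swapping the
channels swaps M1 and M2 — both properties are tested exactly.

## Synapse metrics

* **Marker area / fluorescence**: on the maximum-intensity projection of
  the z-stack (3-D reconstruction is deliberately replaced by a
  projection), the area is the count of above-threshold pixels within
  the IS region × pixel_size², fluorescence the sum over those pixels.
  Otsu within the region is the default threshold.
* **Coalescence score**: published coalescence percentages derive from
  manual scoring of confocal sections, whose quantitative rule cannot be
  recovered; the computational surrogate is declared as such.  The IS
  radius is the equivalent-circle radius of the region; the *central
  fraction* is marker fluorescence inside the central disc (radius =
  `central_disc_fraction` × IS radius, default 0.5) over fluorescence in
  the whole region; `concentrated` means central fraction ≥ 0.5.  A
  uniform marker scores ≈ 0.25 (area ratio), a tight central cluster
  ≈ 1, so the default decision threshold sits between the two modes.
  Both knobs are configuration, and the surrogate is calibrated only on
  synthetic cohorts.
* **Clearance kinetics**: central and peripheral MFI-per-area series are
  extracted per frame from disjoint masks.  `biphasic_kinetics` reports
  time-to-peak (argmax, optional moving-average smoothing),
  peak-fold-induction over the first sample, and the decay rate from a
  log-linear fit over post-peak samples that remain above 10% of the
  peak — samples that have decayed into the detection floor would
  otherwise flatten the rate.  Monotone non-increasing series are
  flagged and fit over the full series.

## Synthetic generators: what they emulate, what they omit

All generators take explicit seeds and are bit-deterministic.

* **Speckle movies** place Gaussian spots (σ default 1.5 px) evaluated
  analytically at pixel centers — no nearest-pixel snapping, so the
  ground-truth drift is exact — and translate them uniformly along −x
  (optionally centripetally toward a stated center) by
  `v·Δt/pixel_size` px/frame.  Order of effects: render, photobleach
  scaling `exp(−rate·t)`, then noise (Gaussian read noise or Poisson
  shot noise).  Defaults: 128² field, 0.16 µm/px, 0.5 s/frame (inside
  the sub-second acquisition regime of TIRF speckle imaging), 30
  speckles, peak 200 AU on a 10 AU background.  The speckle density and
  SNR of real acquisitions are not published for this regime; the
  defaults (sparse spots; validation at SNR 5, defined as spot peak /
  noise σ) are package assumptions, documented here, not literature
  values.
* **Annulus phantoms** assign constant mean intensities to ring,
  interior, and exterior by exact center-to-center distance, plus
  Gaussian noise; true masks ride along as ground truth.
* **Two-channel overlap pairs** construct channel-2 support by mask
  splitting with a fractional balance pixel, so the expected M1 equals
  the requested overlap fraction to machine precision on noise-free
  output — no sampling error.
* **Clearance series** render a central disc decaying exponentially
  (complete clearance, floor 0 by default) and a peripheral annulus with
  a saturating rise; an optional linear rise phase before the central
  decay emulates the initial burst of F-actin accumulation that precedes
  clearance, giving the kinetics analysis a genuine peak to find.
  Defaults (40 frames at 15 s) match minutes-long confocal time lapses.

Not modeled: 3-D point-spread optics, speckle appearance/disappearance
from exchange with the monomer pool, spatially varying flow fields,
cell-shape irregularity, camera gain/offset structure.  Passing recovery
tests therefore demonstrates correctness of the measurement chain, not
robustness to every property of real data; on real movies the dominant
unmodeled effects are heterogeneous flow and speckle turnover, which
shorten usable ridges (the gate's persistence requirement is the knob to
relax).

## Validation problem sizes

The recovery studies use 128² px movies of 100 frames at SNR 5 (16 wake
fits per condition), annuli of widths 5/10/20 px on 128² images,
50-cell-per-arm coalescence cohorts, and 40-frame clearance series —
sizes at which every stage's recovery is stable across seeds while the
full validation completes in seconds.  The demo (`isquant demo`) runs
the same battery end to end and writes a recovery report comparing every
estimate with its generator parameter.
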