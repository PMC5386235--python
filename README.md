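# isquant

Quantification of actin dynamics and signaling-marker organization at the
immune synapse (IS), from calibrated fluorescence-microscopy stacks.

When a T cell engages an antigen-presenting cell, its cytoskeleton
organizes the contact into concentric supramolecular activation clusters:
a central c-SMAC where signaling molecules such as PKC-θ coalesce, and a
lamellipodium-like distal d-SMAC — a ring of F-actin whose centripetal
retrograde flow transports signaling microclusters inward.  `isquant`
implements the image-analysis procedures used to measure this biology:

* **Speckle-flow velocimetry** (`isquant.velocimetry`) — sparse
  fluorescent actin speckles in TIRF movies leave tilted streaks in a
  kymograph (intensity along a line vs time).  The retrograde-flow speed
  is the slope of each streak: the kymograph is thresholded (Otsu by
  default), each connected ridge is fit by ordinary least squares of
  distance *d* on time *t*, and `v = b · pixel_size / frame_interval`
  (µm/s) where `b` is the slope in px/frame.  Per cell, the mean of 16
  wake fits from 4 sections is reported.
* **d-SMAC ring morphometry** (`isquant.ring`) — median filter (20×20 px
  kernel) + thresholding identifies the F-actin-rich ring; its mean radial
  width is the angular average of (external − internal) radius about the
  ring centroid.  For images whose inner border is not resolvable the
  external border is shrunk inward by a reference width (distance-transform
  offset).  Fluorescence density is reported as MFI per area inside vs
  outside the ring, and as their ratio.
* **Manders colocalization** (`isquant.coloc`) — M1 = Σ₁(ch1 where
  ch2 > T₂) / Σ(ch1), and symmetrically M2, with nuclear-region exclusion
  and median pre-filtering.
* **Synapse metrics** (`isquant.metrics`) — marker area/fluorescence at
  the contact, a c-SMAC coalescence score (fraction of marker fluorescence
  inside a central disc), organelle-to-IS distance, two-marker contact
  area, central/peripheral MFI-per-area time series, and biphasic
  (burst-then-decay) kinetics characterization.
* **Synthetic microscopy** (`isquant.synthetic`) — generators for speckle
  movies, annulus phantoms, controlled-overlap channel pairs, and
  clearance time series, each with exact ground truth, so every stage is
  validated by parameter recovery without external data.

## Worked example

```python
from isquant.synthetic import SpeckleMovieParams, simulate_speckle_movie
from isquant.velocimetry import measure_cell_flow
from isquant.cli import default_flow_lines

params = SpeckleMovieParams(flow_velocity=0.10, n_frames=100,
                            noise_model="gaussian", noise_sigma=40.0, seed=1)
stack, truth = simulate_speckle_movie(params)          # 128x128 px, SNR 5
cell = measure_cell_flow(stack, default_flow_lines(stack))
print(f"true 0.100 um/s, recovered {cell.mean_velocity:.4f} "
      f"+/- {cell.sd:.4f} um/s from {len(cell.measurements)} wake fits")
```

prints

```
true 0.100 um/s, recovered 0.1006 +/- 0.0010 um/s from 16 wake fits
```

i.e. the wake pipeline recovers the simulated retrograde-flow speed to
0.6% from sixteen independent ridge fits, with the spread across fits as
the per-cell SD.  The same movie can be analyzed from the shell:

```bash
isquant simulate --kind speckle --velocity 0.10 --seed 1 --out demo/
isquant demo --seed 1 --out demo_report/        # full end-to-end recovery report
```

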