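"""Synthetic fluorescence-microscopy generators with known ground truth.

Every downstream stage of the package (speckle velocimetry, ring
morphometry, colocalization, clearance kinetics) can be validated by
parameter recovery on images produced here.  Each generator returns its
artifact together with a :class:`GroundTruth` record of the parameters and
derived quantities (sub-pixel trajectories, true masks, true curves) that
the corresponding analysis is expected to recover.

Rendering model
---------------
Speckles are isotropic Gaussian spots evaluated analytically at pixel
centers — there is no nearest-pixel snapping, so the ground-truth drift is
exact.  Per frame, the operations are applied in physical order: render
(already PSF-shaped), scale by photobleaching ``exp(-rate * t)``, then add
detection noise (Gaussian read noise or Poisson shot noise).

All generators take an explicit integer ``seed``; identical parameters and
seed give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .io import TimeLapseStack, RegionMask

__all__ = [
    "GroundTruth",
    "SpeckleMovieParams",
    "RingImageParams",
    "simulate_speckle_movie",
    "simulate_ring_image",
    "simulate_two_channel",
    "simulate_clearance_series",
]


@dataclass(frozen=True)
class GroundTruth:
    """Immutable record of generator parameters and derived true values.

    ``params`` maps parameter names to the values used for generation;
    ``derived`` holds arrays the analyses should recover (trajectories,
    masks, intensity curves).  Only ``params`` and ``seed`` are serialized.
    """

    params: dict
    seed: int
    derived: dict = field(default_factory=dict, repr=False, compare=False)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"seed": self.seed, "params": _jsonable(self.params)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Speckle movies
# ---------------------------------------------------------------------------

NoiseModel = Literal["none", "gaussian", "poisson"]


@dataclass(frozen=True)
class SpeckleMovieParams:
    """Parameters of a simulated speckle time-lapse.

    ``flow_velocity`` is in µm/s; the default drift direction is uniform
    translation along −x (decreasing column), matching a line profile drawn
    from the cell edge toward the center.  Setting ``radial_center``
    switches to centripetal flow converging on that ``(row, col)`` point.

    ``frame_interval`` defaults inside the acquisition regime used for
    TIRF speckle imaging of lamellipodial actin (fractions of a second per
    frame); ``pixel_size`` defaults to a 100x-objective scale.
    """

    n_speckles: int = 30
    flow_velocity: float = 0.10  # µm/s
    pixel_size: float = 0.16  # µm/px
    frame_interval: float = 0.5  # s
    n_frames: int = 100
    psf_sigma: float = 1.5  # px
    speckle_intensity: float = 200.0  # AU (peak, pre-noise)
    background: float = 10.0  # AU
    noise_model: NoiseModel = "none"
    noise_sigma: float = 0.0  # AU, for gaussian noise
    photobleach_rate: float = 0.0  # 1/s
    field_size: tuple[int, int] = (128, 128)  # (rows, cols) px
    radial_center: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.photobleach_rate < 0:
            raise ValueError("photobleach_rate must be >= 0")
        if self.n_speckles < 1:
            raise ValueError("n_speckles must be >= 1")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def px_per_frame(self) -> float:
        """True drift per frame in pixels."""
        return self.flow_velocity * self.frame_interval / self.pixel_size


def _render_spots(shape, positions, amplitudes, sigma):
    """Render Gaussian spots evaluated analytically at pixel centers."""
    img = np.zeros(shape, dtype=np.float64)
    rows = np.arange(shape[0], dtype=np.float64)
    cols = np.arange(shape[1], dtype=np.float64)
    # Restrict each spot to a +/- 5 sigma window for speed; the tails beyond
    # are < 1e-5 of the amplitude.
    half = max(1, int(np.ceil(5.0 * sigma)))
    for (r0, c0), amp in zip(positions, amplitudes):
        rlo = max(0, int(np.floor(r0)) - half)
        rhi = min(shape[0], int(np.ceil(r0)) + half + 1)
        clo = max(0, int(np.floor(c0)) - half)
        chi = min(shape[1], int(np.ceil(c0)) + half + 1)
        if rlo >= rhi or clo >= chi:
            continue
        gr = np.exp(-((rows[rlo:rhi] - r0) ** 2) / (2.0 * sigma**2))
        gc = np.exp(-((cols[clo:chi] - c0) ** 2) / (2.0 * sigma**2))
        img[rlo:rhi, clo:chi] += amp * np.outer(gr, gc)
    return img


def _apply_noise(frame, model: NoiseModel, sigma: float, rng: np.random.Generator):
    if model == "none":
        return frame
    if model == "gaussian":
        out = frame + rng.normal(0.0, sigma, size=frame.shape)
        return np.clip(out, 0.0, None)
    # Poisson: pixel values are treated as expected photon counts.
    return rng.poisson(np.clip(frame, 0.0, None)).astype(np.float64)


def simulate_speckle_movie(
    params: SpeckleMovieParams,
) -> tuple[TimeLapseStack, GroundTruth]:
    """Simulate a TIRF-like movie of speckles drifting at a known velocity.

    Speckles are placed uniformly at t=0 (with a margin so spots stay
    measurable) and drift by ``flow_velocity * frame_interval / pixel_size``
    pixels per frame, along −x by default or toward ``radial_center`` in
    centripetal mode.  The ground truth records every sub-pixel trajectory.

    Raises
    ------
    ValueError
        If the per-frame displacement exceeds ``field_size / n_frames``
        (speckles would cross the field faster than it can be sampled —
        an unmeasurable configuration).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_rows, n_cols = p.field_size
    d = p.px_per_frame
    if abs(d) > min(n_rows, n_cols) / p.n_frames:
        raise ValueError(
            f"per-frame displacement {d:.3f} px exceeds field_size/n_frames; "
            "unmeasurable configuration"
        )

    margin = 3.0 * p.psf_sigma
    total_drift = abs(d) * (p.n_frames - 1)
    # Start positions chosen so the full trajectory stays in-field (-x drift).
    r0 = rng.uniform(margin, n_rows - margin, size=p.n_speckles)
    if p.radial_center is None:
        lo = margin + (total_drift if d > 0 else 0.0)
        hi = n_cols - margin - (total_drift if d < 0 else 0.0)
        if lo >= hi:
            raise ValueError("field too small for the requested trajectory length")
        c0 = rng.uniform(lo, hi, size=p.n_speckles)
    else:
        c0 = rng.uniform(margin, n_cols - margin, size=p.n_speckles)

    # trajectories[t, i] = (row, col) of speckle i at frame t.
    traj = np.empty((p.n_frames, p.n_speckles, 2), dtype=np.float64)
    if p.radial_center is None:
        for t in range(p.n_frames):
            traj[t, :, 0] = r0
            traj[t, :, 1] = c0 - d * t  # -x drift: columns decrease
    else:
        cr, cc = p.radial_center
        vec = np.stack([cr - r0, cc - c0], axis=1)
        dist = np.linalg.norm(vec, axis=1)
        unit = vec / np.where(dist > 0, dist, 1.0)[:, None]
        for t in range(p.n_frames):
            step = np.minimum(d * t, dist)  # stop at the center
            traj[t, :, 0] = r0 + unit[:, 0] * step
            traj[t, :, 1] = c0 + unit[:, 1] * step

    frames = np.empty((p.n_frames, n_rows, n_cols), dtype=np.float64)
    for t in range(p.n_frames):
        bleach = np.exp(-p.photobleach_rate * t * p.frame_interval)
        amps = np.full(p.n_speckles, p.speckle_intensity * bleach)
        img = _render_spots((n_rows, n_cols), traj[t], amps, p.psf_sigma)
        img += p.background * bleach
        frames[t] = _apply_noise(img, p.noise_model, p.noise_sigma, rng)

    stack = TimeLapseStack(frames, ("speckle",), p.pixel_size, p.frame_interval)
    gt = GroundTruth(
        params=asdict(p),
        seed=p.seed,
        derived={"trajectories": traj, "px_per_frame": d},
    )
    return stack, gt


# ---------------------------------------------------------------------------
# Annulus (d-SMAC-like ring) images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingImageParams:
    """Parameters of a bright-annulus phantom on a dimmer background.

    Emulates a confocal section of a cell with an F-actin-rich
    lamellipodium-like ring: mean intensity ``ring_mfi`` on the annulus
    between ``inner_radius`` and ``outer_radius``, ``interior_mfi`` on the
    enclosed disc, ``exterior_mfi`` outside.
    """

    outer_radius: float = 50.0
    inner_radius: float = 40.0
    center: tuple[float, float] | None = None  # default: image center
    ring_mfi: float = 200.0
    interior_mfi: float = 100.0
    exterior_mfi: float = 100.0
    noise_sigma: float = 0.0
    image_size: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValueError("need 0 < inner_radius < outer_radius")
        if min(self.ring_mfi, self.interior_mfi, self.exterior_mfi) < 0:
            raise ValueError("MFIs must be >= 0")

    @property
    def center_rc(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)


def simulate_ring_image(params: RingImageParams) -> tuple[np.ndarray, GroundTruth]:
    """Render an annulus phantom; ground truth carries the true masks.

    A pixel belongs to the annulus when its center-to-center distance lies
    in ``[inner_radius, outer_radius]``.  Rejects configurations whose
    annulus comes within 5 px of the image edge.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_rows, n_cols = p.image_size
    cr, cc = p.center_rc
    edge_clearance = min(cr, cc, n_rows - 1 - cr, n_cols - 1 - cc)
    if p.outer_radius > edge_clearance - 5:
        raise ValueError("annulus must keep a >= 5 px margin to the image edge")

    rr, cols = np.ogrid[:n_rows, :n_cols]
    dist = np.hypot(rr - cr, cols - cc)
    annulus = (dist >= p.inner_radius) & (dist <= p.outer_radius)
    interior = dist < p.inner_radius
    exterior = dist > p.outer_radius

    img = np.where(annulus, p.ring_mfi, np.where(interior, p.interior_mfi, p.exterior_mfi))
    img = img.astype(np.float64)
    if p.noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, p.noise_sigma, img.shape), 0.0, None)

    gt = GroundTruth(
        params=asdict(p),
        seed=p.seed,
        derived={
            "annulus_mask": annulus,
            "interior_mask": interior,
            "exterior_mask": exterior,
            "radial_width": p.outer_radius - p.inner_radius,
            "center": (cr, cc),
            "true_ratio_vs_exterior": (
                p.ring_mfi / p.exterior_mfi if p.exterior_mfi > 0 else np.inf
            ),
        },
    )
    return img, gt


# ---------------------------------------------------------------------------
# Two-channel images with controlled fractional overlap
# ---------------------------------------------------------------------------

def simulate_two_channel(
    overlap_fraction: float,
    *,
    image_size: tuple[int, int] = (64, 64),
    ch1_intensity: float = 100.0,
    ch2_intensity: float = 80.0,
    n_support: int = 400,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Construct a two-channel pair whose Manders M1 is exact by design.

    Channel 1 occupies ``n_support`` scattered pixels.  The channel-2
    support is chosen by *mask splitting* so that it covers exactly
    ``overlap_fraction`` of channel 1's total intensity: most ch1 pixels
    share a unit intensity and one balance pixel takes the fractional
    remainder, so no sampling error enters.  On noise-free output,
    M1 == overlap_fraction to machine precision.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = image_size
    n_px = n_rows * n_cols
    if 2 * n_support > n_px:
        raise ValueError("n_support too large for image_size")

    flat_idx = rng.choice(n_px, size=2 * n_support, replace=False)
    ch1_idx = flat_idx[:n_support]
    extra_idx = flat_idx[n_support:]  # ch2-only support, disjoint from ch1

    f = float(overlap_fraction)
    ch1 = np.zeros(n_px, dtype=np.float64)
    weights = np.ones(n_support, dtype=np.float64)
    covered = np.zeros(n_support, dtype=bool)
    if f == 1.0:
        covered[:] = True
    elif f > 0.0:
        # The first n-1 support pixels are unit pixels; the last is a
        # balance pixel of weight w.  Covering c units plus the balance
        # pixel gives (c + w) / (n - 1 + w) == f exactly, with
        # 0 <= w < f/(1-f) guaranteed by c = floor(f*(n-1)).
        n = n_support
        c = int(np.floor(f * (n - 1)))
        w = (f * (n - 1) - c) / (1.0 - f)
        covered[:c] = True
        weights[n - 1] = w
        covered[n - 1] = w > 0
    ch1[ch1_idx] = weights * ch1_intensity
    ch1 = ch1.reshape(image_size)

    if f == 1.0:
        ch2_support = ch1_idx  # shared support exactly
    else:
        ch2_support = np.concatenate([ch1_idx[covered], extra_idx])
    ch2 = np.zeros(n_px, dtype=np.float64)
    ch2[ch2_support] = ch2_intensity
    ch2 = ch2.reshape(image_size)

    # M2 on noise-free output: ch2 is constant over its support, so it is
    # the fraction of ch2 support pixels lying on ch1 support.
    if f == 1.0:
        true_m2 = 1.0
    elif len(ch2_support) == 0:
        true_m2 = 0.0
    else:
        true_m2 = float(covered.sum()) / len(ch2_support)

    if noise_sigma > 0:
        ch1 = np.clip(ch1 + rng.normal(0, noise_sigma, ch1.shape), 0, None)
        ch2 = np.clip(ch2 + rng.normal(0, noise_sigma, ch2.shape), 0, None)

    gt = GroundTruth(
        params={
            "overlap_fraction": f,
            "image_size": list(image_size),
            "ch1_intensity": ch1_intensity,
            "ch2_intensity": ch2_intensity,
            "n_support": n_support,
            "noise_sigma": noise_sigma,
        },
        seed=seed,
        derived={"true_m1": f, "true_m2": float(true_m2)},
    )
    return ch1, ch2, gt


# ---------------------------------------------------------------------------
# Central clearance / peripheral accumulation time series
# ---------------------------------------------------------------------------

def simulate_clearance_series(
    central_decay_rate: float,
    peripheral_rise_rate: float,
    *,
    is_radius: float = 40.0,
    central_fraction: float = 0.5,
    central_initial: float = 200.0,
    central_floor: float = 0.0,
    peripheral_initial: float = 50.0,
    peripheral_plateau: float = 200.0,
    central_rise_time: float = 0.0,
    central_start: float | None = None,
    n_frames: int = 40,
    frame_interval: float = 15.0,
    pixel_size: float = 0.2,
    image_size: tuple[int, int] = (128, 128),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[TimeLapseStack, GroundTruth]:
    """Simulate F-actin clearance at the synapse center with ring buildup.

    The central disc (radius ``central_fraction * is_radius``) decays as
    ``floor + (initial - floor) * exp(-k t)``; the peripheral annulus rises
    as ``initial + (plateau - initial) * (1 - exp(-r t))`` — the canonical
    picture of central F-actin clearance with d-SMAC accumulation.  With
    ``central_rise_time > 0`` the central curve first ramps linearly from
    ``central_start`` (default half of ``central_initial``) up to
    ``central_initial`` over that time, emulating the initial burst of
    F-actin accumulation before clearance sets in; the exponential decay
    then starts from the peak.  The ground truth stores both ideal curves
    and the region masks.
    """
    if central_decay_rate < 0 or peripheral_rise_rate < 0:
        raise ValueError("rates must be >= 0")
    if central_rise_time < 0:
        raise ValueError("central_rise_time must be >= 0")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = image_size
    cr, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    rr, cols = np.ogrid[:n_rows, :n_cols]
    dist = np.hypot(rr - cr, cols - cc)
    central = dist <= central_fraction * is_radius
    peripheral = (dist > central_fraction * is_radius) & (dist <= is_radius)

    t = np.arange(n_frames) * frame_interval
    decay = central_floor + (central_initial - central_floor) * np.exp(
        -central_decay_rate * np.maximum(t - central_rise_time, 0.0)
    )
    if central_rise_time > 0:
        start = central_initial / 2.0 if central_start is None else central_start
        ramp = start + (central_initial - start) * (t / central_rise_time)
        central_curve = np.where(t < central_rise_time, ramp, decay)
    else:
        central_curve = decay
    peripheral_curve = peripheral_initial + (
        peripheral_plateau - peripheral_initial
    ) * (1.0 - np.exp(-peripheral_rise_rate * t))

    frames = np.zeros((n_frames, n_rows, n_cols), dtype=np.float64)
    for k in range(n_frames):
        frame = np.zeros((n_rows, n_cols))
        frame[central] = central_curve[k]
        frame[peripheral] = peripheral_curve[k]
        if noise_sigma > 0:
            frame = np.clip(frame + rng.normal(0, noise_sigma, frame.shape), 0, None)
        frames[k] = frame

    stack = TimeLapseStack(frames, ("lifeact",), pixel_size, frame_interval)
    gt = GroundTruth(
        params={
            "central_decay_rate": central_decay_rate,
            "peripheral_rise_rate": peripheral_rise_rate,
            "is_radius": is_radius,
            "central_fraction": central_fraction,
            "central_rise_time": central_rise_time,
            "n_frames": n_frames,
            "frame_interval": frame_interval,
            "noise_sigma": noise_sigma,
        },
        seed=seed,
        derived={
            "times": t,
            "central_curve": central_curve,
            "peripheral_curve": peripheral_curve,
            "central_mask": central,
            "peripheral_mask": peripheral,
        },
    )
    return stack, gt
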