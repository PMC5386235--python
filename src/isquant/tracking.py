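"""Independent centroid-tracking velocimetry cross-check.

This is a deliberately simple, brute-force alternative route to flow
velocity that shares no code with the kymograph/wake pipeline: spots are
detected per frame by thresholding + connected components, linked across
frames by nearest-centroid matching, and the velocity is the mean frame-to-
frame displacement of the linked tracks.  It exists to cross-validate the
wake pipeline on clean data, not to be a production tracker.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io import TimeLapseStack

__all__ = ["track_centroids", "tracking_velocity"]


def _frame_centroids(frame: np.ndarray, threshold: float) -> np.ndarray:
    binary = frame > threshold
    labels, n = ndimage.label(binary)
    if n == 0:
        return np.empty((0, 2))
    return np.array(ndimage.center_of_mass(frame, labels, range(1, n + 1)))


def track_centroids(
    stack: TimeLapseStack,
    channel: str | int = 0,
    *,
    threshold: float | None = None,
    max_link_distance: float = 5.0,
) -> list[np.ndarray]:
    """Nearest-centroid tracks through the movie.

    Each track is an ``(n_frames_linked, 3)`` array of ``(t, row, col)``.
    ``threshold`` defaults to halfway between the frame minimum and
    maximum of the first frame; tracks are extended greedily to the nearest
    next-frame centroid within ``max_link_distance`` px.
    """
    data = stack.channel(channel)
    if threshold is None:
        f0 = data[0]
        threshold = float(f0.min()) + 0.5 * float(f0.max() - f0.min())
    per_frame = [_frame_centroids(f, threshold) for f in data]

    tracks: list[list[tuple[int, float, float]]] = [
        [(0, r, c)] for r, c in per_frame[0]
    ]
    open_tracks = list(range(len(tracks)))
    for t in range(1, len(per_frame)):
        cents = per_frame[t]
        used = np.zeros(len(cents), dtype=bool)
        still_open = []
        for ti in open_tracks:
            _, r, c = tracks[ti][-1]
            if len(cents) == 0:
                continue
            dist = np.hypot(cents[:, 0] - r, cents[:, 1] - c)
            dist[used] = np.inf
            j = int(np.argmin(dist))
            if dist[j] <= max_link_distance:
                used[j] = True
                tracks[ti].append((t, cents[j, 0], cents[j, 1]))
                still_open.append(ti)
        open_tracks = still_open
    return [np.array(tr) for tr in tracks]


def tracking_velocity(
    stack: TimeLapseStack,
    channel: str | int = 0,
    *,
    threshold: float | None = None,
    min_track_length: int = 5,
    max_link_distance: float = 5.0,
) -> float:
    """Mean speed (µm/s) of tracked spot centroids.

    The speed of each sufficiently long track is its total displacement
    divided by its duration; the reported value is the mean over tracks.
    """
    tracks = track_centroids(
        stack, channel, threshold=threshold, max_link_distance=max_link_distance
    )
    speeds = []
    for tr in tracks:
        if tr.shape[0] < min_track_length:
            continue
        dt_frames = tr[-1, 0] - tr[0, 0]
        if dt_frames <= 0:
            continue
        disp_px = np.hypot(tr[-1, 1] - tr[0, 1], tr[-1, 2] - tr[0, 2])
        speeds.append(
            disp_px * stack.pixel_size / (dt_frames * stack.frame_interval)
        )
    if not speeds:
        raise RuntimeError("no tracks long enough to estimate velocity")
    return float(np.mean(speeds))
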