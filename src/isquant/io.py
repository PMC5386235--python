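"""Calibrated image-stack I/O, region/line specifications, and result tables.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based ``(row, col)``; row 0 is the top of the image.
* A :class:`TimeLapseStack` holds intensities as a ``(frames, channels, rows,
  cols)`` array together with mandatory spatial (``pixel_size``, µm/px) and
  temporal (``frame_interval``, s) calibration.  Analyses that report
  µm-scaled quantities refuse to run without calibration; it is never
  defaulted silently.
* Stacks are written as multi-page TIFF with a JSON sidecar
  (``<stem>.json``) carrying calibration and channel names, so round trips
  are lossless and self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TimeLapseStack",
    "LineSpec",
    "RegionMask",
    "REGION_LABELS",
    "CalibrationError",
    "read_stack",
    "write_stack",
    "write_results_table",
    "read_results_table",
]

#: Closed vocabulary of region labels used across modules.
REGION_LABELS = frozenset(
    {"inside", "outside", "central", "peripheral", "nucleus", "contact"}
)


class CalibrationError(ValueError):
    """Raised when a µm/s-scaled result is requested without calibration."""


@dataclass(frozen=True)
class TimeLapseStack:
    """Calibrated multi-frame, multi-channel image stack.

    Parameters
    ----------
    data:
        Array of shape ``(frames, channels, rows, cols)``.  2-D and 3-D
        inputs are promoted (single frame and/or single channel).
    channels:
        Channel names, one per channel axis entry.
    pixel_size:
        Lateral calibration in µm per pixel (> 0).
    frame_interval:
        Time between consecutive frames in seconds (> 0).
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        elif arr.ndim != 4:
            raise ValueError(f"expected 2-4 dimensional data, got {arr.ndim}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(self.channels) != arr.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel names for {arr.shape[1]} channels"
            )
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise CalibrationError("pixel_size and frame_interval must be > 0")
        if arr.dtype.kind in "fiu" and arr.dtype.kind == "f" and np.any(arr < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return the ``(frames, rows, cols)`` array for one channel."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channels.index(name_or_index)
            except ValueError:
                raise KeyError(f"no channel named {name_or_index!r}") from None
        else:
            idx = int(name_or_index)
        return self.data[:, idx]

    def frame(self, t: int, channel: str | int = 0) -> np.ndarray:
        return self.channel(channel)[t]


@dataclass(frozen=True)
class LineSpec:
    """A straight sampling line with an averaging band.

    ``start`` and ``end`` are ``(row, col)`` pixel coordinates; ``width`` is
    the number of parallel 1-px offset lines averaged perpendicular to the
    line (odd widths are symmetric about the line).
    """

    start: tuple[float, float]
    end: tuple[float, float]
    width: int = 1

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.end):
            raise ValueError("line endpoints must be distinct")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        object.__setattr__(self, "start", (float(self.start[0]), float(self.start[1])))
        object.__setattr__(self, "end", (float(self.end[0]), float(self.end[1])))

    @property
    def length(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    def reversed(self) -> "LineSpec":
        return LineSpec(self.end, self.start, self.width)

    def to_dict(self) -> dict:
        return {"start": list(self.start), "end": list(self.end), "width": self.width}

    @classmethod
    def from_dict(cls, d: dict) -> "LineSpec":
        return cls(tuple(d["start"]), tuple(d["end"]), int(d.get("width", 1)))


@dataclass(frozen=True)
class RegionMask:
    """Boolean pixel mask with a label from the closed region vocabulary."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if self.label not in REGION_LABELS:
            raise ValueError(
                f"label {self.label!r} not in {sorted(REGION_LABELS)}"
            )

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: TimeLapseStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON calibration sidecar.

    Pages are ordered frame-major, channel-minor (TZCYX with Z collapsed).
    """
    path = Path(path)
    f, c, r, w = stack.data.shape
    pages = stack.data.reshape(f * c, r, w)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "channels": list(stack.channels),
        "n_frames": f,
        "dtype": str(stack.data.dtype),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(
    path: str | Path,
    *,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channels: Sequence[str] | None = None,
) -> TimeLapseStack:
    """Read a TIFF stack, taking calibration from the sidecar or overrides.

    Missing calibration (no sidecar and no override) raises
    :class:`CalibrationError` rather than assuming a default.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise CalibrationError(
            f"no calibration for {path.name}: provide pixel_size/frame_interval "
            "overrides or a JSON sidecar"
        )
    names = list(channels) if channels is not None else meta.get("channels")
    n_frames = meta.get("n_frames")
    if names is not None and len(names) > 1:
        n_ch = len(names)
        if pages.shape[0] % n_ch:
            raise ValueError("page count not divisible by channel count")
        pages = pages.reshape(pages.shape[0] // n_ch, n_ch, *pages.shape[1:])
    else:
        if n_frames is not None and pages.shape[0] != n_frames:
            raise ValueError("page count inconsistent with sidecar n_frames")
        pages = pages[:, None]
        names = names or ["ch0"]
    return TimeLapseStack(pages, tuple(names), float(px), float(dt))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit TIFF (255 = True)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["cell_id", "condition", "metric", "value", "units", "seed"]


def write_results_table(records: Sequence[dict], path: str | Path) -> Path:
    """Write per-measurement records to CSV with the shared result schema.

    Every record must provide exactly the schema keys (``cell_id``,
    ``condition``, ``metric``, ``value``, ``units``, ``seed``); an empty
    record list produces a header-only file.
    """
    path = Path(path)
    for rec in records:
        if set(rec) != set(RESULT_COLUMNS):
            raise ValueError(
                f"record keys {sorted(rec)} do not match schema {RESULT_COLUMNS}"
            )
    df = pd.DataFrame(list(records), columns=RESULT_COLUMNS)
    # default float repr is shortest-round-trip, so values survive exactly
    df.to_csv(path, index=False)
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")
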