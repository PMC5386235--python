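"""Manders colocalization with nuclear exclusion and median pre-filtering.

Quantifies the fraction of one channel's fluorescence that sits on pixels
where the other channel is above threshold (Manders M1/M2), as used for
eNOS / F-actin overlap at the cell cortex.  The nuclear region — where
dense chromatin signal would inflate apparent overlap — is excluded from
the analysis domain before computing the coefficients, and both channels
are median filtered to suppress shot noise.

Default thresholds are 0 (any positive signal counts); per-channel
absolute overrides and a Costes-style automatic threshold are available as
explicitly labelled extensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RegionMask
from .ring import median_filter

__all__ = ["MandersResult", "preprocess_for_coloc", "manders_coefficients"]


@dataclass(frozen=True)
class MandersResult:
    m1: float
    m2: float
    threshold_ch1: float
    threshold_ch2: float
    excluded: RegionMask | None = None

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (-eps <= self.m1 <= 1 + eps and -eps <= self.m2 <= 1 + eps):
            raise ValueError("Manders coefficients must lie in [0, 1]")


def preprocess_for_coloc(
    ch1: np.ndarray,
    ch2: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    median_kernel: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exclude the nuclear region and median filter both channels.

    Returns ``(ch1_filtered, ch2_filtered, domain)`` where ``domain`` is
    the boolean analysis mask (everything outside the nucleus).  The
    filtering is the same square-window median used by the ring routine.
    """
    a = np.asarray(ch1, dtype=np.float64)
    b = np.asarray(ch2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    domain = np.ones(a.shape, dtype=bool)
    if nucleus_mask is not None:
        nucleus = np.asarray(nucleus_mask, dtype=bool)
        if nucleus.shape != a.shape:
            raise ValueError("nucleus mask shape differs from channels")
        domain = ~nucleus
    if not domain.any():
        raise ValueError("analysis domain empty: nucleus mask covers the image")
    if median_kernel > 1:
        a = median_filter(a, median_kernel)
        b = median_filter(b, median_kernel)
    return a, b, domain


def manders_coefficients(
    ch1: np.ndarray,
    ch2: np.ndarray,
    domain: np.ndarray | None = None,
    threshold_ch1: float = 0.0,
    threshold_ch2: float = 0.0,
) -> MandersResult:
    """Manders M1/M2 over the analysis domain.

    ``M1`` is the summed ch1 intensity on pixels where ``ch2 >
    threshold_ch2`` divided by the summed ch1 intensity over the whole
    domain; ``M2`` is the symmetric quantity.  Raises when a channel has
    zero total intensity in the domain (coefficient undefined).
    """
    a = np.asarray(ch1, dtype=np.float64)
    b = np.asarray(ch2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if threshold_ch1 < 0 or threshold_ch2 < 0:
        raise ValueError("thresholds must be >= 0")
    if domain is None:
        domain = np.ones(a.shape, dtype=bool)
    domain = np.asarray(domain, dtype=bool)
    if not domain.any():
        raise ValueError("empty analysis domain")

    tot1 = a[domain].sum()
    tot2 = b[domain].sum()
    if tot1 == 0 or tot2 == 0:
        raise ValueError("zero total intensity in a channel: Manders undefined")
    m1 = a[domain & (b > threshold_ch2)].sum() / tot1
    m2 = b[domain & (a > threshold_ch1)].sum() / tot2
    excluded = None
    if not domain.all():
        excluded = RegionMask(~domain, "nucleus")
    return MandersResult(
        m1=float(m1),
        m2=float(m2),
        threshold_ch1=float(threshold_ch1),
        threshold_ch2=float(threshold_ch2),
        excluded=excluded,
    )
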