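"""Network-burst detection and collective-activity statistics.

A network burst is an episode in which a substantial group of ROIs emits
event onsets within a short time window of one another: onsets are chained
while consecutive ones are closer than the chaining window, and a chain
counts as a burst when the fraction of distinct participating ROIs among
the live ROIs reaches a threshold.  Homogeneous cultures burst nearly
network-wide (default threshold 0.5); aggregated cultures burst in
cascades confined to 10-20% of the network (default threshold 0.1).

From the burst sequence follow the inter-burst intervals (IBI,
onset-to-onset), the network activity A = 1 / mean(IBI), and the
post/pre-damage activity ratio Phi = A_after / A_before.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calcium import EventRaster

__all__ = [
    "Burst",
    "BurstSequence",
    "ActivitySummary",
    "detect_network_bursts",
    "inter_burst_intervals",
    "network_activity",
    "activity_ratio",
    "region_burst_counts",
    "activity_summary",
]

DEFAULT_WINDOW_S = 0.2
DEFAULT_MIN_FRACTION = {"homogeneous": 0.5, "aggregated": 0.1}


@dataclass
class Burst:
    onset: float
    offset: float
    rois: np.ndarray  # participating ROI indices (unique, sorted)

    @property
    def n_participants(self) -> int:
        return self.rois.size


@dataclass
class BurstSequence:
    bursts: list[Burst]
    mode: str  # 'aggregated' | 'homogeneous'
    n_live: int
    duration: float

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.bursts])

    @property
    def participation(self) -> np.ndarray:
        """Fraction of live ROIs participating in each burst."""
        return np.array(
            [b.n_participants / self.n_live for b in self.bursts]
        )


@dataclass
class ActivitySummary:
    a: float  # bursts per second (1/mean IBI), nan if < 2 bursts
    ibis: np.ndarray
    n_bursts: int


def detect_network_bursts(
    raster: EventRaster,
    window: float = DEFAULT_WINDOW_S,
    min_fraction: float | None = None,
    mode: str = "homogeneous",
    live: np.ndarray | None = None,
) -> BurstSequence:
    """Chain event onsets into network bursts.

    Onsets (0->1 transitions of the raster) are sorted in time and chained
    while the gap between consecutive onsets is <= ``window`` seconds; a
    chain is a burst when it engages at least ``min_fraction`` of the live
    ROIs.  ``live`` masks out removed/wounded ROIs from the denominator
    (and from participation); by default every ROI counts.
    """
    if raster.n_rois == 0 or raster.n_frames == 0:
        raise ValueError("empty raster")
    if window <= 0:
        raise ValueError("window must be positive")
    if min_fraction is None:
        min_fraction = DEFAULT_MIN_FRACTION[mode]
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    live_mask = (
        np.ones(raster.n_rois, dtype=bool) if live is None else np.asarray(live)
    )
    n_live = int(live_mask.sum())
    duration = raster.n_frames / raster.fps
    if n_live == 0:
        return BurstSequence([], mode, 0, duration)

    rois, frames = raster.onsets()
    keep = live_mask[rois]
    rois, frames = rois[keep], frames[keep]
    order = np.argsort(frames, kind="stable")
    rois, times = rois[order], frames[order] / raster.fps

    bursts: list[Burst] = []
    if times.size:
        # chain boundaries where the inter-onset gap exceeds the window
        breaks = np.flatnonzero(np.diff(times) > window)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, times.size - 1]
        for s, e in zip(starts, ends):
            members = np.unique(rois[s : e + 1])
            if members.size / n_live >= min_fraction:
                bursts.append(
                    Burst(onset=times[s], offset=times[e], rois=members)
                )
    return BurstSequence(bursts, mode, n_live, duration)


def inter_burst_intervals(bursts: BurstSequence) -> np.ndarray:
    """Onset-to-onset intervals between consecutive bursts (seconds)."""
    if len(bursts) < 2:
        warnings.warn("fewer than 2 bursts: no inter-burst intervals")
        return np.array([])
    return np.diff(bursts.onsets)


def network_activity(bursts: BurstSequence) -> float:
    """Network activity A = 1 / mean(IBI), in bursts per second."""
    if len(bursts) < 2:
        raise ValueError(
            "network activity undefined with fewer than 2 bursts"
        )
    return float(1.0 / np.mean(np.diff(bursts.onsets)))


def activity_ratio(a_after: float, a_before: float) -> float:
    """Damage activity ratio Phi = A_after / A_before."""
    if a_before <= 0:
        raise ValueError("pre-damage activity must be positive")
    return float(a_after / a_before)


def activity_summary(bursts: BurstSequence) -> ActivitySummary:
    ibis = np.diff(bursts.onsets) if len(bursts) >= 2 else np.array([])
    a = float(1.0 / ibis.mean()) if ibis.size else float("nan")
    return ActivitySummary(a=a, ibis=ibis, n_bursts=len(bursts))


def region_burst_counts(
    raster: EventRaster,
    regions: dict[str, np.ndarray],
    window: float = DEFAULT_WINDOW_S,
    min_fraction: float = 0.5,
    live: np.ndarray | None = None,
) -> dict[str, int]:
    """Burst counts per region, with detection run within each region.

    ``regions`` maps region label -> ROI indices; every region's
    sub-raster is analyzed independently (region bursting stays
    synchronous within a region even when global synchrony is lost).
    Returns the number of bursts per region over the recording.
    """
    counts: dict[str, int] = {}
    for label, idx in regions.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"region {label!r} has zero ROIs")
        sub = EventRaster(bits=raster.bits[idx], fps=raster.fps)
        sub_live = None if live is None else np.asarray(live)[idx]
        if sub_live is not None and not sub_live.any():
            counts[label] = 0
            continue
        seq = detect_network_bursts(
            sub,
            window=window,
            min_fraction=min_fraction,
            mode="homogeneous",
            live=sub_live,
        )
        counts[label] = len(seq)
    return counts
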