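"""Calcium-fluorescence signal processing: dF/F normalization and
Schmitt-trigger binarization.

The pipeline starts from per-ROI raw fluorescence traces F_i(t).  Each
trace is normalized as dF/F_i(t, %) = 100 * (F_i(t) - F0_i) / F0_i, where
F0_i is the resting (background) fluorescence of ROI i, estimated as a low
percentile of the trace.  The normalized trace is then turned into a
binary activity train with a two-threshold Schmitt trigger: the state
switches to 1 when the trace reaches the high threshold and back to 0
only when it drops below the low one, which suppresses chatter around a
single threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DffTraceSet",
    "EventRaster",
    "estimate_baseline",
    "dff_normalize",
    "noise_sigma",
    "schmitt_binarize",
    "binarize_traces",
    "grid_rois",
]


@dataclass
class DffTraceSet:
    """Normalized traces, ROI x frame, in percent dF/F."""

    values: np.ndarray
    fps: float
    baseline: np.ndarray
    roi_meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("dF/F values must be finite")
        if (self.baseline <= 0).any():
            raise ValueError("baselines must be strictly positive")


@dataclass
class EventRaster:
    """Binary activity trains, ROI x frame ({0,1} entries)."""

    bits: np.ndarray
    fps: float
    roi_meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b = np.asarray(self.bits)
        if not np.isin(b, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.bits = b.astype(np.uint8)

    @property
    def n_rois(self) -> int:
        return self.bits.shape[0]

    @property
    def n_frames(self) -> int:
        return self.bits.shape[1]

    def onsets(self) -> tuple[np.ndarray, np.ndarray]:
        """(roi, frame) indices of 0->1 transitions (event-onset convention)."""
        padded = np.pad(self.bits, ((0, 0), (1, 0)))
        rois, frames = np.nonzero(np.diff(padded, axis=1) == 1)
        return rois, frames


def estimate_baseline(
    traces, window: float | None = None, percentile: float = 0.1
) -> np.ndarray:
    """Per-ROI resting fluorescence F0 as a running low percentile.

    With ``window=None`` (default) the percentile is taken over the whole
    recording, which is appropriate for stationary baselines; otherwise a
    running percentile over ``window`` seconds is computed and its minimum
    per ROI returned.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    values = np.asarray(traces.values, dtype=float)
    if window is not None:
        if window <= 0:
            raise ValueError("window must be positive")
        wlen = max(1, int(round(window * traces.fps)))
        n = values.shape[1]
        starts = range(0, n, wlen)
        per = np.stack(
            [
                np.percentile(values[:, s : s + wlen], 100 * percentile, axis=1)
                for s in starts
            ],
            axis=1,
        )
        f0 = per.min(axis=1)
    else:
        f0 = np.percentile(values, 100 * percentile, axis=1)
    if (f0 <= 0).any():
        raise ValueError(
            "baseline undefined: some ROI has non-positive resting fluorescence"
        )
    return f0


def dff_normalize(traces, baseline: np.ndarray) -> DffTraceSet:
    """Normalize raw traces to percent dF/F against per-ROI baselines."""
    f0 = np.asarray(baseline, dtype=float)
    if (f0 <= 0).any():
        raise ValueError("baseline must be strictly positive")
    values = 100.0 * (np.asarray(traces.values, dtype=float) - f0[:, None]) / f0[:, None]
    return DffTraceSet(
        values=values,
        fps=traces.fps,
        baseline=f0,
        roi_meta=getattr(traces, "roi_meta", None),
    )


def noise_sigma(dff: DffTraceSet) -> np.ndarray:
    """Robust per-ROI noise scale of a dF/F trace.

    Median absolute deviation of the first difference, rescaled to the
    Gaussian sigma (x1.4826) and divided by sqrt(2) to undo the variance
    doubling of differencing.  Insensitive to sparse calcium transients.
    """
    d = np.diff(dff.values, axis=1)
    mad = np.median(np.abs(d - np.median(d, axis=1, keepdims=True)), axis=1)
    return 1.4826 * mad / np.sqrt(2.0)


def schmitt_binarize(
    dff: DffTraceSet,
    high: float | np.ndarray | None = None,
    low: float | np.ndarray | None = None,
) -> EventRaster:
    """Binarize dF/F traces with a two-threshold Schmitt trigger.

    The state starts at 0, switches to 1 when the trace is >= ``high``
    and returns to 0 only when it falls below ``low`` (hysteresis).  When
    thresholds are omitted they default to the per-ROI trace median plus
    4 (high) and 1 (low) robust noise sigmas (see :func:`noise_sigma`),
    so they adapt to each ROI's noise floor; the median centering undoes
    the positive dF/F offset left by a low-percentile baseline.
    """
    v = dff.values
    n = v.shape[0]
    if high is None or low is None:
        sig = noise_sigma(dff)
        sig = np.where(sig > 0, sig, 1.0)
        center = np.median(v, axis=1)
    hi = np.broadcast_to(
        np.asarray(
            center + 4.0 * sig if high is None else high, dtype=float
        ),
        (n,),
    )
    lo = np.broadcast_to(
        np.asarray(
            center + 1.0 * sig if low is None else low, dtype=float
        ),
        (n,),
    )
    if np.any(hi <= lo):
        raise ValueError("Schmitt trigger requires high > low")

    above = v >= hi[:, None]
    below = v < lo[:, None]
    bits = np.zeros_like(v, dtype=np.uint8)
    state = np.zeros(n, dtype=bool)
    for t in range(v.shape[1]):
        state = above[:, t] | (state & ~below[:, t])
        bits[:, t] = state
    return EventRaster(
        bits=bits, fps=dff.fps, roi_meta=getattr(dff, "roi_meta", None)
    )


def binarize_traces(
    traces,
    percentile: float = 0.1,
    window: float | None = None,
    high: float | None = None,
    low: float | None = None,
) -> EventRaster:
    """Convenience path: raw traces -> baseline -> dF/F -> Schmitt raster."""
    f0 = estimate_baseline(traces, window=window, percentile=percentile)
    return schmitt_binarize(dff_normalize(traces, f0), high=high, low=low)


def grid_rois(
    field_side: float, grid: int = 40, mask: str | None = None
) -> pd.DataFrame:
    """Square ROI grid over a field of view.

    Tiles the ``field_side`` x ``field_side`` square (mm, origin at the
    field center) into ``grid`` x ``grid`` tiles and returns their center
    coordinates, row-major and 0-based.  ``mask='circle'`` keeps only
    tiles whose center lies inside the inscribed circle (tiles with no
    tissue under them are dropped).
    """
    if grid < 1:
        raise ValueError("grid must be positive")
    step = field_side / grid
    coords = -field_side / 2 + step * (np.arange(grid) + 0.5)
    rows, cols = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    x = coords[cols.ravel()]
    y = -coords[rows.ravel()]  # row 0 at the top of the field
    df = pd.DataFrame(
        {"row": rows.ravel(), "col": cols.ravel(), "x": x, "y": y}
    )
    if mask == "circle":
        keep = np.hypot(df["x"], df["y"]) <= field_side / 2
        df = df[keep].reset_index(drop=True)
    elif mask is not None:
        raise ValueError(f"unknown mask {mask!r}")
    return df
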