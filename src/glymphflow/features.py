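"""Concentration-time-curve construction and semi-quantitative features.

Every ROI yields one CTC (the per-frame mean over in-ROI voxels).  From each
curve three characteristic parameters are extracted:

* **peak concentration** — maximum of the baseline-subtracted curve [mM];
* **wash-in rate** — maximum forward-difference slope between contrast onset
  and the peak [mM/min];
* **wash-out rate** — negative of the least-squares slope of the segment from
  the peak to the final frame [mM/min], so a clearing curve has a positive
  wash-out rate.  A flat or still-rising tail gives a non-positive value and
  is flagged rather than rejected.

Slopes are estimated on a moving-average-smoothed copy of the curve (default
3-frame window); the peak is taken from the raw curve.  Baseline is the mean
of the pre-injection frames and onset is the first frame exceeding baseline
by three baseline standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dce import CTC

__all__ = ["CTCFeatures", "average_curves", "extract_features", "roi_mean_curve"]


@dataclass(frozen=True)
class CTCFeatures:
    """Semi-quantitative features of one concentration-time curve."""

    peak_concentration: float  # mM, baseline-subtracted
    time_to_peak_s: float
    wash_in_rate: float  # mM/min
    wash_out_rate: float  # mM/min, positive = clearance
    onset_time_s: float
    washout_flagged: bool = False  # True when the tail is flat or rising


def roi_mean_curve(
    volume_series: np.ndarray, roi: np.ndarray, t: np.ndarray,
    subject_id: str = "", roi_id: str = "",
) -> CTC:
    """ROI-mean CTC from a (time, ...) concentration series and a binary ROI.

    ``volume_series`` has time as the leading axis; ``roi`` matches the
    spatial shape of one frame.
    """
    vol = np.asarray(volume_series, dtype=float)
    mask = np.asarray(roi).astype(bool)
    if vol.shape[1:] != mask.shape:
        raise ValueError("ROI shape does not match the spatial shape of the series")
    if not mask.any():
        raise ValueError("ROI is empty")
    t = np.asarray(t, dtype=float)
    if t.shape != (vol.shape[0],):
        raise ValueError("time grid length must match the number of frames")
    curve = vol[:, mask].mean(axis=1)
    return CTC(subject_id=subject_id, roi_id=roi_id, t=t, C=curve)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the boundaries."""
    if window <= 1:
        return y
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def extract_features(
    ctc: CTC, baseline_frames: int = 5, smooth_window: int = 3
) -> CTCFeatures:
    """Extract peak concentration, wash-in rate and wash-out rate from a CTC."""
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    if ctc.t.size < baseline_frames + 3:
        raise ValueError("curve too short for the requested baseline")
    t, c = ctc.t, ctc.C
    baseline = float(np.mean(c[:baseline_frames]))
    baseline_sd = float(np.std(c[:baseline_frames]))
    net = c - baseline
    smoothed = _moving_average(net, smooth_window)

    # peak value from the raw curve; peak location from the smoothed curve so
    # that a single noise spike does not anchor the wash-out segment
    peak_idx = int(np.argmax(smoothed))
    peak = max(float(net[peak_idx]), 0.0)
    time_to_peak = float(t[peak_idx])

    threshold = baseline_sd * 3.0 + 1e-12
    above = np.nonzero(net > threshold)[0]
    onset_idx = int(above[0]) if above.size else 0
    onset_time = float(t[onset_idx])

    # wash-in: steepest ascending forward-difference slope on [onset, peak]
    if peak_idx > onset_idx:
        seg = slice(onset_idx, peak_idx + 1)
        slopes = np.diff(smoothed[seg]) / np.diff(t[seg] / 60.0)
        wash_in = max(float(np.max(slopes)), 0.0)
    else:
        wash_in = 0.0

    # wash-out: negated least-squares slope of the smoothed post-peak segment
    if peak_idx < t.size - 1:
        tt = t[peak_idx:] / 60.0
        yy = smoothed[peak_idx:]
        slope = float(np.polyfit(tt, yy, 1)[0])
        wash_out = -slope
    else:
        wash_out = 0.0
    flagged = wash_out <= 0.0 and peak > 0.0

    return CTCFeatures(
        peak_concentration=peak,
        time_to_peak_s=time_to_peak,
        wash_in_rate=wash_in,
        wash_out_rate=wash_out,
        onset_time_s=onset_time,
        washout_flagged=flagged,
    )


def average_curves(ctcs: list[CTC], grouping: list[str]) -> dict[str, CTC]:
    """Pointwise-mean curve per group label.

    Curves are linearly resampled onto the time grid of the first curve when
    grids differ.  Raises on an empty input or mismatched label list.
    """
    if not ctcs:
        raise ValueError("no curves to average")
    if len(grouping) != len(ctcs):
        raise ValueError("one label per curve is required")
    ref_t = ctcs[0].t
    out: dict[str, CTC] = {}
    for label in dict.fromkeys(grouping):
        members = [c for c, g in zip(ctcs, grouping) if g == label]
        stack = np.vstack([
            c.C if c.t.shape == ref_t.shape and np.allclose(c.t, ref_t)
            else np.interp(ref_t, c.t, c.C)
            for c in members
        ])
        out[label] = CTC(subject_id="", roi_id=f"mean[{label}]", t=ref_t,
                         C=stack.mean(axis=0))
    return out
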