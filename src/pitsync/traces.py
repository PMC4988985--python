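"""Fluorescence normalization and responder detection/classification.

Raw traces are normalized to relative changes F_i/F_0, where F_0 is the
per-cell mean of the first ``n_baseline_frames`` frames (default 50).
Recordings longer than 10 min are truncated before analysis. A cell counts
as a GnRH responder when its normalized trace rises above
baseline mean + k·SD for a sustained run of frames inside the response
horizon; responders are classified as biphasic (1–2 peaks then
plateau/decay) or oscillatory (≥3 recurring peaks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .simulate import RecordingDataset

__all__ = [
    "NormalizedTraces",
    "ResponderCall",
    "normalize_traces",
    "detect_responders",
    "classify_response",
    "MAX_ANALYSIS_DURATION_S",
]

#: Only the first 10 min of a recording enter plots and statistics.
MAX_ANALYSIS_DURATION_S = 600.0


@dataclass
class NormalizedTraces:
    """Normalized ratio traces R = F_i / F_0, cells × frames."""

    ratios: np.ndarray
    timestamps: np.ndarray
    cell_ids: tuple[str, ...]
    n_baseline_frames: int = 50

    @property
    def frame_interval(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    def baseline_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell mean and SD of the baseline frames of R."""
        base = self.ratios[:, : self.n_baseline_frames]
        return base.mean(axis=1), base.std(axis=1, ddof=1)


@dataclass(frozen=True)
class ResponderCall:
    cell_id: str
    is_responder: bool
    response_class: str  # {"biphasic", "oscillatory", "none"}
    peak_ratio: float
    onset_time: Optional[float]  # s, first threshold crossing; None if none


def normalize_traces(
    raw: RecordingDataset, n_baseline_frames: int = 50
) -> NormalizedTraces:
    """Normalize raw fluorescence to F_i/F_0.

    F_0 is the per-cell mean over the first `n_baseline_frames` frames.
    Frames beyond the first 10 min are discarded before normalization.
    """
    F = np.asarray(raw.fluorescence, dtype=float)
    t = np.asarray(raw.timestamps, dtype=float)
    keep = t <= MAX_ANALYSIS_DURATION_S
    F, t = F[:, keep], t[keep]
    if F.shape[1] < n_baseline_frames:
        raise ValueError(
            f"recording has {F.shape[1]} frames; "
            f"need at least n_baseline_frames={n_baseline_frames}"
        )
    bad = np.argwhere(F <= 0)
    if len(bad):
        c, f = bad[0]
        raise ValueError(
            f"non-positive fluorescence at cell {raw.layout.cell_ids[c]!r}, frame {f}"
        )
    f0 = F[:, :n_baseline_frames].mean(axis=1)
    return NormalizedTraces(
        ratios=F / f0[:, None],
        timestamps=t,
        cell_ids=tuple(raw.layout.cell_ids),
        n_baseline_frames=n_baseline_frames,
    )


def detect_responders(
    traces: NormalizedTraces,
    stimulus_window: "TimeWindow | tuple[float, float]",
    k_sd: float = 3.0,
    response_horizon: Optional[float] = None,
    min_run: int = 3,
) -> list[ResponderCall]:
    """Call GnRH responders by a sustained threshold crossing.

    A cell responds when its ratio exceeds baseline mean + `k_sd` × baseline
    SD for at least `min_run` consecutive frames between stimulus onset and
    onset + `response_horizon` (default: stimulus duration + 120 s). The
    sustained-run requirement suppresses single-frame noise excursions.
    `onset_time` is the first frame of the first qualifying run.
    """
    start, end = _window_bounds(stimulus_window)
    t = traces.timestamps
    if response_horizon is None:
        response_horizon = (end - start) + 120.0
    horizon = (t >= start) & (t < start + response_horizon)
    if not horizon.any():
        raise ValueError("stimulus window lies outside the recording")
    mean, sd = traces.baseline_stats()
    thresh = mean + k_sd * sd
    calls: list[ResponderCall] = []
    for i, cid in enumerate(traces.cell_ids):
        seg = traces.ratios[i, horizon]
        seg_t = t[horizon]
        above = seg > thresh[i]
        onset_idx = _first_run(above, min_run)
        if onset_idx is None:
            calls.append(ResponderCall(cid, False, "none", float(seg.max()), None))
            continue
        onset_time = float(seg_t[onset_idx])
        peak = float(seg.max())
        cls = classify_response(
            traces.ratios[i],
            t,
            onset_time,
            threshold=float(thresh[i]),
            peak_ratio=peak,
        )
        calls.append(ResponderCall(cid, True, cls, peak, onset_time))
    return calls


def _first_run(mask: np.ndarray, min_run: int) -> Optional[int]:
    """Index of the start of the first run of ≥ min_run consecutive Trues."""
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= min_run:
            return i - min_run + 1
    return None


def classify_response(
    ratio: np.ndarray,
    timestamps: np.ndarray,
    onset_time: Optional[float],
    threshold: float,
    peak_ratio: Optional[float] = None,
    min_peak_interval_s: float = 10.0,
    prominence_fraction: float = 0.5,
) -> str:
    """Classify a responder trace as biphasic or oscillatory.

    Counts local maxima above `threshold` after `onset_time`, using a peak
    prominence of ``prominence_fraction × (peak_ratio − 1)`` and a minimum
    inter-peak interval. 1–2 peaks → "biphasic"; ≥3 recurring peaks →
    "oscillatory".
    """
    if onset_time is None:
        raise ValueError("classify_response called on a non-responder (no onset)")
    post = timestamps >= onset_time
    seg = np.asarray(ratio, dtype=float)[post]
    if peak_ratio is None:
        peak_ratio = float(seg.max())
    dt = float(timestamps[1] - timestamps[0])
    distance = max(1, int(round(min_peak_interval_s / dt)))
    prominence = prominence_fraction * max(peak_ratio - 1.0, 1e-12)
    peaks, _ = find_peaks(
        seg, height=threshold, prominence=prominence, distance=distance
    )
    # a plateau that never comes back down has its "peak" at the end of the
    # segment, which find_peaks does not count; a responder has >= 1 peak
    n_peaks = max(len(peaks), 1)
    return "oscillatory" if n_peaks >= 3 else "biphasic"


def responder_ids(calls: Sequence[ResponderCall]) -> list[str]:
    """Cell ids of the responders, in call order."""
    return [c.cell_id for c in calls if c.is_responder]


def _window_bounds(window) -> tuple[float, float]:
    if hasattr(window, "start") and hasattr(window, "end"):
        start, end = float(window.start), float(window.end)
    else:
        start, end = map(float, window)
    if not start < end:
        raise ValueError("window start must precede end")
    return start, end
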