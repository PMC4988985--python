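"""Pairwise rank-correlation synchrony analysis.

The synchrony statistic is the Spearman rank correlation between the
normalized fluorescence series of two responding cells inside a time
window. Spearman's rho is computed as the Pearson correlation of midranks
(average ranks on ties), with the p-value from the large-sample t
approximation on n−2 degrees of freedom. Because rank correlation is
invariant to strictly monotone transforms, correlating F_i/F_0 is exactly
equivalent to correlating ΔF/F_0.

Three canonical analysis windows are used: before (100–200 s), during
(250–350 s) and after (500–600 s) GnRH application. All window intervals
are half-open, [start, end).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .simulate import CellLayout
from .traces import NormalizedTraces
from . import distance as _distance

__all__ = [
    "TimeWindow",
    "DEFAULT_WINDOWS",
    "PairCorrelation",
    "CorrelationMatrix",
    "GroupComparison",
    "extract_window",
    "spearman_rho",
    "pairwise_correlations",
    "temporal_heatmap",
    "compare_groups",
]


@dataclass(frozen=True)
class TimeWindow:
    """Half-open analysis interval [start, end) in seconds."""

    name: str
    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    @classmethod
    def before(cls) -> "TimeWindow":
        return cls("before", 100.0, 200.0)

    @classmethod
    def during(cls) -> "TimeWindow":
        return cls("during", 250.0, 350.0)

    @classmethod
    def after(cls) -> "TimeWindow":
        return cls("after", 500.0, 600.0)


DEFAULT_WINDOWS: tuple[TimeWindow, ...] = (
    TimeWindow.before(),
    TimeWindow.during(),
    TimeWindow.after(),
)


@dataclass(frozen=True)
class PairCorrelation:
    """Spearman rho for one unordered cell pair in one window."""

    cell_a: str
    cell_b: str
    window: str
    rho: float
    p_value: float
    distance_um: float
    group: str = ""
    degenerate: bool = False  # zero-variance input; rho undefined


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman-rho matrix over responders for one window position."""

    cell_ids: tuple[str, ...]
    rho: np.ndarray
    window_center: float


@dataclass
class GroupComparison:
    """Mann–Whitney comparison of two rho distributions in one window."""

    window: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    u_statistic: float
    p_value: float
    label_a: str = "a"
    label_b: str = "b"


def extract_window(traces: NormalizedTraces, window: TimeWindow) -> np.ndarray:
    """Per-cell series restricted to frames with start ≤ t < end."""
    t = traces.timestamps
    mask = (t >= window.start) & (t < window.end)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(
            f"window [{window.start}, {window.end}) contains {n} frames at "
            f"frame interval {traces.frame_interval} s; need at least 3"
        )
    return traces.ratios[:, mask]


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1, method="average")


def _rho_p_from_ranks(rank_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix of midranks and t-approximation p-values.

    Rows with zero rank variance give NaN rho (degenerate pairs).
    """
    n = rank_matrix.shape[1]
    centered = rank_matrix - rank_matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ centered.T) / np.outer(norms, norms)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return rho, p


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value.

    rho is the Pearson correlation of midranks; p is two-sided from
    t = rho·sqrt((n−2)/(1−rho²)) on n−2 df. Zero-variance input yields
    (nan, nan) — a degenerate result to be flagged and excluded downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    ranks = _midranks(np.vstack([x, y]))
    rho, p = _rho_p_from_ranks(ranks)
    return float(rho[0, 1]), float(p[0, 1])


def pairwise_correlations(
    traces: NormalizedTraces,
    responders: Sequence[str],
    window: TimeWindow,
    layout: CellLayout,
    group: str = "",
    distance_convention: str = "membrane",
) -> list[PairCorrelation]:
    """Spearman rho for all unordered responder pairs in one window.

    Returns exactly n(n−1)/2 entries, each carrying the intercellular
    distance under `distance_convention`. Zero-variance pairs are flagged
    degenerate (rho = NaN) rather than dropped, so pair counts stay exact.
    """
    responders = list(responders)
    if len(responders) < 2:
        raise ValueError("need at least 2 responders for pairwise correlations")
    id_to_row = {cid: i for i, cid in enumerate(traces.cell_ids)}
    missing = [r for r in responders if r not in id_to_row]
    if missing:
        raise ValueError(f"responders not present in traces: {missing}")
    series = extract_window(traces, window)
    rows = [id_to_row[r] for r in responders]
    ranks = _midranks(series[rows])
    rho, p = _rho_p_from_ranks(ranks)
    dmat = _distance.distance_matrix(layout, convention=distance_convention)
    layout_idx = {cid: i for i, cid in enumerate(layout.cell_ids)}
    out: list[PairCorrelation] = []
    for (i, a), (j, b) in itertools.combinations(enumerate(responders), 2):
        r = rho[i, j]
        out.append(
            PairCorrelation(
                cell_a=a,
                cell_b=b,
                window=window.name,
                rho=float(r),
                p_value=float(p[i, j]),
                distance_um=float(dmat[layout_idx[a], layout_idx[b]]),
                group=group,
                degenerate=bool(np.isnan(r)),
            )
        )
    return out


def temporal_heatmap(
    traces: NormalizedTraces,
    responders: Sequence[str],
    sliding_window_length: float = 50.0,
    step: float = 10.0,
) -> list[CorrelationMatrix]:
    """Sliding-window Spearman matrices over responders (heat-map series).

    One symmetric rho matrix per window position; degenerate entries are
    NaN, defined diagonal entries are 1.
    """
    responders = list(responders)
    if len(responders) < 2:
        raise ValueError("need at least 2 responders for a correlation map")
    if sliding_window_length < 3 * traces.frame_interval:
        raise ValueError("sliding window must span at least 3 frames")
    id_to_row = {cid: i for i, cid in enumerate(traces.cell_ids)}
    rows = [id_to_row[r] for r in responders]
    t0, t1 = float(traces.timestamps[0]), float(traces.timestamps[-1])
    out: list[CorrelationMatrix] = []
    start = t0
    while start + sliding_window_length <= t1 + traces.frame_interval:
        window = TimeWindow("custom", start, start + sliding_window_length)
        try:
            series = extract_window(traces, window)
        except ValueError:
            break
        ranks = _midranks(series[rows])
        rho, _ = _rho_p_from_ranks(ranks)
        out.append(
            CorrelationMatrix(
                cell_ids=tuple(responders),
                rho=rho,
                window_center=start + sliding_window_length / 2.0,
            )
        )
        start += step
    return out


def compare_groups(
    pairs_a: Sequence[PairCorrelation],
    pairs_b: Sequence[PairCorrelation],
    window: Optional[str] = None,
) -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of pairwise rho distributions.

    Uses the normal approximation with tie correction. Degenerate pairs are
    excluded. Both inputs must come from the same analysis window.
    """
    if window is not None:
        pairs_a = [p for p in pairs_a if p.window == window]
        pairs_b = [p for p in pairs_b if p.window == window]
    windows = {p.window for p in pairs_a} | {p.window for p in pairs_b}
    if len(windows) > 1:
        raise ValueError(f"pairs span multiple windows: {sorted(windows)}")
    a = np.asarray([p.rho for p in pairs_a if not p.degenerate])
    b = np.asarray([p.rho for p in pairs_b if not p.degenerate])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must contain at least one valid pair")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        window=windows.pop() if windows else "",
        n_a=len(a),
        n_b=len(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        iqr_b=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
        u_statistic=float(u),
        p_value=float(p),
        label_a=pairs_a[0].group or "a",
        label_b=pairs_b[0].group or "b",
    )
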