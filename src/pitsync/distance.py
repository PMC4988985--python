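"""Distance-resolved correlation analysis.

Intercellular distance is measured either centroid-to-centroid or
membrane-to-membrane (centroid distance minus both radii, floored at 0).
Pairwise Spearman coefficients are regressed on distance by ordinary least
squares (positive coefficients only, by default, matching the published
convention), and regression lines from two genotypes are compared with a
two-sample t-test on slopes and intercepts. A separate short-range analysis
compares rho distributions restricted to pairs less than 5 μm apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import CellLayout

__all__ = [
    "RegressionFit",
    "SlopeComparison",
    "ShortRangeResult",
    "pair_distance",
    "distance_matrix",
    "fit_distance_regression",
    "compare_regressions",
    "short_range_compare",
]


@dataclass
class RegressionFit:
    """OLS fit of rho against intercellular distance for one group/window."""

    slope: float  # per μm
    intercept: float
    se_slope: float
    se_intercept: float
    n: int
    r: float  # Pearson correlation of the fitted relation
    p_correlation: float  # significance of the prerequisite correlation screen
    group: str = ""
    window: str = ""


@dataclass
class SlopeComparison:
    """Between-group comparison of two regression lines.

    t = (b1 − b2) / sqrt(SE1² + SE2²) on n1 + n2 − 4 df, two-sided; the
    intercept comparison is analogous. Significance threshold 0.001 is
    attached as metadata, following the published convention.
    """

    slope_difference: float
    t_slope: float
    df: int
    p_slope: float
    intercept_difference: float
    t_intercept: float
    p_intercept: float
    alpha: float = 0.001


@dataclass
class ShortRangeResult:
    """Group comparison restricted to pairs closer than `threshold_um`."""

    threshold_um: float
    comparison: "GroupComparison"  # noqa: F821 - synchrony.GroupComparison
    n_a: int
    n_b: int


def pair_distance(
    a: tuple[float, float, float],
    b: tuple[float, float, float],
    convention: str = "membrane",
) -> float:
    """Distance between two cells given as (x, y, radius) in μm.

    centroid: Euclidean distance of centroids; membrane:
    max(0, centroid − r_a − r_b).
    """
    xa, ya, ra = a
    xb, yb, rb = b
    if ra < 0 or rb < 0:
        raise ValueError("radii must be non-negative")
    d = float(np.hypot(xa - xb, ya - yb))
    if convention == "centroid":
        return d
    if convention == "membrane":
        return max(0.0, d - ra - rb)
    raise ValueError(f"unknown distance convention {convention!r}")


def distance_matrix(layout: CellLayout, convention: str = "membrane") -> np.ndarray:
    """Full pairwise distance matrix for a layout, in μm."""
    if convention == "centroid":
        return layout.centroid_distances()
    if convention == "membrane":
        return layout.membrane_distances()
    raise ValueError(f"unknown distance convention {convention!r}")


def fit_distance_regression(
    pairs: Sequence["PairCorrelation"],  # noqa: F821
    positive_only: bool = True,
    group: str = "",
    window: str = "",
) -> RegressionFit:
    """OLS regression of Spearman rho on intercellular distance.

    With `positive_only` (the default, matching the published analysis) only
    pairs with rho > 0 enter the fit. Degenerate pairs are always excluded.
    The Pearson correlation screen between rho and distance is reported
    alongside the fit.
    """
    kept = [p for p in pairs if not p.degenerate]
    if positive_only:
        kept = [p for p in kept if p.rho > 0]
    if len(kept) < 3:
        raise ValueError(
            f"need >=3 pairs after filtering, got {len(kept)} "
            f"(of {len(pairs)} input pairs)"
        )
    d = np.asarray([p.distance_um for p in kept])
    r = np.asarray([p.rho for p in kept])
    if np.ptp(d) == 0:
        raise ValueError("all pairs lie at one distance; slope not identifiable")
    fit = stats.linregress(d, r)
    screen_r, screen_p = stats.pearsonr(d, r)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        se_slope=float(fit.stderr),
        se_intercept=float(fit.intercept_stderr),
        n=len(kept),
        r=float(screen_r),
        p_correlation=float(screen_p),
        group=group or (kept[0].group if kept else ""),
        window=window or (kept[0].window if kept else ""),
    )


def compare_regressions(fit_a: RegressionFit, fit_b: RegressionFit) -> SlopeComparison:
    """Two-sample t comparison of slopes and intercepts of two OLS fits."""
    df = fit_a.n + fit_b.n - 4
    if df < 1:
        raise ValueError("too few pairs for a slope comparison")

    def _t_p(d: float, se1: float, se2: float) -> tuple[float, float]:
        se = float(np.hypot(se1, se2))
        if se == 0:
            t = 0.0 if d == 0 else np.inf * np.sign(d)
        else:
            t = d / se
        p = float(2.0 * stats.t.sf(abs(t), df=df))
        return float(t), p

    ds = fit_a.slope - fit_b.slope
    t_s, p_s = _t_p(ds, fit_a.se_slope, fit_b.se_slope)
    di = fit_a.intercept - fit_b.intercept
    t_i, p_i = _t_p(di, fit_a.se_intercept, fit_b.se_intercept)
    return SlopeComparison(
        slope_difference=float(ds),
        t_slope=t_s,
        df=df,
        p_slope=p_s,
        intercept_difference=float(di),
        t_intercept=t_i,
        p_intercept=p_i,
    )


def short_range_compare(
    pairs_a: Sequence["PairCorrelation"],  # noqa: F821
    pairs_b: Sequence["PairCorrelation"],  # noqa: F821
    threshold_um: float = 5.0,
    window: str | None = None,
) -> ShortRangeResult:
    """Mann–Whitney comparison of rho restricted to short-distance pairs.

    Distances carried by the pairs are used as-is (compute them under the
    membrane convention for the canonical <5 μm analysis).
    """
    from .synchrony import compare_groups  # local import; avoids module cycle

    if threshold_um <= 0:
        raise ValueError("threshold_um must be positive")
    short_a = [p for p in pairs_a if p.distance_um < threshold_um]
    short_b = [p for p in pairs_b if p.distance_um < threshold_um]
    if not short_a or not short_b:
        dmin_a = min((p.distance_um for p in pairs_a), default=float("nan"))
        dmin_b = min((p.distance_um for p in pairs_b), default=float("nan"))
        raise ValueError(
            f"no pairs under {threshold_um} μm in one group "
            f"(minimum distances: {dmin_a:.2f} and {dmin_b:.2f} μm)"
        )
    comparison = compare_groups(short_a, short_b, window=window)
    return ShortRangeResult(
        threshold_um=threshold_um,
        comparison=comparison,
        n_a=comparison.n_a,
        n_b=comparison.n_b,
    )
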