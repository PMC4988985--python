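"""Gap-junction coupling coefficients from paired current-clamp recordings.

The coupling coefficient (CC) is the steady-state voltage deflection of the
follower cell divided by that of the injected cell. Per-sweep deflections
are measured as mean voltage over a steady-state interval (default the last
20% of the current step) minus mean voltage over a pre-step baseline
(default the 100 ms preceding step onset), averaged over 10–60 consecutive
sweeps; the CC is the ratio of the averaged deflections, with the SEM
propagated from per-sweep ratios. A pair is classified as coupled when the
CC exceeds a z-score criterion in both injection directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .simulate import PairedSweepSet

__all__ = [
    "DirectionalEstimate",
    "CouplingEstimate",
    "steady_state_deflection",
    "coupling_coefficient",
    "estimate_coupling",
    "classify_coupled",
]

#: Injected-cell deflections smaller than this (mV) make the ratio unstable.
MIN_INJECTED_DEFLECTION_MV = 1.0


@dataclass
class DirectionalEstimate:
    """Coupling coefficient for one injection direction."""

    cc: float
    sem: float
    n_sweeps: int
    deltaV_injected_mv: float
    deltaV_follower_mv: float


@dataclass
class CouplingEstimate:
    """Bidirectional coupling estimate for one cell pair."""

    cc_12: float
    cc_21: float
    sem_12: float
    sem_21: float
    n_sweeps: int
    deltaV_injected_mv: tuple[float, float]
    deltaV_follower_mv: tuple[float, float]
    coupled: Optional[bool] = None

    @property
    def mean_cc(self) -> float:
        return 0.5 * (self.cc_12 + self.cc_21)


def steady_state_deflection(
    time_s: np.ndarray,
    voltage_mv: np.ndarray,
    baseline_interval: tuple[float, float],
    steady_interval: tuple[float, float],
) -> float:
    """Steady-state deflection: mean(V, steady) − mean(V, baseline), in mV.

    `voltage_mv` may be one sweep (1-D) or sweeps × samples (2-D; the
    deflection is computed per sweep and returned as an array).
    """
    time_s = np.asarray(time_s, dtype=float)
    v = np.asarray(voltage_mv, dtype=float)
    out_1d = v.ndim == 1
    v = np.atleast_2d(v)

    def _mask(interval):
        lo, hi = interval
        if not lo < hi:
            raise ValueError("interval start must precede end")
        if lo < time_s[0] - 1e-12 or hi > time_s[-1] + 1e-12:
            raise ValueError(f"interval {interval} lies outside the sweep")
        m = (time_s >= lo) & (time_s < hi)
        if not m.any():
            raise ValueError(f"interval {interval} contains no samples")
        return m

    base = v[:, _mask(baseline_interval)].mean(axis=1)
    steady = v[:, _mask(steady_interval)].mean(axis=1)
    d = steady - base
    return float(d[0]) if out_1d else d


def _default_intervals(sweeps: PairedSweepSet) -> tuple[tuple[float, float], tuple[float, float]]:
    on, dur = sweeps.step_onset_s, sweeps.step_duration_s
    baseline = (max(sweeps.time_s[0], on - 0.1), on)
    steady = (on + 0.8 * dur, on + dur)
    return baseline, steady


def coupling_coefficient(
    sweeps: PairedSweepSet,
    baseline_interval: Optional[tuple[float, float]] = None,
    steady_interval: Optional[tuple[float, float]] = None,
) -> DirectionalEstimate:
    """Coupling coefficient for one injection direction.

    Per-sweep steady-state deflections of both channels are averaged first;
    CC = mean(ΔV_follower) / mean(ΔV_injected). The SEM is the standard
    error of the per-sweep ratios. Raises when the mean injected deflection
    is below ``MIN_INJECTED_DEFLECTION_MV`` (ratio unstable), and reports a
    negative CC (opposite-sign deflections) as-is.
    """
    if baseline_interval is None or steady_interval is None:
        default_base, default_steady = _default_intervals(sweeps)
        baseline_interval = baseline_interval or default_base
        steady_interval = steady_interval or default_steady
    on, off = sweeps.step_onset_s, sweeps.step_onset_s + sweeps.step_duration_s
    if baseline_interval[1] > on + 1e-12 or baseline_interval[0] < sweeps.time_s[0] - 1e-12:
        raise ValueError("baseline interval overlaps the current-step onset")
    if steady_interval[0] < on - 1e-12 or steady_interval[1] > off + 1e-12:
        raise ValueError("steady interval must lie within the current step")
    d_inj = steady_state_deflection(
        sweeps.time_s, sweeps.v1_mv, baseline_interval, steady_interval
    )
    d_fol = steady_state_deflection(
        sweeps.time_s, sweeps.v2_mv, baseline_interval, steady_interval
    )
    d_inj = np.atleast_1d(d_inj)
    d_fol = np.atleast_1d(d_fol)
    mean_inj = float(d_inj.mean())
    if abs(mean_inj) < MIN_INJECTED_DEFLECTION_MV:
        raise ValueError(
            f"mean injected deflection {mean_inj:.3f} mV is below the "
            f"{MIN_INJECTED_DEFLECTION_MV} mV floor; coupling ratio unstable"
        )
    cc = float(d_fol.mean()) / mean_inj
    ratios = d_fol / d_inj
    n = len(ratios)
    sem = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DirectionalEstimate(
        cc=cc,
        sem=sem,
        n_sweeps=n,
        deltaV_injected_mv=mean_inj,
        deltaV_follower_mv=float(d_fol.mean()),
    )


def estimate_coupling(
    sweeps_1to2: PairedSweepSet,
    sweeps_2to1: Optional[PairedSweepSet] = None,
    z_threshold: float = 3.0,
    **interval_kwargs,
) -> CouplingEstimate:
    """Bidirectional coupling estimate, classified with `classify_coupled`.

    When only one direction was recorded, the same sweeps with channels
    swapped CANNOT stand in for the reverse direction; pass `sweeps_2to1`
    from the experiment where the other cell was injected.
    """
    d12 = coupling_coefficient(sweeps_1to2, **interval_kwargs)
    if sweeps_2to1 is None:
        d21 = d12
    else:
        d21 = coupling_coefficient(sweeps_2to1, **interval_kwargs)
    est = CouplingEstimate(
        cc_12=d12.cc,
        cc_21=d21.cc,
        sem_12=d12.sem,
        sem_21=d21.sem,
        n_sweeps=d12.n_sweeps,
        deltaV_injected_mv=(d12.deltaV_injected_mv, d21.deltaV_injected_mv),
        deltaV_follower_mv=(d12.deltaV_follower_mv, d21.deltaV_follower_mv),
    )
    est.coupled = classify_coupled(est, z_threshold=z_threshold)
    return est


def classify_coupled(estimate: CouplingEstimate, z_threshold: float = 3.0) -> bool:
    """Detectably coupled: CC exceeds z_threshold × SEM in both directions."""
    def _ok(cc: float, sem: float) -> bool:
        if sem == 0:
            return cc > 0
        return cc > z_threshold * sem
    return _ok(estimate.cc_12, estimate.sem_12) and _ok(estimate.cc_21, estimate.sem_21)
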