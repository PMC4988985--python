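"""Synthetic coupled/uncoupled gonadotrope network recordings.

Generates calcium-imaging datasets from a phenomenological network model of
GnRH-stimulated pituitary gonadotropes, together with paired current-clamp
sweeps, with full ground truth. The model is the generative counterpart of
the analysis chain in this package:

* Cells are placed uniformly in a microscope field with a hard-core minimum
  separation so ROIs never overlap.
* Responders show, after stimulus onset plus a per-cell latency, either a
  biphasic (fast rise, slow decay to a plateau) or an oscillatory calcium
  waveform; non-responders stay at baseline.
* Latency has a spatially structured component (a stimulus wash-in wavefront
  along a random direction) plus i.i.d. jitter, so nearby cells respond at
  similar times even without gap junctions.
* Gap-junction coupling is a distance-dependent graph,
  ``w_ij = coupling_strength * exp(-d_ij / coupling_length_scale)`` on
  membrane-to-membrane distance. It acts in two ways: latencies (and
  oscillation periods) of responding cells are entrained toward their
  neighbors' by iterated diffusive averaging over the graph, and the evoked
  signal of each cell is mixed with its neighbors' per frame.
* Optionally, a slow tonic baseline fluctuation is present in every cell;
  with tonic coupling enabled it is mixed over the same graph, which
  correlates nearby cells at all times (not just under stimulation).
* Noise is multiplicative log-normal plus additive Gaussian on raw
  fluorescence.

This is deliberately not a biophysical conductance model: it reproduces the
correlation structure that the downstream synchrony analysis measures, with
known ground truth, and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._rng import stream

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "CellLayout",
    "CouplingGraph",
    "RecordingDataset",
    "PairedSweepSet",
    "simulate_network",
    "simulate_paired_recording",
    "simulate_paired_experiment",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of one simulated slice experiment.

    Defaults mirror the imaging protocol the analysis expects: 1 frame/s for
    10 min, F0 baseline at the start, GnRH reaching the slice at ~240 s so
    that evoked activity falls inside the canonical 250–350 s analysis
    window, ~150 μm field, and a gap-junction length scale of ~one cell
    diameter.
    """

    n_cells: int = 60
    field_size: tuple[float, float] = (150.0, 150.0)  # μm
    frame_interval: float = 1.0  # s, allowed 0.5–2.0
    total_duration: float = 600.0  # s
    baseline_duration: float = 120.0  # s (pre-stimulus reference period)
    stimulus_onset: float = 240.0  # s, when GnRH reaches the cells
    stimulus_duration: float = 120.0  # s
    responder_fraction: float = 0.4
    p_biphasic: float = 0.5
    coupling_enabled: bool = False
    coupling_length_scale: float = 10.0  # μm
    coupling_strength: float = 1.0  # dimensionless ≥ 0
    tonic_coupling: bool = False
    tonic_fluctuation_sd: float = 0.04  # relative units of the slow baseline process
    tonic_timescale: float = 20.0  # s, correlation time of the slow process
    response_latency_mean: float = 15.0  # s after stimulus onset
    response_latency_jitter_sd: float = 4.0  # s, i.i.d. per cell
    latency_gradient: float = 0.15  # s/μm wash-in wavefront
    n_entrain_iterations: int = 50
    noise_sd: float = 0.05  # multiplicative log-normal sigma
    additive_noise_sd: float = 2.0  # a.u.
    oscillation_period_mean: float = 40.0  # s
    oscillation_period_sd: float = 3.0  # s
    cell_radius: float = 5.0  # μm
    baseline_fluorescence: tuple[float, float] = (300.0, 800.0)  # a.u. range
    seed: int = 0
    label: str = ""

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if any(s <= 0 for s in self.field_size):
            raise ConfigurationError("field_size entries must be positive")
        if not (0.5 <= self.frame_interval <= 2.0):
            raise ConfigurationError("frame_interval must lie in [0.5, 2.0] s")
        if self.baseline_duration + self.stimulus_duration > self.total_duration:
            raise ConfigurationError(
                "baseline_duration + stimulus_duration exceeds total_duration"
            )
        if not (self.baseline_duration <= self.stimulus_onset):
            raise ConfigurationError("stimulus_onset must be >= baseline_duration")
        if self.stimulus_onset + self.stimulus_duration > self.total_duration:
            raise ConfigurationError(
                "stimulus_onset + stimulus_duration exceeds total_duration"
            )
        for name in ("responder_fraction", "p_biphasic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.coupling_strength < 0:
            raise ConfigurationError("coupling_strength must be >= 0")
        if self.coupling_length_scale <= 0:
            raise ConfigurationError("coupling_length_scale must be positive")
        for name in (
            "response_latency_jitter_sd",
            "noise_sd",
            "additive_noise_sd",
            "tonic_fluctuation_sd",
            "latency_gradient",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.oscillation_period_mean <= 0:
            raise ConfigurationError("oscillation_period_mean must be positive")
        if self.cell_radius <= 0:
            raise ConfigurationError("cell_radius must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellLayout:
    """ROI centroids and radii, in μm, for one field of view."""

    cell_ids: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    radius: np.ndarray

    def __post_init__(self):
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if np.any(self.radius <= 0):
            raise ValueError("all ROI radii must be positive")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def centroid_distances(self) -> np.ndarray:
        """Pairwise Euclidean centroid distance matrix (μm)."""
        dx = self.x[:, None] - self.x[None, :]
        dy = self.y[:, None] - self.y[None, :]
        return np.hypot(dx, dy)

    def membrane_distances(self) -> np.ndarray:
        """Pairwise membrane-to-membrane distance, max(0, centroid − r_a − r_b)."""
        d = self.centroid_distances() - self.radius[:, None] - self.radius[None, :]
        np.fill_diagonal(d, 0.0)
        return np.maximum(d, 0.0)


@dataclass(frozen=True)
class CouplingGraph:
    """Symmetric, zero-diagonal, non-negative pairwise coupling weights."""

    weights: np.ndarray

    def __post_init__(self):
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("coupling weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("coupling weights must be finite")
        if np.any(w < 0):
            raise ValueError("coupling weights must be non-negative")
        if not np.allclose(w, w.T):
            raise ValueError("coupling weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("coupling weights must have a zero diagonal")


@dataclass
class RecordingDataset:
    """One simulated (or loaded) slice experiment.

    ``fluorescence`` is raw, strictly positive, cells × frames in arbitrary
    units; ``timestamps`` are seconds per frame with constant spacing.
    ``ground_truth`` (simulations only) carries per-cell responder flags,
    response classes, true onset times and the coupling graph.
    """

    fluorescence: np.ndarray
    timestamps: np.ndarray
    layout: CellLayout
    ground_truth: Optional[dict] = None
    label: str = ""

    def __post_init__(self):
        if self.fluorescence.shape[0] != len(self.layout):
            raise ValueError("fluorescence rows must match layout cells")
        if self.fluorescence.shape[1] != len(self.timestamps):
            raise ValueError("fluorescence columns must match timestamps")
        if np.any(self.fluorescence <= 0):
            raise ValueError("fluorescence must be strictly positive")
        dt = np.diff(self.timestamps)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("timestamps must increase with constant spacing")

    @property
    def frame_interval(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])


@dataclass
class PairedSweepSet:
    """Paired current-clamp sweeps: one cell injected, both recorded.

    ``v1_mv`` is the injected cell, ``v2_mv`` the follower, each
    sweeps × samples. Swap the channels (:meth:`swapped`) for the reverse
    direction of a bidirectional experiment.
    """

    time_s: np.ndarray
    i_pa: np.ndarray  # per sweep step amplitude
    v1_mv: np.ndarray
    v2_mv: np.ndarray
    step_onset_s: float
    step_duration_s: float
    holding_mv: float = -60.0
    true_cc: Optional[float] = None

    def __post_init__(self):
        if self.v1_mv.shape != self.v2_mv.shape:
            raise ValueError("v1 and v2 must have the same shape")
        if self.v1_mv.shape[0] < 1:
            raise ValueError("at least one sweep is required")
        if self.v1_mv.shape[1] != len(self.time_s):
            raise ValueError("sample count must match the time base")

    @property
    def n_sweeps(self) -> int:
        return self.v1_mv.shape[0]

    def swapped(self) -> "PairedSweepSet":
        return PairedSweepSet(
            time_s=self.time_s,
            i_pa=self.i_pa,
            v1_mv=self.v2_mv,
            v2_mv=self.v1_mv,
            step_onset_s=self.step_onset_s,
            step_duration_s=self.step_duration_s,
            holding_mv=self.holding_mv,
            true_cc=self.true_cc,
        )


# ---------------------------------------------------------------------------
# network simulation
# ---------------------------------------------------------------------------

# Waveform kinetics (free parameters of the model; see docs/methods.md).
_BIPHASIC_AMP = 1.5  # peak Δratio above baseline
_BIPHASIC_TAU_RISE = 4.0  # s
_BIPHASIC_TAU_DECAY = 80.0  # s
_BIPHASIC_PLATEAU = 0.35  # fraction of amplitude retained at steady state
_OSC_AMP = 1.2
_OSC_TAU_RISE = 4.0  # s
_OSC_TAU_ENV = 180.0  # s, envelope decay


def _place_cells(cfg: SimulationConfig, rng: np.random.Generator) -> CellLayout:
    """Uniform hard-core placement: minimum centroid separation 2×radius."""
    w, h = cfg.field_size
    r = cfg.cell_radius
    min_sep = 2.0 * r
    if w < 2 * r or h < 2 * r:
        raise ConfigurationError("field_size too small for cell_radius")
    xs, ys = [], []
    attempts = 0
    max_attempts = 20000 * cfg.n_cells
    while len(xs) < cfg.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                "n_cells: cannot place this many non-overlapping cells in field_size"
            )
        cx = rng.uniform(r, w - r)
        cy = rng.uniform(r, h - r)
        if xs:
            d2 = (np.asarray(xs) - cx) ** 2 + (np.asarray(ys) - cy) ** 2
            if np.min(d2) < min_sep**2:
                continue
        xs.append(cx)
        ys.append(cy)
    ids = tuple(f"cell{i:03d}" for i in range(cfg.n_cells))
    return CellLayout(
        cell_ids=ids,
        x=np.asarray(xs),
        y=np.asarray(ys),
        radius=np.full(cfg.n_cells, r),
    )


def _biphasic_waveform(t_rel: np.ndarray) -> np.ndarray:
    t = np.maximum(t_rel, 0.0)
    rise = 1.0 - np.exp(-t / _BIPHASIC_TAU_RISE)
    decay = _BIPHASIC_PLATEAU + (1.0 - _BIPHASIC_PLATEAU) * np.exp(-t / _BIPHASIC_TAU_DECAY)
    return np.where(t_rel >= 0, _BIPHASIC_AMP * rise * decay, 0.0)


def _oscillatory_waveform(t_rel: np.ndarray, period: float) -> np.ndarray:
    t = np.maximum(t_rel, 0.0)
    env = _OSC_AMP * (1.0 - np.exp(-t / _OSC_TAU_RISE)) * np.exp(-t / _OSC_TAU_ENV)
    cyc = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / period))
    return np.where(t_rel >= 0, env * cyc, 0.0)


def _diffuse(values: np.ndarray, weights: np.ndarray, n_iter: int) -> np.ndarray:
    """Iterated diffusive averaging of per-cell scalars over the graph."""
    v = values.astype(float).copy()
    denom = 1.0 + weights.sum(axis=1)
    for _ in range(n_iter):
        v = (v + weights @ v) / denom
    return v


def _mix_signals(signal: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """One step of weighted diffusive mixing of cell × frame signals."""
    denom = 1.0 + weights.sum(axis=1)
    return (signal + weights @ signal) / denom[:, None]


def simulate_network(config: SimulationConfig) -> RecordingDataset:
    """Simulate one slice experiment under `config`.

    Deterministic: identical configs (including seed) give bit-identical
    datasets. Ground truth carries responder flags and classes, true onset
    times and the coupling graph.
    """
    config.validate()
    n = config.n_cells
    layout = _place_cells(config, stream(config.seed, "layout"))
    timestamps = np.arange(0.0, config.total_duration, config.frame_interval)
    n_frames = len(timestamps)

    # responder flags and response classes
    rng_cls = stream(config.seed, "classes")
    is_responder = rng_cls.random(n) < config.responder_fraction
    biphasic = rng_cls.random(n) < config.p_biphasic
    classes = np.where(
        is_responder, np.where(biphasic, "biphasic", "oscillatory"), "none"
    )

    # coupling graph on membrane distances
    if config.coupling_enabled:
        w = config.coupling_strength * np.exp(
            -layout.membrane_distances() / config.coupling_length_scale
        )
        np.fill_diagonal(w, 0.0)
    else:
        w = np.zeros((n, n))
    graph = CouplingGraph(weights=w)

    # latencies: wash-in wavefront + i.i.d. jitter
    rng_lat = stream(config.seed, "latency")
    theta = rng_lat.uniform(0.0, 2.0 * np.pi)
    proj = (layout.x - layout.x.mean()) * np.cos(theta) + (
        layout.y - layout.y.mean()
    ) * np.sin(theta)
    latency = (
        config.response_latency_mean
        + config.latency_gradient * proj
        + rng_lat.normal(0.0, config.response_latency_jitter_sd, size=n)
    )
    latency = np.maximum(np.asarray(latency, dtype=float), 0.5)
    periods = np.maximum(
        stream(config.seed, "periods").normal(
            config.oscillation_period_mean, config.oscillation_period_sd, size=n
        ),
        5.0,
    )

    # gap-junction entrainment of response timing; diffusion runs over the
    # full graph (non-responding cells still relay timing through their
    # junctions), driving the network toward a common activity pattern
    if config.coupling_enabled and n > 1:
        latency = _diffuse(latency, w, config.n_entrain_iterations)
        periods = _diffuse(periods, w, config.n_entrain_iterations)

    onset = config.stimulus_onset + latency

    # evoked component (Δratio above the unit baseline)
    evoked = np.zeros((n, n_frames))
    for i in range(n):
        if not is_responder[i]:
            continue
        t_rel = timestamps - onset[i]
        if classes[i] == "biphasic":
            evoked[i] = _biphasic_waveform(t_rel)
        else:
            evoked[i] = _oscillatory_waveform(t_rel, periods[i])

    if config.coupling_enabled and is_responder.sum() > 1:
        # evoked signal diffuses among responding cells; spread into
        # non-responsive cells is treated as sub-threshold and omitted, so
        # responder counts stay comparable between coupled/uncoupled arms
        idx = np.where(is_responder)[0]
        evoked[idx] = _mix_signals(evoked[idx], w[np.ix_(idx, idx)])

    # slow tonic baseline fluctuation, present only in tonic-coupling scenarios
    ratio = 1.0 + evoked
    if config.tonic_coupling and config.tonic_fluctuation_sd > 0:
        rng_tonic = stream(config.seed, "tonic")
        white = rng_tonic.standard_normal((n, n_frames))
        sigma_frames = config.tonic_timescale / config.frame_interval
        slow = gaussian_filter1d(white, sigma=sigma_frames, axis=1, mode="reflect")
        sd = slow.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        slow = slow / sd * config.tonic_fluctuation_sd
        if config.coupling_enabled:
            # mixing sets the correlation structure of the shared
            # fluctuation; re-standardize so tonic_fluctuation_sd stays the
            # per-cell amplitude rather than being averaged away
            slow = _mix_signals(slow, w)
            sd = slow.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            slow = slow / sd * config.tonic_fluctuation_sd
        ratio = ratio * (1.0 + slow)

    # raw fluorescence: per-cell baseline level, multiplicative + additive noise
    rng_noise = stream(config.seed, "noise")
    f0 = rng_noise.uniform(*config.baseline_fluorescence, size=n)
    raw = f0[:, None] * ratio
    if config.noise_sd > 0:
        raw = raw * np.exp(
            config.noise_sd * rng_noise.standard_normal((n, n_frames))
        )
    if config.additive_noise_sd > 0:
        raw = raw + config.additive_noise_sd * rng_noise.standard_normal((n, n_frames))
    raw = np.maximum(raw, 1.0)

    ground_truth = {
        "is_responder": is_responder.tolist(),
        "response_class": classes.tolist(),
        "onset_time_s": [float(t) if r else None for t, r in zip(onset, is_responder)],
        "coupling_weights": w.tolist(),
        "config": _config_to_jsonable(config),
    }
    return RecordingDataset(
        fluorescence=raw,
        timestamps=timestamps,
        layout=layout,
        ground_truth=ground_truth,
        label=config.label,
    )


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["field_size"] = list(d["field_size"])
    d["baseline_fluorescence"] = list(d["baseline_fluorescence"])
    return d


# ---------------------------------------------------------------------------
# paired-recording simulation
# ---------------------------------------------------------------------------


def simulate_paired_recording(
    true_cc: float,
    step_amplitude_pa: float = -50.0,
    n_sweeps: int = 30,
    noise_sd_mv: float = 0.1,
    seed: int = 0,
    *,
    input_resistance_mohm: float = 200.0,
    membrane_tau_ms: float = 10.0,
    holding_mv: float = -60.0,
    sample_rate_hz: float = 5000.0,
    baseline_ms: float = 100.0,
    step_ms: float = 500.0,
    post_ms: float = 200.0,
) -> PairedSweepSet:
    """Simulate a unidirectional paired current-clamp recording.

    A hyperpolarizing current step into cell 1 produces an ohmic
    steady-state deflection ``ΔV1 = R_in × I`` with first-order membrane
    kinetics; cell 2 follows with ``ΔV2 = true_cc × ΔV1`` and the same
    kinetics. Independent Gaussian noise is added per sample on both
    channels.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if true_cc < 0:
        raise ValueError("true_cc must be >= 0")
    rng = stream(seed, "paired_recording")
    dt = 1.0 / sample_rate_hz
    total_s = (baseline_ms + step_ms + post_ms) / 1000.0
    time_s = np.arange(0.0, total_s, dt)
    onset = baseline_ms / 1000.0
    dur = step_ms / 1000.0
    tau = membrane_tau_ms / 1000.0

    dv_ss = input_resistance_mohm * 1e6 * step_amplitude_pa * 1e-12 * 1e3  # mV
    wave = np.zeros_like(time_s)
    in_step = (time_s >= onset) & (time_s < onset + dur)
    after = time_s >= onset + dur
    wave[in_step] = dv_ss * (1.0 - np.exp(-(time_s[in_step] - onset) / tau))
    v_end = dv_ss * (1.0 - np.exp(-dur / tau))
    wave[after] = v_end * np.exp(-(time_s[after] - onset - dur) / tau)

    v1 = holding_mv + np.tile(wave, (n_sweeps, 1))
    v2 = holding_mv + true_cc * np.tile(wave, (n_sweeps, 1))
    if noise_sd_mv > 0:
        v1 = v1 + noise_sd_mv * rng.standard_normal(v1.shape)
        v2 = v2 + noise_sd_mv * rng.standard_normal(v2.shape)

    return PairedSweepSet(
        time_s=time_s,
        i_pa=np.full(n_sweeps, step_amplitude_pa),
        v1_mv=v1,
        v2_mv=v2,
        step_onset_s=onset,
        step_duration_s=dur,
        holding_mv=holding_mv,
        true_cc=true_cc,
    )


def simulate_paired_experiment(
    true_cc: float,
    step_amplitude_pa: float = -50.0,
    n_sweeps: int = 30,
    noise_sd_mv: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> tuple[PairedSweepSet, PairedSweepSet]:
    """Bidirectional paired experiment: inject cell 1, then cell 2.

    Returns two sweep sets, one per injection direction, with independent
    noise, both with the same (symmetric) true coupling coefficient.
    """
    a = simulate_paired_recording(
        true_cc, step_amplitude_pa, n_sweeps, noise_sd_mv, seed=2 * seed, **kwargs
    )
    b = simulate_paired_recording(
        true_cc, step_amplitude_pa, n_sweeps, noise_sd_mv, seed=2 * seed + 1, **kwargs
    )
    return a, b
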