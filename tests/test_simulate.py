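"""Generator sanity: determinism, layout geometry, ground-truth structure,
and recovery of the coupled-network correlation signature."""

import numpy as np
import pytest

from pitsync import (
    ConfigurationError,
    SimulationConfig,
    TimeWindow,
    detect_responders,
    normalize_traces,
    pairwise_correlations,
    responder_ids,
    simulate_network,
    simulate_paired_recording,
)


def small(**kw) -> SimulationConfig:
    return SimulationConfig(n_cells=25, seed=7, **kw)


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_cells", 0),
        ("frame_interval", 0.25),
        ("frame_interval", 3.0),
        ("responder_fraction", 1.5),
        ("p_biphasic", -0.1),
        ("coupling_strength", -1.0),
        ("noise_sd", -0.01),
        ("baseline_duration", 550.0),  # baseline + stimulus > total
        ("stimulus_onset", 550.0),  # onset + stimulus > total
        ("cell_radius", 0.0),
    ],
)
def test_invalid_config_error_names_field(field, value):
    cfg = SimulationConfig(**{field: value})
    with pytest.raises(ConfigurationError, match=field.split("_")[0]):
        simulate_network(cfg)


def test_identical_seed_gives_bit_identical_dataset():
    a = simulate_network(small(coupling_enabled=True))
    b = simulate_network(small(coupling_enabled=True))
    assert np.array_equal(a.fluorescence, b.fluorescence)
    assert np.array_equal(a.layout.x, b.layout.x)
    assert a.ground_truth == b.ground_truth
    c = simulate_network(small(coupling_enabled=True).with_(seed=8))
    assert not np.array_equal(a.fluorescence, c.fluorescence)


def test_layout_hard_core_and_bounds():
    ds = simulate_network(small())
    lay = ds.layout
    d = lay.centroid_distances()
    off_diag = d[~np.eye(len(lay), dtype=bool)]
    assert off_diag.min() >= 2 * lay.radius[0]
    assert (lay.x >= lay.radius).all() and (lay.x <= 150 - lay.radius[0]).all()
    assert (lay.y >= lay.radius).all() and (lay.y <= 150 - lay.radius[0]).all()


def test_coupling_graph_symmetric_zero_diagonal():
    ds = simulate_network(small(coupling_enabled=True))
    w = np.asarray(ds.ground_truth["coupling_weights"])
    assert np.allclose(w, w.T)
    assert np.all(np.diag(w) == 0)
    assert np.all(w >= 0) and np.all(np.isfinite(w))
    # distance dependence: nearest pair couples harder than farthest pair
    d = ds.layout.membrane_distances()
    iu = np.triu_indices(len(ds.layout), 1)
    assert w[iu][np.argmin(d[iu])] > w[iu][np.argmax(d[iu])]


def test_zero_responder_fraction_gives_flat_field():
    ds = simulate_network(small(responder_fraction=0.0))
    traces = normalize_traces(ds)
    calls = detect_responders(traces, (240.0, 360.0))
    assert sum(c.is_responder for c in calls) == 0
    assert all(c.response_class == "none" for c in calls)


def test_noise_free_single_class_traces_identical_without_jitter():
    cfg = small(
        noise_sd=0.0,
        additive_noise_sd=0.0,
        coupling_strength=0.0,
        p_biphasic=1.0,
        responder_fraction=1.0,
        response_latency_jitter_sd=0.0,
        latency_gradient=0.0,
    )
    ds = simulate_network(cfg)
    ratios = normalize_traces(ds).ratios
    assert np.allclose(ratios, ratios[0], atol=1e-12)


def test_timestamps_uniform_and_fluorescence_positive():
    ds = simulate_network(small(frame_interval=2.0))
    assert np.all(ds.fluorescence > 0)
    dt = np.diff(ds.timestamps)
    assert np.allclose(dt, 2.0)


def _median_during_rho(coupled: bool, seed: int, n_cells: int = 60) -> float:
    cfg = SimulationConfig(n_cells=n_cells, coupling_enabled=coupled, seed=seed)
    ds = simulate_network(cfg)
    traces = normalize_traces(ds)
    ids = responder_ids(detect_responders(traces, (240.0, 360.0)))
    pairs = pairwise_correlations(traces, ids, TimeWindow.during(), ds.layout)
    return float(np.nanmedian([p.rho for p in pairs]))


def test_coupling_raises_during_window_synchrony():
    """Parameter-recovery oracle: the coupled arm shows a higher median
    during-window Spearman rho than the uncoupled arm in >=9/10 seeds."""
    wins = sum(
        _median_during_rho(True, 300 + s) > _median_during_rho(False, 400 + s)
        for s in range(10)
    )
    assert wins >= 9


def test_synchrony_monotone_in_coupling_strength():
    """Mean during-window rho is non-decreasing over a coupling grid."""
    means = []
    for strength in (0.0, 0.5, 1.0):
        vals = []
        for s in range(10):
            cfg = SimulationConfig(
                n_cells=40,
                coupling_enabled=True,
                coupling_strength=strength,
                seed=500 + s,
            )
            ds = simulate_network(cfg)
            traces = normalize_traces(ds)
            ids = responder_ids(detect_responders(traces, (240.0, 360.0)))
            pairs = pairwise_correlations(traces, ids, TimeWindow.during(), ds.layout)
            vals.append(np.nanmedian([p.rho for p in pairs]))
        means.append(np.mean(vals))
    assert means[0] <= means[1] <= means[2]


def test_short_pairs_more_correlated_than_distant_pairs():
    """In coupled tonic simulations, pairs <5 μm apart (membrane) out-correlate
    pairs >50 μm apart, averaged over seeds."""
    short, far = [], []
    for s in range(5):
        cfg = SimulationConfig(
            coupling_enabled=True, tonic_coupling=True, seed=600 + s
        )
        ds = simulate_network(cfg)
        traces = normalize_traces(ds)
        ids = responder_ids(detect_responders(traces, (240.0, 360.0)))
        pairs = pairwise_correlations(traces, ids, TimeWindow.during(), ds.layout)
        short += [p.rho for p in pairs if p.distance_um < 5 and not p.degenerate]
        far += [p.rho for p in pairs if p.distance_um > 50 and not p.degenerate]
    assert np.mean(short) > np.mean(far)


# ---------------------------------------------------------------------------
# paired-recording simulator
# ---------------------------------------------------------------------------


def test_zero_cc_noise_free_follower_flat():
    s = simulate_paired_recording(0.0, noise_sd_mv=0.0, seed=1)
    assert np.allclose(s.v2_mv, s.holding_mv)
    assert not np.allclose(s.v1_mv, s.holding_mv)


def test_noise_free_deflection_ratio_exact_per_sweep():
    s = simulate_paired_recording(0.025, noise_sd_mv=0.0, n_sweeps=5, seed=1)
    d1 = s.v1_mv.min(axis=1) - s.holding_mv
    d2 = s.v2_mv.min(axis=1) - s.holding_mv
    assert np.allclose(d2 / d1, 0.025, atol=1e-12)


def test_paired_recording_validates_arguments():
    with pytest.raises(ValueError):
        simulate_paired_recording(0.025, n_sweeps=0)
    with pytest.raises(ValueError):
        simulate_paired_recording(-0.1)
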