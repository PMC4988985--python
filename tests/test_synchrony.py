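"""Spearman machinery: oracle equivalence, invariances, window handling,
heat maps and the Mann–Whitney group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pitsync import (
    PairCorrelation,
    SimulationConfig,
    TimeWindow,
    compare_groups,
    detect_responders,
    extract_window,
    normalize_traces,
    pairwise_correlations,
    responder_ids,
    simulate_network,
    spearman_rho,
    temporal_heatmap,
)
from pitsync.traces import NormalizedTraces


def brute_force_spearman(x, y) -> float:
    """Independent oracle: explicit midranks, then the Pearson formula."""

    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def make_traces(R: np.ndarray, frame_interval: float = 1.0) -> NormalizedTraces:
    return NormalizedTraces(
        ratios=R,
        timestamps=np.arange(R.shape[1]) * frame_interval,
        cell_ids=tuple(f"c{i}" for i in range(R.shape[0])),
    )


# ---------------------------------------------------------------------------
# spearman_rho
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
        ([1, 2, 3, 4], [8, 6, 4, 2], -1.0),
    ],
)
def test_spearman_closed_forms(x, y, expected):
    rho, p = spearman_rho(x, y)
    assert rho == pytest.approx(expected, abs=1e-14)
    assert p == pytest.approx(0.0, abs=1e-12)


def test_spearman_matches_brute_force_oracle_and_scipy(rng):
    for _ in range(300):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        if rng.random() < 0.3:  # inject ties
            x = np.round(x)
        rho, p = spearman_rho(x, y)
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        sp_rho, sp_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(sp_rho, abs=1e-12)
        assert p == pytest.approx(sp_p, abs=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(-10**6, 10**6), min_size=5, max_size=30, unique=True),
       st.integers(0, 2**31 - 1))
def test_spearman_invariant_under_monotone_transforms(xs, seed):
    y = np.random.default_rng(seed).normal(size=len(xs))
    # well-spaced values so the transforms stay injective in float arithmetic
    x = np.asarray(xs, dtype=float) / 1e3
    rho0, _ = spearman_rho(x, y)
    for f in (lambda v: np.exp(v / 1e3), lambda v: v**3):
        rho, _ = spearman_rho(f(x), y)
        assert rho == pytest.approx(rho0, abs=1e-12)


def test_spearman_degenerate_input_flagged():
    rho, p = spearman_rho([1.0] * 5, [1, 2, 3, 4, 5])
    assert np.isnan(rho) and np.isnan(p)
    with pytest.raises(ValueError):
        spearman_rho([1, 2], [3, 4])


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "frame_interval,window,expected",
    [(1.0, (100, 200), 100), (2.0, (250, 350), 50)],
)
def test_window_sample_counts(frame_interval, window, expected, rng):
    R = rng.uniform(0.9, 1.1, size=(2, int(600 / frame_interval)))
    traces = make_traces(R, frame_interval)
    out = extract_window(traces, TimeWindow("custom", *window))
    assert out.shape == (2, expected)


def test_window_outside_recording_errors(rng):
    traces = make_traces(rng.uniform(0.9, 1.1, size=(2, 100)))
    with pytest.raises(ValueError, match="window"):
        extract_window(traces, TimeWindow("custom", 500.0, 600.0))


# ---------------------------------------------------------------------------
# pairwise correlations
# ---------------------------------------------------------------------------


def test_pair_count_and_identical_pair(rng):
    cfg = SimulationConfig(n_cells=40, responder_fraction=1.0, seed=3)
    ds = simulate_network(cfg)
    traces = normalize_traces(ds)
    ids = list(traces.cell_ids)[:32]
    pairs = pairwise_correlations(traces, ids, TimeWindow.during(), ds.layout)
    assert len(pairs) == 32 * 31 // 2 == 496
    keys = {frozenset((p.cell_a, p.cell_b)) for p in pairs}
    assert len(keys) == 496  # no duplicated unordered pairs
    # two identical traces correlate perfectly
    traces.ratios[1] = traces.ratios[0]
    two = pairwise_correlations(traces, ids[:2], TimeWindow.during(), ds.layout)
    assert len(two) == 1 and two[0].rho == pytest.approx(1.0, abs=1e-12)


def test_pairwise_agrees_with_scalar_spearman():
    ds = simulate_network(SimulationConfig(n_cells=12, seed=9))
    traces = normalize_traces(ds)
    ids = list(traces.cell_ids)
    window = TimeWindow.during()
    pairs = pairwise_correlations(traces, ids, window, ds.layout)
    series = extract_window(traces, window)
    lookup = {cid: i for i, cid in enumerate(traces.cell_ids)}
    for p in pairs[:20]:
        rho, pv = spearman_rho(series[lookup[p.cell_a]], series[lookup[p.cell_b]])
        assert p.rho == pytest.approx(rho, abs=1e-12)
        assert p.p_value == pytest.approx(pv, abs=1e-12)


def test_uncoupled_before_window_is_null():
    meds = []
    for seed in range(10):
        ds = simulate_network(SimulationConfig(seed=900 + seed))
        traces = normalize_traces(ds)
        ids = responder_ids(detect_responders(traces, (240.0, 360.0)))
        pairs = pairwise_correlations(traces, ids, TimeWindow.before(), ds.layout)
        meds.append(np.nanmedian([p.rho for p in pairs]))
    assert abs(np.median(meds)) < 0.1


def test_fewer_than_two_responders_errors():
    ds = simulate_network(SimulationConfig(n_cells=10, seed=2))
    traces = normalize_traces(ds)
    with pytest.raises(ValueError, match="responders"):
        pairwise_correlations(traces, ["cell000"], TimeWindow.during(), ds.layout)


# ---------------------------------------------------------------------------
# temporal heat maps
# ---------------------------------------------------------------------------


def test_heatmap_symmetric_unit_diagonal_and_stimulus_rise():
    ds = simulate_network(SimulationConfig(coupling_enabled=True, seed=4))
    traces = normalize_traces(ds)
    ids = responder_ids(detect_responders(traces, (240.0, 360.0)))
    mats = temporal_heatmap(traces, ids, sliding_window_length=50.0, step=10.0)
    assert len(mats) > 10
    for m in mats[:5]:
        defined = ~np.isnan(m.rho)
        assert np.allclose(m.rho[defined], m.rho.T[defined])
        diag = np.diag(m.rho)
        assert np.allclose(diag[~np.isnan(diag)], 1.0)
    off = ~np.eye(len(ids), dtype=bool)
    pre = [np.nanmean(m.rho[off]) for m in mats if m.window_center < 200]
    stim = [np.nanmean(m.rho[off]) for m in mats if 250 <= m.window_center < 360]
    assert np.mean(stim) > np.mean(pre)


def test_heatmap_constant_traces_degenerate_and_single_responder_errors():
    R = np.ones((3, 300))
    traces = make_traces(R)
    mats = temporal_heatmap(traces, list(traces.cell_ids))
    assert all(np.isnan(m.rho).all() for m in mats)
    with pytest.raises(ValueError):
        temporal_heatmap(traces, ["c0"])


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def _pairs(rhos, window="during", group="g"):
    return [
        PairCorrelation("a", f"b{i}", window, float(r), 0.5, 10.0, group)
        for i, r in enumerate(rhos)
    ]


def test_identical_groups_not_significant(rng):
    rhos = rng.uniform(-0.5, 0.9, size=150)
    comp = compare_groups(_pairs(rhos), _pairs(rhos))
    assert comp.p_value >= 0.99
    assert comp.median_a == comp.median_b


def test_shifted_group_detected(rng):
    a = rng.normal(0.0, 0.2, size=200)
    comp = compare_groups(_pairs(a + 0.5), _pairs(a))
    assert comp.p_value < 0.001
    assert comp.median_a > comp.median_b


def test_group_comparison_input_validation(rng):
    with pytest.raises(ValueError):
        compare_groups(_pairs([]), _pairs([0.1]))
    with pytest.raises(ValueError, match="windows"):
        compare_groups(_pairs([0.1], window="before"), _pairs([0.2], window="during"))
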