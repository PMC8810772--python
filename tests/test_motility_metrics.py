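"""Displacement-module index, histograms and the rank-sum comparison."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from wormrig import motility_metrics as mm
from wormrig import robot_model as rm
from wormrig import scene_sim as sim
from wormrig import tracking_controller as tc
from wormrig.errors import InsufficientSampleError, InvalidParameterError
from wormrig.pipeline import modules_from_scene, modules_from_sessionlog

from conftest import make_small_scene


# ---------------------------------------------------------------------------
# Displacement modules
# ---------------------------------------------------------------------------

def test_module_of_a_3_4_5_displacement():
    series = mm.displacement_modules([(0, 0), (3, 4)])
    assert series.modules.tolist() == [5.0]


def test_constant_position_gives_zero_modules():
    series = mm.displacement_modules([(2, 2)] * 5)
    assert np.all(series.modules == 0.0)


def test_hand_evaluated_module_sequence():
    series = mm.displacement_modules([(0, 0), (1, 1), (1, 3)])
    assert series.modules == pytest.approx([math.sqrt(2), 2.0])
    assert series.total == pytest.approx(3.41421356, abs=1e-6)


def test_deltas_mode_matches_positions_mode():
    pos = np.array([(0, 0), (2, 1), (5, 5), (5, 5)], dtype=float)
    a = mm.displacement_modules(pos)
    b = mm.displacement_modules(np.diff(pos, axis=0), kind="deltas")
    assert np.allclose(a.modules, b.modules)


def test_empty_input_rejected():
    with pytest.raises(InvalidParameterError):
        mm.displacement_modules(np.empty((0, 2)))
    with pytest.raises(InvalidParameterError):
        mm.displacement_modules([(1, 1)])  # single position: no displacement


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000),
       st.floats(-100, 100, allow_nan=False),
       st.floats(-100, 100, allow_nan=False),
       st.floats(-5, 5, allow_nan=False))
def test_modules_translation_invariant_and_scale_covariant(seed, tx, ty, c):
    rng = np.random.default_rng(seed)
    pos = rng.normal(size=(10, 2)) * 10
    base = mm.displacement_modules(pos).modules
    shifted = mm.displacement_modules(pos + [tx, ty]).modules
    assert np.allclose(shifted, base, atol=1e-8)
    scaled = mm.displacement_modules(pos * c).modules
    assert np.allclose(scaled, abs(c) * base, atol=1e-8)


# ---------------------------------------------------------------------------
# Percentages and histograms
# ---------------------------------------------------------------------------

def _series(worm_id, values):
    return mm.ModuleSeries(worm_id=worm_id, modules=np.asarray(values, float))


def test_single_worm_is_the_100_percent_anchor():
    pct = mm.module_sum_percent([_series(0, [1, 2, 3])])
    assert pct == {0: 100.0}


def test_zero_worm_is_zero_percent():
    pct = mm.module_sum_percent([_series(0, [5, 5]), _series(1, [0, 0])])
    assert pct[1] == 0.0


def test_percent_of_maximum_normalization():
    pct = mm.module_sum_percent([_series(0, [10]), _series(1, [5]),
                                 _series(2, [0])])
    assert pct == {0: 100.0, 1: 50.0, 2: 0.0}


def test_group_total_normalization():
    pct = mm.module_sum_percent([_series(0, [10]), _series(1, [5]),
                                 _series(2, [5])],
                                normalization="group_total")
    assert pct == {0: 50.0, 1: 25.0, 2: 25.0}


def test_relative_frequency_static_worm():
    freq = mm.relative_frequency(_series(0, [0.5] * 8))
    assert freq[0] == 1.0 and freq.sum() == pytest.approx(1.0)


def test_relative_frequency_direct_count():
    spec = mm.HistogramSpec(bin_edges=(0, 1, 2, 3, 4))
    freq = mm.relative_frequency([0.5, 1.5, 1.6, 3.2], spec)
    assert freq.tolist() == [0.25, 0.5, 0.0, 0.25, 0.0]


def test_overflow_bin_collects_tail():
    spec = mm.HistogramSpec(bin_edges=(0, 1, 2))
    freq = mm.relative_frequency([0.5, 50.0, 99.0], spec)
    assert freq[-1] == pytest.approx(2 / 3)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 200))
def test_histogram_is_probability_vector(seed, n):
    rng = np.random.default_rng(seed)
    freq = mm.relative_frequency(rng.exponential(3.0, n))
    assert np.all(freq >= 0)
    assert freq.sum() == pytest.approx(1.0, abs=1e-9)


def test_histogram_spec_validation():
    with pytest.raises(InvalidParameterError):
        mm.HistogramSpec(bin_edges=(0, 0, 1))


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

def test_identical_samples_give_p_one():
    assert mm.rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0


def test_fully_separated_triples():
    """2 of 20 equally likely rank splits are as extreme: p = 0.1."""
    assert mm.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def _enumeration_oracle(a, b):
    """Independent oracle: permute the pooled data labels exhaustively."""
    pooled = np.concatenate([a, b])
    n = len(a)
    from scipy.stats import rankdata
    ranks = rankdata(pooled)
    w_obs = ranks[:n].sum()
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(idx)].sum()
        total += 1
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
    return min(1.0, 2 * min(le, ge) / total)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10_000))
def test_exact_branch_equals_enumeration_oracle(n, m, seed):
    rng = np.random.default_rng(seed)
    a = np.round(rng.normal(size=n), 1)  # rounding induces occasional ties
    b = np.round(rng.normal(size=m), 1)
    assert mm.rank_sum_test(a, b) == pytest.approx(
        _enumeration_oracle(a, b), abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 10_000))
def test_exact_branch_matches_scipy_exact(n, m, seed):
    """Cross-check against the library implementation on tie-free data."""
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=n), rng.normal(size=m)
    expected = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert mm.rank_sum_test(a, b) == pytest.approx(expected.pvalue, abs=1e-9)


def test_exact_and_normal_branches_agree():
    """At n = m = 8 the two computation routes differ by < 0.02."""
    rng = np.random.default_rng(3)
    from wormrig.motility_metrics import _exact_p, _normal_approx_p
    from scipy.stats import rankdata
    for _ in range(20):
        a, b = rng.normal(size=8), rng.normal(size=8)
        ranks = rankdata(np.concatenate([a, b]))
        w = float(ranks[:8].sum())
        assert abs(_exact_p(ranks, 8, w)
                   - _normal_approx_p(ranks, 8, 8, w)) < 0.02


def test_empty_sample_rejected():
    with pytest.raises(InvalidParameterError):
        mm.rank_sum_test([], [1, 2])


# ---------------------------------------------------------------------------
# Strain comparison
# ---------------------------------------------------------------------------

def _strain_modules(model, n_worms, seed, duration=30.0):
    scene = sim.simulate_trajectories([model], n_worms, duration=duration,
                                      dt=0.5, seed=seed)
    return modules_from_scene(scene, sample_dt=0.5)


def test_exchangeable_groups_not_significant():
    """The same worms split into two identical 'strains' give large p."""
    series = _strain_modules(sim.WT_LIKE, 12, seed=5)
    groups = {"a": series, "b": [mm.ModuleSeries(s.worm_id + 100, s.modules,
                                                 "b") for s in series]}
    report = mm.compare_strains(groups)
    assert report.p_values[("a", "b")] > 0.9


def test_wt_vs_severe_always_significant():
    for seed in range(5):
        groups = {
            "wt": _strain_modules(sim.WT_LIKE, 30, seed=seed),
            "unc": _strain_modules(sim.SEVERE_UNCOORDINATED, 30, seed=seed)}
        report = mm.compare_strains(groups)
        assert report.p_values[("wt", "unc")] < 0.05


def test_severe_strain_concentrates_in_lowest_bin():
    """Module histograms mirror motility: the uncoordinated strain piles up
    in the [0-1) step bin, the wild-type-like strain the least."""
    groups = {name: _strain_modules(model, 20, seed=9)
              for name, model in sim.STRAIN_PRESETS.items()}
    report = mm.compare_strains(groups)
    low_bin = {s: h[0] for s, h in report.histograms.items()}
    assert low_bin["severe-unc"] > low_bin["mild-deficit"] > low_bin["wt-like"]


def test_single_worm_strain_rejected():
    groups = {"a": [_series(0, [1, 2])], "b": [_series(1, [1]),
                                               _series(2, [2])]}
    with pytest.raises(InsufficientSampleError):
        mm.compare_strains(groups)
    with pytest.raises(InsufficientSampleError):
        mm.compare_strains({"only": [_series(0, [1]), _series(1, [2])]})


def test_report_serialization_round_trips():
    groups = {"wt": _strain_modules(sim.WT_LIKE, 4, seed=2),
              "unc": _strain_modules(sim.SEVERE_UNCOORDINATED, 4, seed=2)}
    report = mm.compare_strains(groups)
    d = report.to_dict()
    assert set(d["histograms"]) == {"wt-like", "severe-unc"} or \
        set(d["histograms"]) == {"wt", "unc"}
    for freqs in d["histograms"].values():
        assert sum(freqs) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Pipeline consistency: session-log modules vs ground truth
# ---------------------------------------------------------------------------

def test_sessionlog_modules_match_ground_truth(controller_config):
    """Control-action modules equal ground-truth displacement modules to
    within step quantization at every instant."""
    model = sim.StrainMotilityModel("slow", speed_scale=50.0, seed=1)
    scene = make_small_scene([model], 1, duration=60, seed=8)
    log, _, frames = tc.run_session(scene, controller_config)
    assert len(frames[0]) == 60
    logged = modules_from_sessionlog(log)[0]
    ts = np.array(log.capture_times[0])
    worm = scene.worms[0]
    pos = np.array([worm.position_at(t, scene.dt)
                    for t in np.concatenate([[ts[0] - 0.5], ts])])
    pos_steps = pos / rm.STEP_SIZE_MM
    truth = mm.displacement_modules(pos_steps).modules
    # per-instant agreement within quantization (residual carry <= 1 step/axis)
    assert np.max(np.abs(logged.modules - truth)) <= 2.0
    assert np.mean(np.abs(logged.modules - truth)) <= 1.0
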