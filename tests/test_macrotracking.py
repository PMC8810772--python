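"""Adaptive segmentation, size classification and identity association."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormrig import macrotracking as mt
from wormrig import scene_sim as sim
from wormrig.errors import InvalidParameterError
from wormrig.scene_sim import CameraModel, Frame

from conftest import make_small_scene


def _frame(pixels):
    cam = CameraModel(scale=27.31, image_size=np.asarray(pixels).shape)
    return Frame(pixels=np.asarray(pixels, dtype=float), t=0.0, camera=cam,
                 kind="macro")


PARAMS = mt.SegmentationParams(window=25, offset=15.0, min_area=10,
                               max_area=5000, max_jump=60.0)


def test_uniform_frame_segments_to_nothing():
    mask = mt.segment_adaptive(_frame(np.full((64, 64), 180.0)), PARAMS)
    assert not mask.any()


def test_window_larger_than_image_rejected():
    with pytest.raises(InvalidParameterError):
        mt.segment_adaptive(_frame(np.full((16, 16), 180.0)),
                            mt.SegmentationParams(window=25))


def test_params_validation():
    with pytest.raises(InvalidParameterError):
        mt.SegmentationParams(window=4)
    with pytest.raises(InvalidParameterError):
        mt.SegmentationParams(min_area=100, max_area=50)


def _disc_image(background, centre, radius, depth):
    img = np.array(background, dtype=float)
    yy, xx = np.ogrid[0:img.shape[0], 0:img.shape[1]]
    disc = np.hypot(xx - centre[0], yy - centre[1]) <= radius
    img[disc] -= depth
    return img, disc


def test_dark_disc_matches_global_threshold_oracle():
    """On a uniform background the adaptive result equals global thresholding."""
    img, disc = _disc_image(np.full((96, 96), 180.0), (48, 48), 8, 50.0)
    mask = mt.segment_adaptive(_frame(img), PARAMS)
    global_mask = img < 180.0 - PARAMS.offset  # oracle: global threshold
    assert np.array_equal(mask, global_mask)
    dets = mt.classify_by_size(mask, PARAMS)
    assert len(dets) == 1
    assert dets[0].centroid == pytest.approx((48, 48), abs=0.5)


def test_ramp_defeats_global_threshold_but_not_adaptive():
    """Illumination ramp steeper than the worm contrast: no single global
    threshold isolates the disc, the local-mean threshold does."""
    cols = np.linspace(100.0, 220.0, 128)
    ramp = np.tile(cols, (128, 1))
    img, disc = _disc_image(ramp, (64, 64), 6, 40.0)
    # oracle: every global threshold fails to produce exactly the disc
    for thr in np.arange(90.0, 225.0, 1.0):
        assert not np.array_equal(img < thr, disc)
    mask = mt.segment_adaptive(_frame(img), PARAMS)
    dets = mt.classify_by_size(mask, PARAMS)
    assert len(dets) == 1
    assert dets[0].centroid == pytest.approx((64, 64), abs=1.0)


def test_classify_by_size_gate():
    img = np.zeros((64, 200), dtype=int)
    img[2:3, 0:2] = 1  # area 2
    img[10:14, 10:20] = 2  # area 40
    img[20:60, 50:175] = 3  # area 5000
    params = mt.SegmentationParams(min_area=10, max_area=600)
    dets = mt.classify_by_size(img, params)
    assert [d.area for d in dets] == [40]


def test_classify_empty_mask():
    assert mt.classify_by_size(np.zeros((32, 32), dtype=bool), PARAMS) == []


def test_rendered_worm_area_within_default_gate():
    """A 1 mm worm at macro resolution falls in the default [20, 600] gate."""
    model = sim.StrainMotilityModel("still", speed_scale=0.0)
    scene = make_small_scene([model], 1, duration=1.0, seed=3,
                             body_length=1.0)
    frame = sim.render_macro_frame(scene, 0.0,
                                   camera=sim.macro_camera((400, 400)))
    params = mt.SegmentationParams()  # defaults: [20, 600]
    dets = mt.classify_by_size(mt.segment_adaptive(frame, params), params)
    assert len(dets) == 1
    assert 20 <= dets[0].area <= 600


# ---------------------------------------------------------------------------
# Identity association
# ---------------------------------------------------------------------------

def _det(x, y):
    return mt.Detection(centroid=(float(x), float(y)), area=50,
                        bbox=(0, 0, 1, 1))


def _brute_force(prev, current, max_jump):
    """Oracle: exhaustive minimum-total-distance assignment, then gating."""
    n, m = len(prev), len(current)
    k = min(n, m)
    best, best_cost = None, np.inf
    if n <= m:
        pairings = (tuple(zip(range(n), cols))
                    for cols in itertools.permutations(range(m), k))
    else:
        pairings = (tuple(zip(rows, range(m)))
                    for rows in itertools.permutations(range(n), k))
    for pairing in pairings:
        cost = sum(np.hypot(prev[r][1][0] - current[c].centroid[0],
                            prev[r][1][1] - current[c].centroid[1])
                   for r, c in pairing)
        if cost < best_cost - 1e-12:
            best_cost, best = cost, list(pairing)
    assignment = {prev[r][0]: c for r, c in best
                  if np.hypot(prev[r][1][0] - current[c].centroid[0],
                              prev[r][1][1] - current[c].centroid[1])
                  <= max_jump}
    return assignment


def test_single_worm_small_step_keeps_id():
    assignment, censored, new = mt.associate_identities(
        [(7, (10.0, 10.0))], [_det(12, 11)], max_jump=60)
    assert list(assignment) == [7] and not censored and not new


def test_two_worms_match_brute_force():
    prev = [(0, (10.0, 10.0)), (1, (100.0, 100.0))]
    current = [_det(103, 99), _det(12, 13)]
    assignment, censored, new = mt.associate_identities(prev, current, 60)
    oracle = _brute_force(prev, current, 60)
    assert {k: current[v].centroid for k, v in oracle.items()} == \
        {k: d.centroid for k, d in assignment.items()}
    assert not censored and not new


def test_merge_censors_the_farther_identity():
    """Two worms merging into one blob: nearer id continues, other censored."""
    prev = [(0, (10.0, 10.0)), (1, (40.0, 10.0))]
    current = [_det(14, 10)]
    assignment, censored, new = mt.associate_identities(prev, current, 60)
    assert list(assignment) == [0]
    assert censored == [1]
    assert not new


def test_long_jump_breaks_identity_and_spawns_new():
    assignment, censored, new = mt.associate_identities(
        [(3, (10.0, 10.0))], [_det(300, 300)], max_jump=60)
    assert not assignment
    assert censored == [3]
    assert len(new) == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10_000))
def test_association_equals_brute_force_oracle(n_prev, n_cur, seed):
    """Optimal matching equals exhaustive enumeration for <= 6 objects."""
    rng = np.random.default_rng(seed)
    prev = [(i, tuple(rng.uniform(0, 500, 2))) for i in range(n_prev)]
    current = [_det(*rng.uniform(0, 500, 2)) for _ in range(n_cur)]
    assignment, _, _ = mt.associate_identities(prev, current, max_jump=1e9)
    oracle = _brute_force(prev, current, max_jump=1e9)
    assert {k: d.centroid for k, d in assignment.items()} == \
        {k: current[v].centroid for k, v in oracle.items()}


# ---------------------------------------------------------------------------
# End-to-end against simulator ground truth
# ---------------------------------------------------------------------------

def _separated_scene(n_worms, duration, min_sep_mm, seed0=0):
    """First seed whose worms stay pairwise farther than min_sep_mm apart."""
    model = sim.StrainMotilityModel("wt-slowish", speed_scale=80.0,
                                    pause_prob=0.05, seed=1)
    for seed in range(seed0, seed0 + 50):
        scene = make_small_scene([model], n_worms, duration, seed,
                                 plate_radius=8.0, body_length=1.0)
        ok = True
        for t in scene.times:
            pos = scene.positions_at(t)
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            if np.min(d[np.triu_indices(n_worms, 1)]) < min_sep_mm:
                ok = False
                break
        if ok:
            return scene
    raise AssertionError("no separated scene found")


def test_identity_tracks_ground_truth_on_separated_scene():
    """Worms > 2*max_jump apart: every identity matches truth on all frames."""
    params = mt.SegmentationParams()
    cam = sim.macro_camera((640, 640))
    max_jump_mm = params.max_jump * cam.scale_mm
    scene = _separated_scene(3, duration=30, min_sep_mm=2 * max_jump_mm)
    table = mt.TrackTable()
    for t in np.arange(0.0, scene.duration + 1e-9, 1.0):
        frame = sim.render_macro_frame(scene, t, camera=cam)
        dets = mt.classify_by_size(mt.segment_adaptive(frame, params),
                                   params, frame_t=t)
        assert len(dets) == 3  # count recovered exactly
        table.update(dets, t, params.max_jump)
    assert not table.censored
    assert len(table.tracks) == 3
    # match each track to its ground-truth worm on every frame
    for wid, dets in table.tracks.items():
        first_world = cam.pixel_to_world(np.array(dets[0].centroid))
        truth = min(scene.worms, key=lambda w: np.linalg.norm(
            w.positions[0] - first_world))
        for det in dets:
            world = cam.pixel_to_world(np.array(det.centroid))
            gt = truth.position_at(det.frame_t, scene.dt)
            assert np.linalg.norm(world - gt) < 3 * cam.scale_mm


def test_tracktable_roundtrip_dataframe():
    table = mt.TrackTable()
    table.update([_det(10, 10), _det(100, 100)], 0.0, 60)
    table.update([_det(12, 11), _det(101, 102)], 1.0, 60)
    df = table.to_dataframe()
    assert set(df.columns) == {"worm_id", "t", "cx_pxl", "cy_pxl", "area",
                               "censored"}
    assert len(df) == 4
    assert sorted(df["worm_id"].unique()) == [0, 1]
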