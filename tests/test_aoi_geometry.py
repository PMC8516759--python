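"""AOI construction from head keypoints: orientation, width, box geometry."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from facegaze.aoi_geometry import (
    AoiParams,
    FaceOrientation,
    HeadKeypoints,
    UndetectedHeadError,
    build_aoi,
    classify_orientation,
    head_width,
)


def kp_with_visible(points, frame=0, person=0):
    """HeadKeypoints with the given visible (x, y) points filling the first
    slots; remaining landmarks invisible."""
    xs = [0.0] * 5
    ys = [0.0] * 5
    vis = [False] * 5
    for i, (x, y) in enumerate(points):
        xs[i], ys[i], vis[i] = x, y, True
    return HeadKeypoints(frame, person, tuple(xs), tuple(ys), tuple(vis))


# strategy: 2..5 visible points at distinct-ish pixel positions
coords = st.floats(min_value=0, max_value=2000, allow_nan=False)
point = st.tuples(coords, coords)
visible_sets = st.lists(point, min_size=2, max_size=5)


@pytest.mark.parametrize(
    "n_visible, expected",
    [
        (5, FaceOrientation.FRONTAL),
        (4, FaceOrientation.PROFILE),
        (3, FaceOrientation.PROFILE),
        (2, FaceOrientation.PROFILE),
        (1, FaceOrientation.UNDETECTED),
        (0, FaceOrientation.UNDETECTED),
    ],
)
def test_orientation_from_visibility_count(n_visible, expected):
    kp = kp_with_visible([(10.0 * i, 5.0 * i) for i in range(n_visible)])
    assert classify_orientation(kp) is expected


def test_head_width_is_largest_pairwise_distance():
    assert head_width(kp_with_visible([(0, 0), (3, 4)])) == pytest.approx(5.0)
    collinear = [(0, 0), (10, 0), (20, 0), (30, 0), (40, 0)]
    assert head_width(kp_with_visible(collinear)) == pytest.approx(40.0)


@given(visible_sets)
def test_head_width_matches_brute_force(points):
    kp = kp_with_visible(points)
    brute = max(
        math.dist(a, b) for i, a in enumerate(points) for b in points[i:]
    )
    assert head_width(kp) == pytest.approx(brute)


def test_head_width_requires_two_visible_points():
    with pytest.raises(UndetectedHeadError):
        head_width(kp_with_visible([(5, 5)]))


def test_build_aoi_profile_example():
    kp = kp_with_visible([(0, 0), (30, 0)])
    params = AoiParams(aspect_ratio_profile=1.0, margin_profile=1.0,
                       center_offset_profile=0.0)
    aoi = build_aoi(kp, params)
    assert (aoi.center_x, aoi.center_y) == (15.0, 0.0)
    assert aoi.width == pytest.approx(30.0)
    assert aoi.height == pytest.approx(30.0)
    assert aoi.shape == "rectangle"


def test_build_aoi_frontal_scaling():
    # frontal head of span 30 px with aspect 1.2 and margin 1.1
    pts = [(0, 0), (30, 0), (15, 5), (10, 2), (20, 2)]
    kp = kp_with_visible(pts)
    assert classify_orientation(kp) is FaceOrientation.FRONTAL
    params = AoiParams(aspect_ratio_frontal=1.2, margin_frontal=1.1)
    aoi = build_aoi(kp, params)
    assert aoi.width == pytest.approx(33.0)
    assert aoi.height == pytest.approx(39.6)


def test_build_aoi_undetected_returns_none():
    assert build_aoi(kp_with_visible([(5, 5)]), AoiParams()) is None
    assert build_aoi(kp_with_visible([]), AoiParams()) is None


def test_center_offset_shifts_center_downward():
    kp = kp_with_visible([(0, 100), (30, 100)])
    base = build_aoi(kp, AoiParams(center_offset_profile=0.0))
    shifted = build_aoi(kp, AoiParams(center_offset_profile=0.25))
    assert shifted.center_y == pytest.approx(base.center_y + 0.25 * base.height)
    assert shifted.center_x == base.center_x


@given(visible_sets, st.floats(min_value=1.0, max_value=3.0),
       st.floats(min_value=0.05, max_value=2.0))
def test_margin_monotone_and_aspect_height_only(points, margin, extra):
    kp = kp_with_visible(points)
    base = build_aoi(kp, AoiParams(margin_frontal=margin, margin_profile=margin))
    if base is None:  # coincident points: degenerate, no AOI
        return
    bigger = build_aoi(kp, AoiParams(margin_frontal=margin + extra,
                                     margin_profile=margin + extra))
    assert bigger.width > base.width and bigger.height > base.height
    taller = build_aoi(kp, AoiParams(
        margin_frontal=margin, margin_profile=margin,
        aspect_ratio_frontal=1.4 + extra, aspect_ratio_profile=1.2 + extra))
    assert taller.width == pytest.approx(base.width)
    assert taller.height > base.height


@given(visible_sets)
def test_aoi_contains_all_visible_keypoints(points):
    """The centroid of n points lies within (n-1)/n of the diameter of every
    point, so with margin >= 1.6 (and aspect >= 1, no offset) the box is
    guaranteed to cover every visible landmark."""
    kp = kp_with_visible(points)
    aoi = build_aoi(kp, AoiParams(margin_frontal=1.6, margin_profile=1.6,
                                  aspect_ratio_frontal=1.0,
                                  aspect_ratio_profile=1.0))
    if aoi is None:
        return
    eps = 1e-6 * max(1.0, aoi.width)
    for x, y in kp.visible_points():
        assert abs(x - aoi.center_x) <= aoi.width / 2 + eps
        assert abs(y - aoi.center_y) <= aoi.height / 2 + eps


def test_two_point_aoi_contains_points_at_unit_margin():
    # with two points the centroid is the midpoint, so margin 1 suffices
    kp = kp_with_visible([(3, 7), (40, 31)])
    aoi = build_aoi(kp, AoiParams(margin_profile=1.0, aspect_ratio_profile=1.0))
    for x, y in kp.visible_points():
        assert abs(x - aoi.center_x) <= aoi.width / 2 + 1e-9
        assert abs(y - aoi.center_y) <= aoi.height / 2 + 1e-9


@given(visible_sets, st.floats(min_value=0, max_value=500),
       st.floats(min_value=0, max_value=500))
def test_translation_equivariance(points, dx, dy):
    kp = kp_with_visible(points)
    moved = kp_with_visible([(x + dx, y + dy) for x, y in points])
    params = AoiParams(center_offset_frontal=0.1, center_offset_profile=-0.1)
    a = build_aoi(kp, params)
    b = build_aoi(moved, params)
    if a is None:
        assert b is None
        return
    assert b.center_x == pytest.approx(a.center_x + dx, abs=1e-6)
    assert b.center_y == pytest.approx(a.center_y + dy, abs=1e-6)
    assert b.width == pytest.approx(a.width)
    assert b.height == pytest.approx(a.height)


@given(visible_sets)
def test_oval_shares_box_with_rectangle(points):
    kp = kp_with_visible(points)
    rect = build_aoi(kp, AoiParams(shape="rectangle"))
    oval = build_aoi(kp, AoiParams(shape="oval"))
    if rect is None:
        return
    assert (oval.center_x, oval.center_y) == (rect.center_x, rect.center_y)
    assert (oval.width, oval.height) == (rect.width, rect.height)
    rect_area = rect.width * rect.height
    oval_area = math.pi / 4 * oval.width * oval.height
    assert oval_area == pytest.approx(math.pi / 4 * rect_area)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        AoiParams(aspect_ratio_frontal=0)
    with pytest.raises(ValueError):
        AoiParams(margin_profile=-1)
    with pytest.raises(ValueError):
        AoiParams(center_offset_frontal=1.5)
    with pytest.raises(ValueError):
        AoiParams(shape="triangle")


def test_visible_landmarks_must_have_valid_coordinates():
    with pytest.raises(ValueError):
        HeadKeypoints(0, 0, (float("nan"), 0, 0, 0, 0), (0,) * 5,
                      (True, False, False, False, False))
    with pytest.raises(ValueError):
        HeadKeypoints(0, 0, (-1, 0, 0, 0, 0), (0,) * 5,
                      (True, False, False, False, False))
    # invisible slots may hold anything
    HeadKeypoints(0, 0, (0,) * 5, (0,) * 5, (False,) * 5)
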