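"""Per-40-ms gaze annotation: frame bookkeeping, hit testing, timelines."""

import numpy as np
import pytest

from facegaze.aoi_geometry import Aoi
from facegaze.gaze_annotation import (
    GazeSample,
    Timeline,
    annotate_multi_class,
    annotate_single_class,
    face_gaze_duration,
    frames_for_duration,
    gaze_for_frame,
    hit_test,
)


@pytest.mark.parametrize(
    "duration_s, n_frames",
    [(421.04, 10526), (1102.76, 27569), (758.92, 18973), (1.0, 25), (0.0, 0)],
)
def test_frames_for_duration(duration_s, n_frames):
    assert frames_for_duration(duration_s) == n_frames


def test_frames_for_duration_rejects_negative():
    with pytest.raises(ValueError):
        frames_for_duration(-1.0)


class TestGazeForFrame:
    def samples(self, *ts, valid=None):
        valid = valid or [True] * len(ts)
        return [GazeSample(t, 0.0, 0.0, v) for t, v in zip(ts, valid)]

    def test_nearest_to_midpoint(self):
        s = self.samples(0, 10, 20, 30)
        assert gaze_for_frame(s, 0).timestamp_ms == 20

    def test_empty_window_is_missing(self):
        s = self.samples(0, 10, 20, 30, 100)
        assert gaze_for_frame(s, 1) is None

    def test_tie_goes_to_earlier_sample(self):
        # 15 and 25 ms are both 5 ms from the frame-0 midpoint (20 ms)
        s = self.samples(15, 25)
        assert gaze_for_frame(s, 0).timestamp_ms == 15
        # exhaustive check over the window: no sample is strictly nearer
        mid = 20
        assert all(abs(x.timestamp_ms - mid) >= 5 for x in s)

    def test_window_is_half_open(self):
        s = self.samples(40)
        assert gaze_for_frame(s, 0) is None
        assert gaze_for_frame(s, 1).timestamp_ms == 40

    def test_invalid_samples_skipped(self):
        s = self.samples(20, 35, valid=[False, True])
        assert gaze_for_frame(s, 0).timestamp_ms == 35


class TestHitTest:
    rect = Aoi(0, "rectangle", 15, 0, 30, 30)
    oval = Aoi(0, "oval", 15, 0, 30, 30)

    def test_center_always_inside(self):
        assert hit_test(15, 0, self.rect)
        assert hit_test(15, 0, self.oval)

    def test_rectangle_corner_inclusive(self):
        assert hit_test(30, 15, self.rect)
        assert not hit_test(30.01, 15, self.rect)

    def test_oval_excludes_rectangle_corner(self):
        # corner lies at ellipse value 1 + 1 = 2 > 1
        assert not hit_test(30, 15, self.oval)
        # but includes its own boundary
        assert hit_test(30, 0, self.oval)

    def test_oval_subset_of_rectangle(self, rng):
        for _ in range(200):
            x, y = rng.uniform(-10, 40), rng.uniform(-25, 25)
            if hit_test(x, y, self.oval):
                assert hit_test(x, y, self.rect)


def _aoi(cx, cy, w=20, h=20, identity=None):
    return Aoi(0, "rectangle", cx, cy, w, h, identity)


def _midpoint_samples(points):
    """One valid sample per frame at the frame midpoint; None = no sample."""
    return [
        GazeSample(f * 40 + 20, x, y, True)
        for f, p in enumerate(points) if p is not None
        for x, y in [p]
    ]


class TestAnnotateSingleClass:
    def test_hit_and_miss_and_missing(self):
        aois = {0: [_aoi(50, 50)], 2: [_aoi(50, 50)], 3: [_aoi(50, 50)]}
        samples = _midpoint_samples([(50, 50), (50, 50), (500, 500), None])
        tl = annotate_single_class(samples, aois, 4)
        # frame 0: inside -> 1; frame 1: no AOI -> 0; frame 2: outside -> 0;
        # frame 3: AOI present but gaze missing -> 0
        assert tl.labels == (1, 0, 0, 0)

    def test_any_of_several_aois_counts(self):
        aois = {0: [_aoi(500, 500), _aoi(50, 50)]}
        tl = annotate_single_class(_midpoint_samples([(50, 50)]), aois, 1)
        assert tl.labels == (1,)


class TestAnnotateMultiClass:
    def test_identity_of_hit_aoi(self):
        aois = {0: [_aoi(50, 50, identity="patient")],
                1: [_aoi(50, 50, identity="patient")]}
        samples = _midpoint_samples([(50, 50), (400, 400)])
        tl = annotate_multi_class(samples, aois, 2)
        assert tl.labels == ("patient", 0)

    def test_overlap_resolved_by_nearest_center(self):
        aois = {0: [_aoi(50, 50, w=40, h=40, identity="patient"),
                    _aoi(70, 50, w=40, h=40, identity="caregiver")]}
        # gaze at (55, 50): inside both, nearer the patient centre
        tl = annotate_multi_class(_midpoint_samples([(55, 50)]), aois, 1)
        assert tl.labels == ("patient",)
        # and the mirror point lands on the caregiver
        tl = annotate_multi_class(_midpoint_samples([(65, 50)]), aois, 1)
        assert tl.labels == ("caregiver",)

    def test_untagged_aoi_rejected(self):
        with pytest.raises(ValueError):
            annotate_multi_class(_midpoint_samples([(50, 50)]),
                                 {0: [_aoi(50, 50)]}, 1)


class TestFaceGazeDuration:
    def test_counts_nonzero_frames(self):
        assert face_gaze_duration(Timeline((1,) * 666 + (0,) * 10)) == \
            pytest.approx(26.64)
        assert face_gaze_duration(Timeline((0,) * 100)) == 0.0

    def test_identity_filter(self):
        labels = ("patient",) * 765 + ("researcher",) * 4 + (0,) * 731
        tl = Timeline(labels)
        assert face_gaze_duration(tl, "patient") == pytest.approx(30.60)
        assert face_gaze_duration(tl, "researcher") == pytest.approx(0.16)

    def test_identity_durations_conserve_total(self, rng):
        idents = ["a", "b", "c"]
        labels = tuple(rng.choice([0] + idents, size=500).tolist())
        labels = tuple(0 if lab == "0" else lab for lab in labels)
        tl = Timeline(labels)
        total = sum(face_gaze_duration(tl, i) for i in idents)
        zero = sum(1 for lab in tl if lab == 0) * 0.04
        assert total + zero == pytest.approx(tl.n_frames * 0.04)


def test_single_class_equals_collapsed_multi_class(rng):
    """Oracle equivalence on random scenes: binary annotation is the
    identity-collapsed multi-class annotation."""
    for _ in range(20):
        n_frames = 30
        aois = {}
        for f in range(n_frames):
            aois[f] = [
                _aoi(rng.uniform(0, 200), rng.uniform(0, 200),
                     w=rng.uniform(10, 80), h=rng.uniform(10, 80),
                     identity=ident)
                for ident in ("p", "q")
            ]
        samples = [
            GazeSample(f * 40 + 20, rng.uniform(0, 200), rng.uniform(0, 200))
            for f in range(n_frames)
        ]
        single = annotate_single_class(samples, aois, n_frames)
        multi = annotate_multi_class(samples, aois, n_frames)
        assert single.labels == multi.collapse_binary().labels


def test_timeline_duration_bookkeeping():
    tl = Timeline((0, 1) * 50)
    assert tl.n_frames == 100
    assert tl.duration_seconds == pytest.approx(4.0)
    assert tl.is_binary
    assert not Timeline((0, "x")).is_binary
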