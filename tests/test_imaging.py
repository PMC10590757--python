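"""Imaging chain: background, registration, detection, linking, extraction."""

import itertools

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk as disk_footprint

import vacuoscope as v
from vacuoscope.imaging import Stack

from conftest import disk_frame


class TestSubtractBackground:
    def test_constant_frame_removed(self):
        stack = Stack(np.full((3, 40, 40), 13.0))
        out = v.subtract_background(stack, radius=10)
        assert np.allclose(out.frames, 0.0)

    def test_disk_contrast_preserved(self):
        frame = disk_frame((160, 160), 80, 80, 13.5, value=50.0, background=100.0)
        out = v.subtract_background(Stack(frame[None]), radius=50)
        # oracle: explicit grayscale opening (erosion then dilation)
        footprint = disk_footprint(50)
        eroded = ndimage.grey_erosion(frame, footprint=footprint)
        opened = ndimage.grey_dilation(eroded, footprint=footprint)
        oracle = np.clip(frame - opened, 0, None)
        assert np.allclose(out.frames[0], oracle)
        assert out.frames[0][80, 80] == pytest.approx(50.0, rel=0.05)
        assert np.all(out.frames[0] >= 0)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            v.subtract_background(Stack(np.zeros((1, 30, 30))), radius=50)

    def test_default_radius_is_50(self):
        import inspect

        assert inspect.signature(v.subtract_background).parameters["radius"].default == 50


class TestRegistration:
    def test_identical_frames_zero_shift(self):
        frame = disk_frame((80, 80), 30, 40, 10.0)
        _, shifts = v.register_stack(Stack(np.stack([frame] * 4)))
        assert np.all(shifts == 0)

    def test_constructed_translation_recovered(self):
        base = disk_frame((100, 100), 45, 55, 10.0) + disk_frame((100, 100), 70, 20, 6.0)
        moved = np.roll(np.roll(base, -2, axis=0), 3, axis=1)  # dx=+3, dy=-2
        registered, shifts = v.register_stack(Stack(np.stack([base, moved])))
        assert tuple(shifts[1]) == (3, -2)
        core = np.s_[10:90, 10:90]
        assert np.allclose(registered.frames[1][core], base[core])

    def test_single_frame_is_identity(self):
        frame = disk_frame((50, 50), 25, 25, 8.0)
        registered, shifts = v.register_stack(Stack(frame[None]))
        assert shifts.shape == (1, 2) and np.all(shifts == 0)
        assert np.array_equal(registered.frames[0], frame)

    def test_registration_is_idempotent(self):
        base = disk_frame((100, 100), 45, 55, 10.0)
        moved = np.roll(base, 4, axis=1)
        registered, _ = v.register_stack(Stack(np.stack([base, moved])))
        _, shifts2 = v.register_stack(registered)
        assert np.all(shifts2 == 0)


class TestDetection:
    def test_single_disk_detected_at_center(self):
        frame = disk_frame((128, 128), 60.0, 64.0, 13.5)
        dets = v.detect_vacuoles(frame, diameter=27.0, threshold=0.3)
        assert len(dets) == 1
        assert abs(dets[0].x - 60.0) < 1.0 and abs(dets[0].y - 64.0) < 1.0
        assert dets[0].quality > 0.3

    def test_blank_frame_no_detections(self):
        assert v.detect_vacuoles(np.zeros((64, 64))) == []

    def test_two_disks_40px_apart(self):
        frame = disk_frame((128, 128), 40.0, 64.0, 13.5) + disk_frame((128, 128), 80.0, 64.0, 13.5)
        dets = v.detect_vacuoles(frame, diameter=27.0, threshold=0.3)
        assert len(dets) == 2
        xs = sorted(d.x for d in dets)
        assert xs[0] == pytest.approx(40.0, abs=1.0) and xs[1] == pytest.approx(80.0, abs=1.0)

    def test_non_finite_pixels_rejected(self):
        frame = np.zeros((32, 32))
        frame[3, 3] = np.nan
        with pytest.raises(ValueError):
            v.detect_vacuoles(frame)

    def test_log_response_peaks_at_matched_diameter(self):
        frame = disk_frame((128, 128), 64.0, 64.0, 13.5)
        qualities = {}
        for diameter in [17, 22, 27, 32, 37]:
            dets = v.detect_vacuoles(frame, diameter=diameter, threshold=0.1)
            qualities[diameter] = max(d.quality for d in dets)
        assert max(qualities, key=qualities.get) == 27


def _mk_det(frame, x, y):
    return v.Detection(frame=frame, x=x, y=y, radius=13.5, quality=1.0)


def _brute_force_frame_cost(preds_gates, dets):
    """Best one-to-one matching: maximize matches, then minimize cost."""
    best = None
    n_tr = len(preds_gates)
    for k in range(min(n_tr, len(dets)), -1, -1):
        for tr_sub in itertools.combinations(range(n_tr), k):
            for det_perm in itertools.permutations(range(len(dets)), k):
                cost = 0.0
                ok = True
                for ti, dj in zip(tr_sub, det_perm):
                    pred, gate = preds_gates[ti]
                    d2 = (pred[0] - dets[dj].x) ** 2 + (pred[1] - dets[dj].y) ** 2
                    if d2 > gate**2:
                        ok = False
                        break
                    cost += d2
                if ok and (best is None or cost < best[1]):
                    best = (k, cost)
        if best is not None:
            return best
    return (0, 0.0)


class TestLinking:
    def test_static_spot_yields_single_full_track(self):
        dets = [[_mk_det(t, 50.0, 50.0)] for t in range(8)]
        tracks = v.link_tracks(dets)
        assert len(tracks) == 1 and len(tracks[0]) == 8
        assert tracks[0].frames == list(range(8))

    def test_large_jump_terminates_track(self):
        dets = [[_mk_det(0, 10.0, 10.0)], [_mk_det(1, 45.0, 10.0)]]  # 35 px > 25 px gate
        tracks = v.link_tracks(dets)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_crossing_spots_match_brute_force_optimum(self):
        # two constant-velocity spots crossing paths within the gates
        frames = []
        for t in range(6):
            frames.append(
                [_mk_det(t, 10.0 + 8.0 * t, 30.0), _mk_det(t, 50.0 - 8.0 * t, 34.0)]
            )
        tracks = v.link_tracks(frames)
        assert len(tracks) == 2
        assert all(len(t) == 6 for t in tracks)
        # constant-velocity prediction keeps each track straight through the cross
        for tr in tracks:
            xs = [d.x for d in tr.detections]
            steps = np.diff(xs)
            assert np.allclose(steps, steps[0], atol=1e-9)

    def test_linking_cost_equals_brute_force_on_small_random_frames(self):
        rng = np.random.default_rng(0)
        for _trial in range(20):
            n0 = rng.integers(1, 6)
            frame0 = [_mk_det(0, x, y) for x, y in rng.uniform(10, 90, size=(n0, 2))]
            n1 = rng.integers(1, 6)
            frame1 = [
                _mk_det(1, x + rng.uniform(-15, 15), y + rng.uniform(-15, 15))
                for x, y in rng.uniform(10, 90, size=(n1, 2))
            ]
            tracks = v.link_tracks([frame0, frame1], initial_radius=25.0, radius=20.0)
            linked = [t for t in tracks if len(t) == 2]
            cost = sum(
                (t.detections[0].x - t.detections[1].x) ** 2
                + (t.detections[0].y - t.detections[1].y) ** 2
                for t in linked
            )
            preds_gates = [((d.x, d.y), 25.0) for d in frame0]
            k_opt, cost_opt = _brute_force_frame_cost(preds_gates, frame1)
            assert len(linked) == k_opt
            assert cost == pytest.approx(cost_opt, abs=1e-9)


class TestExtraction:
    def test_uniform_frames_give_constant_trace(self):
        stack = Stack(np.full((5, 64, 64), 3.25), dt=2.0, channel="a")
        track = v.Track(track_id=0, detections=[_mk_det(t, 32.0, 32.0) for t in range(5)])
        traces = v.extract_traces([track], {"a": stack})
        assert np.allclose(traces[0].channels["a"], 3.25)
        assert np.allclose(traces[0].times, np.arange(5) * 2.0)

    def test_constant_reference_makes_ratio_proportional(self):
        rep = Stack(np.stack([np.full((40, 40), val) for val in [1.0, 2.0, 4.0]]), dt=1.0)
        ref = Stack(np.full((3, 40, 40), 2.0), dt=1.0)
        track = v.Track(track_id=0, detections=[_mk_det(t, 20.0, 20.0) for t in range(3)])
        tr = v.extract_traces([track], {"rep": rep, "ref": ref})[0]
        assert np.allclose(tr.ratio("rep", "ref"), tr.channels["rep"] / 2.0)

    def test_out_of_frame_samples_excluded(self):
        stack = Stack(np.ones((4, 64, 64)), dt=1.0)
        dets = [_mk_det(0, 2.0, 2.0)] + [_mk_det(t, 32.0, 32.0) for t in range(1, 4)]
        tr = v.extract_traces([v.Track(track_id=0, detections=dets)], {"a": stack})[0]
        assert tr.n == 3  # the edge sample is dropped, the uniform run kept

    def test_round_trip_on_noise_free_render(self, rendered_scene):
        traces, stacks, truth = rendered_scene
        channel_stacks = {k: Stack(s, dt=2.0, channel=k) for k, s in stacks.items()}
        dets = v.detect_stack(channel_stacks["vsep"])
        tracks = v.link_tracks(dets)
        extracted = v.extract_traces(tracks, channel_stacks)
        assert len(extracted) == len(traces)
        for tr, trk in zip(extracted, tracks):
            start = np.array([trk.detections[0].x, trk.detections[0].y])
            i = int(np.argmin(np.linalg.norm(truth.centers[0] - start, axis=1)))
            for ch in ("vsep", "ref"):
                rel = np.abs(tr.channels[ch] - traces[i].channels[ch]) / traces[i].channels[ch]
                assert rel.max() < 0.01


class TestEndToEndRecovery:
    def test_all_cells_tracked_with_subpixel_accuracy(self, rendered_scene):
        traces, stacks, truth = rendered_scene
        stack = Stack(stacks["vsep"], dt=2.0, channel="vsep")
        tracks = v.link_tracks(v.detect_stack(stack))
        n_frames = stack.n_frames
        full = [t for t in tracks if len(t) == n_frames]
        assert len(full) == len(traces)
        errors = []
        for i in range(len(traces)):
            gt = truth.centers[:, i, :]
            dists = [
                np.mean(
                    np.linalg.norm(np.array([[d.x, d.y] for d in t.detections]) - gt, axis=1)
                )
                for t in full
            ]
            errors.append(min(dists))
        assert np.mean(errors) < 1.0
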