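"""Recording I/O and preprocessing: segmentation, normalization, detection, extraction."""

import numpy as np
import pytest

from gaitdmd.pressure import (
    Pass,
    PressureRecording,
    StepSignal,
    detect_steps,
    extract_step_signal,
    normalize_direction,
    preprocess_recording,
    read_frames_h5,
    read_frames_text,
    segment_passes,
    write_frames_h5,
    write_frames_text,
)


def make_rec(tensor, **kw):
    return PressureRecording(tensor=np.asarray(tensor, dtype=float), **kw)


class TestTextFormat:
    def test_roundtrip_identity(self, tmp_path, rng):
        rec = make_rec(rng.integers(0, 100, size=(3, 2, 2)).astype(float),
                       dt=0.02, cell_size=0.005)
        path = tmp_path / "rec.txt"
        write_frames_text(rec, path)
        back = read_frames_text(path)
        assert np.array_equal(back.tensor, rec.tensor)
        assert back.dt == rec.dt and back.cell_size == rec.cell_size

    def test_inconsistent_row_raises_with_frame(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# dt=0.02 cell=0.005 rows=2 cols=2 frames=1\n"
                        "Frame 0\n1,2\n3,4,5\n")
        with pytest.raises(ValueError, match="frame 0 row 1"):
            read_frames_text(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_frames_text(path)

    def test_missing_header_raises(self, tmp_path):
        path = tmp_path / "nohdr.txt"
        path.write_text("Frame 0\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="header"):
            read_frames_text(path)

    def test_truncated_frame_raises(self, tmp_path):
        path = tmp_path / "trunc.txt"
        path.write_text("# dt=0.02 cell=0.005 rows=2 cols=2 frames=2\n"
                        "Frame 0\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="Frame 1"):
            read_frames_text(path)


class TestH5Format:
    def test_roundtrip(self, tmp_path, rng):
        rec = make_rec(rng.random((4, 3, 5)), dt=0.02, cell_size=0.005)
        path = tmp_path / "rec.h5"
        write_frames_h5(rec, path)
        back = read_frames_h5(path)
        assert np.allclose(back.tensor, rec.tensor)
        assert back.dt == rec.dt


class TestRecordingValidation:
    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_rec(-np.ones((1, 2, 2)))

    def test_wrong_ndim_rejected(self):
        with pytest.raises(ValueError, match="3D"):
            make_rec(np.ones((2, 2)))


class TestSegmentPasses:
    def test_forced_segmentation(self):
        frames = np.zeros((22, 2, 2))
        frames[0:5] = 1.0     # 5 active
        frames[15:22] = 1.0   # 10 zeros, then 7 active
        passes = segment_passes(make_rec(frames), min_gap=5)
        assert [p.tensor.shape[0] for p in passes] == [5, 7]
        assert [p.frame_range for p in passes] == [(0, 5), (15, 22)]

    def test_no_zero_frames_single_pass(self):
        passes = segment_passes(make_rec(np.ones((8, 2, 2))), min_gap=5)
        assert len(passes) == 1 and passes[0].frame_range == (0, 8)

    def test_all_zero_recording_empty_list(self):
        assert segment_passes(make_rec(np.zeros((10, 2, 2)))) == []

    def test_short_gap_not_split(self):
        frames = np.zeros((13, 2, 2))
        frames[0:5] = 1.0
        frames[9:13] = 1.0    # 4-frame gap < min_gap
        passes = segment_passes(make_rec(frames), min_gap=5)
        assert len(passes) == 1

    def test_min_gap_validated(self):
        with pytest.raises(ValueError, match="min_gap"):
            segment_passes(make_rec(np.ones((4, 2, 2))), min_gap=0)

    def test_pass_count_matches_generator(self, small_recording):
        rec, truth = small_recording
        passes = segment_passes(rec, min_gap=5)
        assert len(passes) == 1 + max(t.pass_index for t in truth)  # 2 passes


class TestNormalizeDirection:
    def _pass(self, tensor, index):
        t = np.asarray(tensor, dtype=float)
        return Pass(tensor=t, frame_range=(0, t.shape[0]), index=index,
                    dt=0.02, cell_size=0.005)

    def test_even_pass_unchanged(self):
        p = self._pass([[[1, 2], [3, 4]]], index=0)
        assert np.array_equal(normalize_direction(p).tensor, p.tensor)

    def test_odd_pass_double_flip(self):
        p = self._pass([[[1, 2], [3, 4]]], index=1)
        assert normalize_direction(p).tensor[0].tolist() == [[4, 3], [2, 1]]

    def test_double_normalization_rejected(self):
        p = normalize_direction(self._pass([[[1, 2], [3, 4]]], index=1))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_direction(p)

    def test_flip_is_involution_and_conserves_pressure(self, rng):
        t = rng.random((3, 4, 5))
        p = self._pass(t, index=1)
        flipped = normalize_direction(p).tensor
        assert np.array_equal(flipped[:, ::-1, ::-1], t)
        assert np.allclose(flipped.sum(axis=(1, 2)), t.sum(axis=(1, 2)))


class TestDetectSteps:
    def test_counts_and_labels_match_generator(self, small_recording):
        rec, truth = small_recording
        regions = []
        for p in segment_passes(rec):
            regions += detect_steps(normalize_direction(p))
        assert len(regions) == len(truth) == 8
        feet = sorted(r.foot for r in regions)
        assert feet == sorted(t.foot for t in truth)

    def test_stance_windows_match_generator(self, small_recording):
        rec, truth = small_recording
        tmap = {(t.pass_index, t.foot, t.cycle): t for t in truth}
        for p in segment_passes(rec):
            pn = normalize_direction(p)
            for reg in detect_steps(pn):
                t = tmap[(pn.index, reg.foot, reg.cycle)]
                act = np.flatnonzero(t.values > 0.005 * t.values.max())
                start = t.start_frame + act[0] - pn.frame_range[0]
                end = t.start_frame + act[-1] + 1 - pn.frame_range[0]
                assert abs(reg.frame_range[0] - start) <= 1
                assert abs(reg.frame_range[1] - end) <= 1

    def test_blank_pass_no_steps(self):
        p = Pass(tensor=np.zeros((5, 10, 10)), frame_range=(0, 5), index=0,
                 dt=0.02, cell_size=0.005, normalized=True)
        assert detect_steps(p) == []

    def test_unnormalized_pass_rejected(self):
        p = Pass(tensor=np.ones((2, 30, 30)), frame_range=(0, 2), index=0,
                 dt=0.02, cell_size=0.005)
        with pytest.raises(ValueError, match="normalized"):
            detect_steps(p)

    def test_small_specks_ignored(self):
        t = np.zeros((3, 40, 40))
        t[:, 5:7, 5:7] = 10.0            # 4-cell speck < min_area
        t[:, 20:30, 20:28] = 50.0        # real footprint
        p = Pass(tensor=t, frame_range=(0, 3), index=0, dt=0.02,
                 cell_size=0.005, normalized=True)
        assert len(detect_steps(p, min_area=20)) == 1


class TestExtractStepSignal:
    def test_uniform_pressure_analytic_integral(self):
        # pressure P over A cells for one frame -> P * A * cell^2
        t = np.zeros((1, 30, 30))
        t[0, 10:15, 10:14] = 200.0       # 20 cells
        p = Pass(tensor=t, frame_range=(0, 1), index=0, dt=0.02,
                 cell_size=0.005, normalized=True)
        region = detect_steps(p, min_area=5)[0]
        sig = extract_step_signal(p, region, pad_to=10)
        assert sig.values[0] == pytest.approx(200.0 * 20 * 0.005**2)

    def test_padding_contract(self, small_recording):
        rec, _ = small_recording
        p = normalize_direction(segment_passes(rec)[0])
        region = detect_steps(p)[0]
        sig = extract_step_signal(p, region, pad_to=100)
        assert sig.n_frames == 100
        assert np.all(sig.values[sig.stance_len:] == 0.0)
        assert sig.stance_len == region.frame_range[1] - region.frame_range[0]

    def test_stance_longer_than_pad_raises(self, small_recording):
        rec, _ = small_recording
        p = normalize_direction(segment_passes(rec)[0])
        region = detect_steps(p)[0]
        with pytest.raises(ValueError, match="pad_to"):
            extract_step_signal(p, region, pad_to=10)


class TestStepSignal:
    def test_from_force_pads_and_zeroes(self):
        force = np.concatenate([np.full(45, 100.0), np.full(55, 0.1)])
        sig = StepSignal.from_force(force, dt=0.02, pad_to=100)
        assert sig.stance_len == 45
        assert np.all(sig.values[45:] == 0.0)

    def test_from_force_overflow_raises(self):
        with pytest.raises(ValueError, match="pad_to"):
            StepSignal.from_force(np.ones(60), dt=0.02, pad_to=50)

    def test_stance_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="stance_len"):
            StepSignal(values=np.zeros(10), dt=0.02, stance_len=11)


class TestEndToEnd:
    def test_preprocess_recovers_all_steps(self, small_recording):
        rec, truth = small_recording
        steps = preprocess_recording(rec)
        assert len(steps) == len(truth)
        assert sorted(s.foot for s in steps) == sorted(t.foot for t in truth)

    def test_force_conservation_through_pipeline(self, small_recording):
        rec, truth = small_recording
        tmap = {(t.pass_index, t.foot, t.cycle): t for t in truth}
        for p in segment_passes(rec):
            pn = normalize_direction(p)
            for reg in detect_steps(pn):
                t = tmap[(pn.index, reg.foot, reg.cycle)]
                sig = extract_step_signal(pn, reg, pad_to=100)
                det_start = pn.frame_range[0] + reg.frame_range[0]
                off = det_start - t.start_frame
                gt = t.values[off:off + 100]
                err = np.linalg.norm(sig.values[:gt.size] - gt) / np.linalg.norm(gt)
                assert err <= 0.01
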