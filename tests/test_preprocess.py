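import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qfadd.exceptions import NormalizationError, SegmentationError, ValidationError
from qfadd.preprocess import (
    AccumulationSeries,
    BleachScaling,
    DriftTrack,
    adjust_roi,
    apply_drift_correction,
    bleach_correct,
    estimate_drift,
    extract_series,
    segment_nucleus,
)
from qfadd.stack_io import ImageStack, PixelMask
from qfadd.synthgen import SynthSpec, generate_stack

META = {
    "pixel_size_nm": 86.77,
    "frame_interval_s": 2.0,
    "n_pre_damage_frames": 2,
    "damage_frame_index": 2,
}


def make_stack(frames, n_pre=2, damage=2):
    return ImageStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size_nm=86.77,
        frame_interval_s=2.0,
        n_pre_damage_frames=n_pre,
        damage_frame_index=damage,
    )


def disk_frame(shape=(64, 64), center=(32, 32), radius=20, level=100.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return level * (((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2)


class TestSegmentNucleus:
    def test_noisy_disk_high_jaccard(self, rng):
        truth = disk_frame() > 0
        frames = np.stack(
            [disk_frame() + rng.normal(0, 5, (64, 64)).clip(-50, 50) + 50 for _ in range(4)]
        )
        stack = make_stack(frames.clip(0), n_pre=4, damage=4)
        mask = segment_nucleus(stack, reference_frames=4)
        inter = (mask.grid & truth).sum()
        union = (mask.grid | truth).sum()
        assert inter / union >= 0.95

    def test_blank_frames_raise(self):
        stack = make_stack(np.zeros((4, 32, 32)), n_pre=4, damage=4)
        with pytest.raises(SegmentationError, match="no foreground"):
            segment_nucleus(stack)

    def test_small_specks_removed(self):
        frame = disk_frame(radius=15)
        frame[2:5, 2:3] = 100.0  # 3-px speck far from the disk
        frame[60:63, 60:61] = 100.0
        stack = make_stack(np.stack([frame, frame]), n_pre=2, damage=2)
        mask = segment_nucleus(stack)
        assert not mask.grid[2:5, 2:3].any()
        assert not mask.grid[60:63, 60:61].any()
        assert mask.grid[32, 32]

    def test_mask_is_single_filled_component(self):
        frame = disk_frame(radius=18)
        frame[30:34, 30:34] = 0.0  # punch a hole; segmentation must fill it
        stack = make_stack(np.stack([frame, frame]), n_pre=2, damage=2)
        mask = segment_nucleus(stack)
        assert mask.grid[31, 31]


class TestEstimateDrift:
    def test_integer_circular_shift_recovered_exactly(self, rng):
        frame0 = rng.uniform(0, 100, (48, 48))
        frames = [frame0, np.roll(frame0, (3, -2), axis=(0, 1)), np.roll(frame0, (7, 5), axis=(0, 1))]
        track = estimate_drift(make_stack(np.stack(frames)))
        assert track.shifts.tolist() == [[0, 0], [3, -2], [7, 5]]

    def test_identical_frames_zero_shift(self, rng):
        frame = rng.uniform(0, 100, (32, 32))
        track = estimate_drift(make_stack(np.stack([frame] * 5), n_pre=2, damage=2))
        assert not track.shifts.any()

    def test_shift_recovered_under_noise(self, rng):
        frame0 = disk_frame(shape=(64, 64), radius=18) + 20
        shifted = np.roll(frame0, (0, 5), axis=(0, 1))
        noisy = np.stack([f + rng.normal(0, 2.0, f.shape) for f in (frame0, shifted)])
        track = estimate_drift(make_stack(noisy.clip(0)))
        assert track.shifts[1].tolist() == [0, 5]

    @settings(deadline=None, max_examples=20)
    @given(dy=st.integers(-10, 10), dx=st.integers(-10, 10))
    def test_random_circular_shifts_exact(self, dy, dx):
        rng = np.random.default_rng(7)
        frame0 = rng.uniform(0, 100, (40, 40))
        frames = np.stack([frame0, np.roll(frame0, (dy, dx), axis=(0, 1))])
        track = estimate_drift(make_stack(frames))
        assert track.shifts[1].tolist() == [dy, dx]


class TestApplyDriftCorrection:
    def test_zero_track_is_identity(self, rng):
        stack = make_stack(rng.uniform(0, 10, (3, 16, 16)))
        out = apply_drift_correction(stack, DriftTrack(np.zeros((3, 2), int)))
        np.testing.assert_array_equal(out.frames, stack.frames)
        assert out.valid.all()

    def test_estimate_then_correct_restores_reference(self, rng):
        frame0 = rng.uniform(0, 100, (48, 48))
        frames = np.stack([frame0] + [np.roll(frame0, (k, -k), axis=(0, 1)) for k in (2, 4)])
        stack = make_stack(frames)
        corrected = apply_drift_correction(stack, estimate_drift(stack))
        for k in range(1, 3):
            sel = corrected.valid[k]
            np.testing.assert_allclose(corrected.frames[k][sel], frame0[sel])

    def test_idempotence_corrected_stack_has_zero_drift(self, rng):
        frame0 = disk_frame() + rng.uniform(0, 5, (64, 64))
        frames = np.stack([frame0, np.roll(frame0, (6, 1), axis=(0, 1))])
        stack = make_stack(frames)
        corrected = apply_drift_correction(stack, estimate_drift(stack))
        assert not estimate_drift(corrected).shifts.any()

    def test_track_length_mismatch(self, rng):
        stack = make_stack(rng.uniform(0, 10, (3, 16, 16)))
        with pytest.raises(ValidationError, match="length"):
            apply_drift_correction(stack, DriftTrack(np.zeros((2, 2), int)))


class TestBleachCorrect:
    def test_constant_stack_unit_scaling(self):
        frame = disk_frame(level=50.0)
        stack = make_stack(np.stack([frame] * 4), n_pre=2, damage=2)
        nucleus = PixelMask(grid=frame > 0, role="nucleus")
        scaling = bleach_correct(stack, nucleus, reference_frames=2)
        np.testing.assert_allclose(scaling.s, 1.0)

    def test_scaling_arithmetic(self):
        # reference nuclear intensity 1000; a frame at 800 scales by 1.25,
        # so a raw ROI reading of 80 becomes 100
        nucleus = PixelMask(grid=np.ones((10, 10), bool), role="nucleus")
        frames = np.stack([np.full((10, 10), 10.0), np.full((10, 10), 8.0)])
        stack = make_stack(frames, n_pre=1, damage=1)
        scaling = bleach_correct(stack, nucleus, reference_frames=1)
        assert scaling.I_o == pytest.approx(1000.0)
        assert scaling.s[1] == pytest.approx(1.25)
        assert scaling.s[1] * 80.0 == pytest.approx(100.0)

    def test_exponential_bleach_conservation(self):
        frame = disk_frame(level=200.0) + 10
        decay = np.exp(-0.05 * np.arange(12))
        frames = np.stack([frame * d for d in decay])
        stack = make_stack(frames, n_pre=3, damage=3)
        nucleus = PixelMask(grid=np.ones((64, 64), bool), role="nucleus")
        scaling = bleach_correct(stack, nucleus, reference_frames=3)
        corrected_totals = scaling.s * scaling.I_net
        np.testing.assert_allclose(corrected_totals, scaling.I_o, rtol=1e-9)

    def test_empty_nuclear_signal_names_frame(self):
        frames = np.stack([np.ones((8, 8)), np.zeros((8, 8))])
        stack = make_stack(frames, n_pre=1, damage=1)
        nucleus = PixelMask(grid=np.ones((8, 8), bool), role="nucleus")
        with pytest.raises(ValidationError, match="frame 1"):
            bleach_correct(stack, nucleus, reference_frames=1)

    @settings(deadline=None, max_examples=25)
    @given(
        decays=st.lists(st.floats(0.2, 1.0), min_size=2, max_size=8),
    )
    def test_conservation_property(self, decays):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 10, (16, 16))
        frames = np.stack([base * d for d in decays])
        stack = make_stack(frames, n_pre=1, damage=1)
        nucleus = PixelMask(grid=np.ones((16, 16), bool), role="nucleus")
        scaling = bleach_correct(stack, nucleus, reference_frames=1)
        np.testing.assert_allclose(scaling.s * scaling.I_net, scaling.I_o, rtol=1e-9)


class TestAdjustRoi:
    def stripe(self, height=10, shape=(64, 64), top=20):
        grid = np.zeros(shape, bool)
        grid[top : top + height, :] = True
        return PixelMask(grid=grid, role="roi")

    def test_zero_adjustment_identity(self):
        roi = self.stripe()
        out = adjust_roi(roi, 0, 0)
        np.testing.assert_array_equal(out.grid, roi.grid)

    def test_grow_y_stripe_height(self):
        out = adjust_roi(self.stripe(height=10), x_adjust=0, y_adjust=10)
        rows = np.flatnonzero(out.grid.any(axis=1))
        assert len(rows) == 30

    def test_shrink_x_rectangle_width(self):
        grid = np.zeros((64, 64), bool)
        grid[10:20, 10:50] = True  # 40 px wide
        out = adjust_roi(PixelMask(grid=grid, role="roi"), x_adjust=-10, y_adjust=0)
        cols = np.flatnonzero(out.grid.any(axis=0))
        assert len(cols) == 20

    def test_emptying_adjustment_raises(self):
        with pytest.raises(ValidationError, match="no pixels"):
            adjust_roi(self.stripe(height=4), x_adjust=0, y_adjust=-4)


class TestExtractSeries:
    def test_flat_roi_gives_unit_series(self):
        frame = np.full((16, 16), 5.0)
        stack = make_stack(np.stack([frame] * 6), n_pre=2, damage=2)
        nucleus = PixelMask(grid=np.ones((16, 16), bool), role="nucleus")
        roi = PixelMask(grid=frame > 0, role="roi")
        series = extract_series(stack, nucleus, roi, BleachScaling.identity(6))
        np.testing.assert_allclose(series.I_norm, 1.0)

    def test_normalization_arithmetic(self):
        # ROI sums 100, 100 pre-damage then 150, 200 -> 1, 1, 1.5, 2.0
        frames = np.stack([np.full((10, 10), v / 100.0) for v in (100, 100, 150, 200)])
        stack = make_stack(frames, n_pre=2, damage=2)
        nucleus = PixelMask(grid=np.ones((10, 10), bool), role="nucleus")
        roi = PixelMask(grid=np.ones((10, 10), bool), role="roi")
        series = extract_series(stack, nucleus, roi, BleachScaling.identity(4))
        np.testing.assert_allclose(series.I_norm, [1.0, 1.0, 1.5, 2.0])
        np.testing.assert_allclose(series.times, [-4.0, -2.0, 0.0, 2.0])

    def test_pre_damage_mean_is_one(self, rng):
        frames = rng.uniform(1, 10, (8, 12, 12))
        stack = make_stack(frames, n_pre=3, damage=3)
        nucleus = PixelMask(grid=np.ones((12, 12), bool), role="nucleus")
        roi_grid = np.zeros((12, 12), bool)
        roi_grid[4:8, :] = True
        series = extract_series(
            stack, nucleus, PixelMask(grid=roi_grid, role="roi"), BleachScaling.identity(8)
        )
        assert series.I_norm[:3].mean() == pytest.approx(1.0)

    def test_disjoint_roi_raises(self):
        stack = make_stack(np.ones((4, 8, 8)), n_pre=2, damage=2)
        nucleus_grid = np.zeros((8, 8), bool)
        nucleus_grid[:4] = True
        roi_grid = np.zeros((8, 8), bool)
        roi_grid[6:] = True
        with pytest.raises(ValidationError, match="intersect"):
            extract_series(
                stack,
                PixelMask(grid=nucleus_grid, role="nucleus"),
                PixelMask(grid=roi_grid, role="roi"),
                BleachScaling.identity(4),
            )

    def test_zero_predamage_raises(self):
        frames = np.zeros((4, 8, 8))
        frames[2:] = 1.0
        stack = make_stack(frames, n_pre=2, damage=2)
        full = PixelMask(grid=np.ones((8, 8), bool), role="nucleus")
        with pytest.raises(NormalizationError):
            extract_series(stack, full, PixelMask(grid=full.grid, role="roi"),
                           BleachScaling.identity(4))


class TestSeriesRoundTrip:
    def test_csv_round_trip(self, tmp_path):
        series = AccumulationSeries(
            times=np.array([-2.0, 0.0, 2.0, 4.0]),
            I_prime=np.array([10.0, 11.0, 15.0, 18.0]),
            I_norm=np.array([1.0, 1.1, 1.5, 1.8]),
            n_pre_damage_frames=1,
            raw=np.array([10.0, 11.0, 15.0, 18.0]),
        )
        series.to_csv(tmp_path / "s.csv")
        back = AccumulationSeries.from_csv(tmp_path / "s.csv")
        np.testing.assert_allclose(back.I_norm, series.I_norm)
        np.testing.assert_allclose(back.times, series.times)
        assert back.n_pre_damage_frames == 1


class TestDriftArtifactOnSynthetic:
    def test_corrected_series_monotone_raw_decays(self):
        spec = SynthSpec(
            image_shape=(120, 96),
            nucleus_center=(36, 48),
            nucleus_radii=(22, 30),
            roi_stripe_height=8,
            roi_center=(36, 48),
            true_delta_x=6,
            true_F_ppt=500,
            frame_interval_s=1.0,
            n_pre_frames=4,
            n_post_frames=24,
            drift_per_frame=(1.0, 0.0),
            n_particles=4000,
            seed=5,
        )
        stack, roi, truth = generate_stack(spec)
        identity = BleachScaling.identity(stack.n_frames)
        raw = extract_series(stack, truth["nucleus"], roi, identity)
        corrected_stack = apply_drift_correction(stack, estimate_drift(stack))
        cor = extract_series(corrected_stack, truth["nucleus"], roi, identity)
        r = raw.I_norm[raw.post_damage]
        c = cor.I_norm[cor.post_damage]
        # damage stripe drifts out of the fixed ROI: uncorrected decays late
        assert r[-1] < 0.8 * r.max()
        # corrected series keeps accumulating (no spurious dissipation)
        assert np.diff(c).min() >= -0.02 * c[-1]
        assert c[-1] == pytest.approx(c.max(), rel=0.02)
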