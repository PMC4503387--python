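"""Block matching, motion waveforms, beat detection and condition comparison."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from mpquant import (
    ImageStack,
    block_match_motion,
    compare_conditions,
    contraction_heatmap,
    detect_beats,
    motion_waveform,
)
from mpquant import synthetic as syn
from mpquant.exceptions import InsufficientDataError


def textured_frame(shape=(48, 48), seed=0, contrast=30.0):
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.normal(100.0, contrast, shape), 1.0)


# ---------------------------------------------------------------------------
# block matching
# ---------------------------------------------------------------------------

def test_identical_frames_give_zero_vectors():
    A = textured_frame()
    stack = ImageStack(np.stack([A, A, A]), frame_rate=20.0, pixel_size=1.0)
    field = block_match_motion(stack, block_size=8, search_radius=3, step=4,
                               min_std=2.0)
    assert np.all(field.vectors == 0.0)
    assert field.confident.all()


@pytest.mark.parametrize("shift", [(3, 0), (0, 2), (-2, 1), (4, -4)])
def test_pure_integer_translation_recovered_exactly(shift):
    dx, dy = shift
    A = textured_frame(seed=1)
    B = np.roll(A, (dy, dx), axis=(0, 1))
    stack = ImageStack(np.stack([A, B]), frame_rate=20.0, pixel_size=1.0)
    field = block_match_motion(stack, block_size=8, search_radius=4, step=4)
    v = field.vectors[0][field.confident[0]]
    assert len(v) > 0
    assert np.all(v == np.array([dx, dy], dtype=float))


def test_featureless_blocks_are_low_confidence():
    A = np.full((48, 48), 50.0)
    stack = ImageStack(np.stack([A, A]), frame_rate=20.0, pixel_size=1.0)
    field = block_match_motion(stack, block_size=8, search_radius=2, step=4)
    assert not field.confident.any()
    assert np.all(field.vectors == 0.0)


def test_vector_magnitude_bounded_by_search_radius():
    res = syn.simulate_beating_stack(syn.SyntheticBeatConfig(
        n_frames=60, beat_frequency=1.5, peak_velocity=10.0, seed=4))
    field = block_match_motion(res.stack, search_radius=4, step=8)
    max_um = 4 * res.stack.pixel_size * math.sqrt(2)
    assert np.linalg.norm(field.vectors, axis=-1).max() <= max_um + 1e-9


def test_subpixel_accuracy_against_analytic_field():
    """Median error below half a pixel on the synthetic beating stack."""
    cfg = syn.SyntheticBeatConfig(n_frames=100, beat_frequency=1.0,
                                  peak_velocity=10.0, seed=8)
    res = syn.simulate_beating_stack(cfg)
    field = block_match_motion(res.stack, search_radius=4, step=8)
    px = res.stack.pixel_size
    errors = []
    truth_mag = np.abs(np.diff(res.displacement_um))  # μm, uniform over disc
    c = (cfg.image_size - 1) / 2.0
    for t in range(len(truth_mag)):
        for i, by in enumerate(field.block_y):
            for j, bx in enumerate(field.block_x):
                if not field.confident[t, i, j]:
                    continue
                r = math.hypot(by - c, bx - c)
                if r < res.core_radius_px or r > res.disc_radius_px - 8:
                    continue
                d = res.displacement_um[t + 1] - res.displacement_um[t]
                ux, uy = (bx - c) / r, (by - c) / r
                true_v = np.array([d * ux, d * uy])
                errors.append(np.linalg.norm(field.vectors[t, i, j] - true_v))
    errors = np.array(errors) / px
    assert len(errors) > 500
    assert np.median(errors) < 0.5


def test_time_reversal_negates_field():
    cfg = syn.SyntheticBeatConfig(n_frames=100, beat_frequency=1.0,
                                  peak_velocity=10.0, seed=7)
    res = syn.simulate_beating_stack(cfg)
    fwd = block_match_motion(res.stack, search_radius=4, step=8)
    rev_stack = ImageStack(res.stack.frames[::-1].copy(), 20.0,
                           res.stack.pixel_size)
    rev = block_match_motion(rev_stack, search_radius=4, step=8)
    mask = fwd.confident & rev.confident[::-1]
    diff = np.abs(fwd.vectors + rev.vectors[::-1])[mask]
    px = res.stack.pixel_size
    assert np.median(diff) < 0.1 * px
    assert np.percentile(diff, 95) < 0.3 * px
    wf, wr = motion_waveform(fwd), motion_waveform(rev)
    # mean-speed magnitudes carry a small direction-dependent bias; the
    # waveform agrees within ~0.03 px/frame equivalent
    assert np.nanmedian(np.abs(wf.mean_speed - wr.mean_speed[::-1])) < 0.5


# ---------------------------------------------------------------------------
# waveform
# ---------------------------------------------------------------------------

def test_uniform_translation_waveform_arithmetic():
    """1 pixel/frame at 20 fps and 1 μm/pixel is a constant 20 μm/s."""
    base = textured_frame((64, 64), seed=3)
    frames = [np.roll(base, (0, k), axis=(0, 1)) for k in range(5)]
    stack = ImageStack(np.stack(frames), frame_rate=20.0, pixel_size=1.0)
    field = block_match_motion(stack, block_size=8, search_radius=2, step=8)
    wf = motion_waveform(field)
    assert wf.valid.all()
    assert np.allclose(wf.mean_speed, 20.0)
    assert np.allclose(wf.times, (np.arange(4) + 0.5) / 20.0)


def test_all_zero_field_gives_flat_zero_waveform():
    A = textured_frame()
    stack = ImageStack(np.stack([A] * 6), frame_rate=20.0, pixel_size=1.0)
    wf = motion_waveform(block_match_motion(stack, 8, 2, 4))
    assert np.all(wf.mean_speed == 0.0)


def test_waveform_flags_allfeatureless_frames():
    A = np.full((48, 48), 10.0)
    stack = ImageStack(np.stack([A, A]), frame_rate=20.0, pixel_size=1.0)
    wf = motion_waveform(block_match_motion(stack, 8, 2, 4))
    assert not wf.valid.any()
    assert np.isnan(wf.mean_speed).all()


# ---------------------------------------------------------------------------
# beats
# ---------------------------------------------------------------------------

def test_one_hz_stack_yields_25_contraction_peaks(beat_1hz_analysis):
    """A 1.0-Hz, 25-s recording contains 25 contraction peaks at 1.00 Hz."""
    result, field, wf = beat_1hz_analysis
    assert len(wf.contraction_peak_times) == 25
    assert wf.beat_frequency == pytest.approx(1.0, abs=0.05)
    assert wf.max_contraction_velocity == pytest.approx(10.0, rel=0.15)


def test_waveform_shows_two_humps_per_cycle(beat_1hz_analysis):
    result, field, wf = beat_1hz_analysis
    # contraction + relaxation peaks together: two per cycle over 25 s,
    # minus the edge peaks excluded by interior peak detection
    total = len(wf.contraction_peak_times) + len(wf.relaxation_peak_times)
    assert 48 <= total <= 50


def test_fft_cross_check_of_peak_interval_frequency(beat_1hz_analysis):
    """The dominant FFT line of the speed waveform sits at twice the beat
    frequency (two humps per cycle), consistent with the peak-interval
    estimate."""
    result, field, wf = beat_1hz_analysis
    s = np.where(wf.valid, wf.mean_speed, 0.0)
    s = s - s.mean()
    spectrum = np.abs(np.fft.rfft(s))
    freqs = np.fft.rfftfreq(len(s), d=1.0 / wf.frame_rate)
    dominant = freqs[np.argmax(spectrum)]
    assert dominant == pytest.approx(2.0 * wf.beat_frequency, abs=0.05)


def test_quiescent_stack_detects_no_beats():
    res = syn.simulate_beating_stack(syn.SyntheticBeatConfig(
        peak_velocity=0.0, n_frames=120, seed=5))
    wf = detect_beats(motion_waveform(
        block_match_motion(res.stack, search_radius=2, step=8)))
    assert wf.quiescent
    assert wf.beat_frequency == 0.0
    assert wf.max_contraction_velocity == 0.0


def test_frequency_ordering_between_stacks():
    freqs = {}
    for f in (0.6, 1.2):
        res = syn.simulate_beating_stack(syn.SyntheticBeatConfig(
            beat_frequency=f, peak_velocity=10.0, n_frames=200, seed=19))
        wf = detect_beats(motion_waveform(
            block_match_motion(res.stack, search_radius=4, step=8)))
        freqs[f] = wf.beat_frequency
    assert freqs[1.2] > freqs[0.6]
    assert freqs[1.2] / freqs[0.6] == pytest.approx(2.0, rel=0.05)


def test_detect_beats_needs_two_seconds():
    wf_short = motion_waveform(block_match_motion(
        syn.simulate_beating_stack(syn.SyntheticBeatConfig(
            n_frames=20, beat_frequency=2.0, peak_velocity=5.0,
            seed=1)).stack, search_radius=2, step=8))
    with pytest.raises(InsufficientDataError):
        detect_beats(wf_short)


# ---------------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------------

def test_heatmap_zero_field_is_zero():
    A = textured_frame()
    stack = ImageStack(np.stack([A] * 4), frame_rate=20.0, pixel_size=1.0)
    heat = contraction_heatmap(block_match_motion(stack, 8, 2, 4))
    assert np.all(heat == 0.0)


def test_heatmap_support_concentric_with_moving_disc(beat_1hz_analysis):
    result, field, wf = beat_1hz_analysis
    heat = contraction_heatmap(field)
    ys, xs = np.nonzero(heat > heat.max() / 2)
    cy = field.block_y[ys].mean()
    cx = field.block_x[xs].mean()
    c = (result.config.image_size - 1) / 2.0
    assert abs(cy - c) <= field.block_size
    assert abs(cx - c) <= field.block_size
    assert heat.max() >= np.nanmax(wf.mean_speed)


def test_heatmap_scales_linearly_with_peak_velocity():
    """Doubling the peak velocity doubles the heatmap over interior blocks.

    Blocks straddling the tissue rim mix moving and static content and can
    over-read, and near-core blocks span strongly varying motion
    directions, so linearity is asserted where the motion model holds: the
    annular band of blocks fully inside the disc and away from the core.
    """
    heats = {}
    for pv in (5.0, 10.0):
        cfg = syn.SyntheticBeatConfig(
            beat_frequency=1.0, peak_velocity=pv, n_frames=100, seed=33)
        res = syn.simulate_beating_stack(cfg)
        field = block_match_motion(res.stack, search_radius=4, step=8)
        heat = contraction_heatmap(field)
        c = (cfg.image_size - 1) / 2.0
        by, bx = np.meshgrid(field.block_y, field.block_x, indexing="ij")
        r = np.hypot(by - c, bx - c)
        band = (r >= 12.0) & (r <= res.disc_radius_px - field.block_size / 2)
        heats[pv] = heat[band]
    ratio = heats[10.0] / heats[5.0]
    assert np.median(ratio) == pytest.approx(2.0, rel=0.1)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def _waveform_with(freq, vel):
    from mpquant.contraction import MotionWaveform

    t = np.arange(100) / 20.0
    return MotionWaveform(times=t, mean_speed=np.zeros_like(t),
                          valid=np.ones_like(t, bool), frame_rate=20.0,
                          beat_frequency=freq, max_contraction_velocity=vel,
                          quiescent=False)


def test_identical_groups_give_p_of_one():
    grp = [_waveform_with(1.0, 10.0) for _ in range(4)]
    table = compare_conditions(grp, [_waveform_with(1.0, 10.0) for _ in range(4)])
    assert (table.pvalue == 1.0).all()
    assert table.degenerate.all()


def test_halved_groups_separate_significantly():
    rng = np.random.default_rng(0)
    a = [_waveform_with(1.0 + rng.normal(0, 0.05), 10.0 + rng.normal(0, 0.5))
         for _ in range(6)]
    b = [_waveform_with(0.5 + rng.normal(0, 0.025), 5.0 + rng.normal(0, 0.25))
         for _ in range(6)]
    table = compare_conditions(a, b, labels=("control", "drug"))
    assert (table.pvalue < 0.05).all()
    assert (table.mean_drug < table.mean_control).all()


def test_small_group_raises_naming_group():
    a = [_waveform_with(1.0, 10.0) for _ in range(3)]
    with pytest.raises(ValueError, match="drug"):
        compare_conditions(a, [_waveform_with(1.0, 10.0)],
                           labels=("control", "drug"))


def test_extra_metrics_included():
    a = [_waveform_with(1.0, 10.0) for _ in range(3)]
    b = [_waveform_with(0.9, 9.0) for _ in range(3)]
    table = compare_conditions(
        a, b, extra_a={"chamber_height_um": [200, 220, 210]},
        extra_b={"chamber_height_um": [150, 140, 160]})
    assert "chamber_height_um" in table.index
    assert table.loc["chamber_height_um", "pvalue"] < 0.05


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

def test_imagestack_tiff_round_trip(tmp_path):
    res = syn.simulate_beating_stack(syn.SyntheticBeatConfig(
        n_frames=40, image_size=32, seed=2))
    path = tmp_path / "stack.tif"
    res.stack.to_tiff(path)
    loaded = ImageStack.from_tiff(path, 20.0, 0.5)
    assert np.allclose(loaded.frames, res.stack.frames)


def test_imagestack_validation():
    with pytest.raises(ValueError):
        ImageStack(np.zeros((1, 8, 8)), 20.0, 1.0)
    with pytest.raises(ValueError):
        ImageStack(np.zeros((3, 8, 8)), -1.0, 1.0)
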