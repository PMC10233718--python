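"""Detection chain: preprocessing, peak finding (vs. oracle), refinement."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nascentquant.detection import (
    DetectionParams,
    detect_spots,
    find_peaks_max_not_mask,
    preprocess_channel,
    refine_gaussian3d,
    rolling_ball_background,
    segment_spots,
)
from nascentquant.io import ImageStack


def render_gauss3d(shape, center, amplitude, sigma_xy, sigma_z, background=0.0):
    z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    z0, y0, x0 = center
    return background + amplitude * np.exp(
        -((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma_xy ** 2)
        - ((z - z0) ** 2) / (2 * sigma_z ** 2)
    )


# ---------------------------------------------------------------------------
# rolling ball / preprocessing


def exact_ball_opening(img, radius):
    """Brute-force non-flat grayscale opening with a ball element."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = yy * yy + xx * xx <= r * r
    h = np.zeros_like(yy, dtype=float)
    h[inside] = np.sqrt(r * r - (yy * yy + xx * xx)[inside])
    ny, nx = img.shape
    pad = np.pad(img, r, mode="edge")
    eroded = np.empty_like(img, dtype=float)
    for i in range(ny):
        for j in range(nx):
            win = pad[i : i + 2 * r + 1, j : j + 2 * r + 1]
            eroded[i, j] = np.min(win[inside] - h[inside])
    pad_e = np.pad(eroded, r, mode="edge")
    opened = np.empty_like(img, dtype=float)
    for i in range(ny):
        for j in range(nx):
            win = pad_e[i : i + 2 * r + 1, j : j + 2 * r + 1]
            opened[i, j] = np.max(win[inside] + h[inside])
    return opened


class TestRollingBall:
    def test_exact_path_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, (24, 30))
        got = rolling_ball_background(img, radius=5, shrink=1)
        want = np.minimum(exact_ball_opening(img, 5), img)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_constant_image_background_is_the_image(self):
        img = np.full((40, 40), 12.5)
        np.testing.assert_allclose(rolling_ball_background(img, 15), img)

    def test_background_never_exceeds_input(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 200, (64, 64))
        bg = rolling_ball_background(img, 15)
        assert np.all(bg <= img + 1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 100, (48, 48))
        bg = rolling_ball_background(img, 15)
        bg_shifted = rolling_ball_background(img + 37.0, 15)
        np.testing.assert_allclose(bg_shifted, bg + 37.0, atol=1e-6)

    def test_shrink_path_close_to_exact(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 50, (48, 48)) + render_gauss3d(
            (1, 48, 48), (0, 24, 24), 200, 1.4, 1)[0]
        fast = rolling_ball_background(img, 15)  # shrink 2
        exact = rolling_ball_background(img, 15, shrink=1)
        # acceleration error stays small relative to the signal scale
        assert np.max(np.abs(fast - exact)) < 12.0
        assert np.mean(np.abs(fast - exact)) < 2.0


class TestPreprocess:
    def test_constant_volume_maps_to_zero(self):
        vol = np.full((4, 64, 64), 33.0)
        np.testing.assert_allclose(preprocess_channel(vol), 0.0, atol=1e-6)

    def test_offset_invariance(self):
        rng = np.random.default_rng(4)
        vol = rng.uniform(0, 100, (3, 64, 64))
        a = preprocess_channel(vol)
        b = preprocess_channel(vol + 50.0)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_spot_survives_preprocessing(self):
        vol = render_gauss3d((8, 64, 64), (4, 32, 32), 300, 1.4, 0.7, background=20)
        out = preprocess_channel(vol)
        z, y, x = np.unravel_index(np.argmax(out), out.shape)
        assert (z, y, x) == (4, 32, 32)
        assert out[4, 32, 32] > 100

    def test_too_small_field_is_error(self):
        with pytest.raises(ValueError, match="rolling-ball"):
            preprocess_channel(np.zeros((4, 16, 16)))

    def test_output_non_negative(self):
        rng = np.random.default_rng(5)
        vol = rng.uniform(0, 100, (3, 64, 64))
        assert np.min(preprocess_channel(vol)) >= 0.0


# ---------------------------------------------------------------------------
# max-not-mask vs. brute-force oracle


def oracle_max_not_mask(volume, params: DetectionParams):
    """Literal re-implementation with explicit loops over mask voxels."""
    work = np.array(volume, dtype=float)
    vmax = work.max() if work.size else 0.0
    thr = params.stop_fraction * vmax
    rz = params.mask_depth_z / 2.0
    rxy = params.mask_diameter_xy / 2.0
    nz, ny, nx = work.shape
    peaks = []
    while True:
        best = (-np.inf, None)
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    if work[z, y, x] > best[0]:
                        best = (work[z, y, x], (z, y, x))
        val, (z0, y0, x0) = best
        if val <= thr or val <= 0:
            break
        peaks.append((z0, y0, x0, val))
        for dz in range(-int(rz), int(rz) + 1):
            for dy in range(-int(rxy), int(rxy) + 1):
                for dx in range(-int(rxy), int(rxy) + 1):
                    if (dz / rz) ** 2 + (dy / rxy) ** 2 + (dx / rxy) ** 2 <= 1.0:
                        z, y, x = z0 + dz, y0 + dy, x0 + dx
                        if 0 <= z < nz and 0 <= y < ny and 0 <= x < nx:
                            work[z, y, x] = 0.0
    return peaks


class TestMaxNotMask:
    def test_single_impulse(self):
        vol = np.zeros((6, 32, 32))
        vol[3, 10, 20] = 100.0
        peaks = find_peaks_max_not_mask(vol)
        assert peaks == [(3, 10, 20, 100.0)]

    def test_close_impulses_merge_into_one_peak(self):
        vol = np.zeros((6, 64, 64))
        vol[3, 30, 30] = 100.0
        vol[3, 30, 35] = 90.0  # within the 20 px xy mask of the first
        peaks = find_peaks_max_not_mask(vol)
        assert [(p[0], p[1], p[2]) for p in peaks] == [(3, 30, 30)]

    def test_stop_fraction_floor(self):
        vol = np.zeros((6, 64, 64))
        vol[3, 10, 10] = 100.0
        vol[3, 10, 50] = 4.0  # below 5% of the max
        peaks = find_peaks_max_not_mask(vol)
        assert len(peaks) == 1

    def test_all_zero_volume_yields_no_peaks(self):
        assert find_peaks_max_not_mask(np.zeros((4, 32, 32))) == []

    def test_intensities_strictly_decreasing(self):
        rng = np.random.default_rng(6)
        vol = rng.uniform(0, 100, (8, 40, 40))
        peaks = find_peaks_max_not_mask(vol)
        vals = [p[3] for p in peaks]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_matches_oracle_on_random_volumes(self):
        params = DetectionParams()
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vol = rng.uniform(0, 100, (6, 24, 24))
            got = find_peaks_max_not_mask(vol, params)
            want = oracle_max_not_mask(vol, params)
            assert [(z, y, x) for z, y, x, _ in got] == [(z, y, x) for z, y, x, _ in want]

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           rxy=st.floats(3.0, 12.0), rz=st.floats(2.0, 5.0))
    def test_oracle_property(self, seed, rxy, rz):
        params = DetectionParams(mask_diameter_xy=2 * rxy, mask_depth_z=2 * rz)
        vol = np.random.default_rng(seed).uniform(0, 100, (5, 16, 16))
        got = find_peaks_max_not_mask(vol, params)
        want = oracle_max_not_mask(vol, params)
        assert [(z, y, x) for z, y, x, _ in got] == [(z, y, x) for z, y, x, _ in want]


# ---------------------------------------------------------------------------
# 3D Gaussian refinement


class TestRefine:
    def test_subvoxel_recovery_noiseless(self):
        center = (9.63, 31.37, 32.81)
        vol = render_gauss3d((20, 64, 64), center, 400, 1.4, 0.7, background=10)
        spot = refine_gaussian3d(vol, (10, 31, 33))
        assert spot.accepted
        assert spot.z_px == pytest.approx(center[0], abs=0.02)
        assert spot.y_px == pytest.approx(center[1], abs=0.02)
        assert spot.x_px == pytest.approx(center[2], abs=0.02)
        assert spot.amplitude == pytest.approx(400, rel=0.01)
        assert spot.background == pytest.approx(10, abs=0.5)

    def test_seed_far_from_center_hits_constraint(self):
        vol = render_gauss3d((20, 64, 64), (10, 32, 32), 400, 1.4, 0.7)
        spot = refine_gaussian3d(vol, (10, 32, 38))
        assert not spot.accepted
        assert spot.reason == "constraint"

    def test_window_outside_volume_is_edge_rejection(self):
        vol = np.zeros((20, 64, 64))
        spot = refine_gaussian3d(vol, (1, 2, 2))
        assert not spot.accepted and spot.reason == "edge"

    def test_non_finite_window_raises(self):
        vol = np.zeros((20, 64, 64))
        vol[10, 32, 32] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            refine_gaussian3d(vol, (10, 32, 32))


# ---------------------------------------------------------------------------
# segmentation detector


class TestSegmentSpots:
    def test_single_spot_centroid(self):
        vol = render_gauss3d((10, 64, 64), (5, 20.4, 40.6), 300, 1.4, 0.7)
        out = segment_spots(vol)
        assert len(out) == 1
        assert out.loc[0, "y_px"] == pytest.approx(20.4, abs=0.2)
        assert out.loc[0, "x_px"] == pytest.approx(40.6, abs=0.2)

    def test_single_voxel_component_removed(self):
        vol = render_gauss3d((10, 64, 64), (5, 20, 20), 300, 1.4, 0.7)
        vol[5, 50, 50] = vol.max() * 0.9  # isolated hot pixel
        out = segment_spots(vol, DetectionParams(size_filter=(4, 2000)))
        assert len(out) == 1
        assert abs(out.loc[0, "x_px"] - 20) < 1

    def test_oversized_component_removed(self):
        vol = np.zeros((10, 64, 64))
        vol[2:8, 10:60, 10:60] = 100.0  # way over the size filter
        out = segment_spots(vol, DetectionParams(size_filter=(2, 2000)))
        assert len(out) == 0

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        vol = rng.uniform(0, 100, (3, 24, 24))
        counts = [len(segment_spots(vol, DetectionParams(seg_threshold=t,
                                                         size_filter=(1, 10_000))))
                  for t in (0.2, 0.4, 0.6, 0.8)]
        # components only shrink or vanish but can also split; total voxel
        # mass above threshold is what must shrink
        masses = [np.sum(vol > t * vol.max()) for t in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(masses, masses[1:]))
        assert all(c >= 0 for c in counts)

    def test_empty_volume(self):
        assert len(segment_spots(np.zeros((4, 32, 32)))) == 0


# ---------------------------------------------------------------------------
# full chain on rendered data


class TestDetectSpots:
    def test_recovers_known_spots(self, noisy_section, det_params):
        params, stack, truth = noisy_section
        n_match = 0
        n_true = 0
        errs = []
        for ch in params.probe_channels:
            table = detect_spots(stack, ch, det_params)
            acc = table[table["accepted"]]
            true_ch = truth.spots[truth.spots["channel"] == ch]
            n_true += len(true_ch)
            for _, s in true_ch.iterrows():
                t_px = np.array([s.z_nm / params.voxel_size_z,
                                 s.y_nm / params.voxel_size_xy,
                                 s.x_nm / params.voxel_size_xy])
                if not len(acc):
                    continue
                got = acc[["z_px", "y_px", "x_px"]].to_numpy()
                d = np.linalg.norm((got - t_px) * np.array([1, 1, 1]), axis=1)
                if d.min() < 2.0:
                    n_match += 1
                    errs.append(np.linalg.norm((got[np.argmin(d)] - t_px)[1:]))
        assert n_true > 0
        assert n_match / n_true > 0.9
        assert np.sqrt(np.mean(np.square(errs))) < 0.3  # xy px

    def test_score_normalized_and_sorted(self, clean_section, det_params):
        params, stack, truth = clean_section
        table = detect_spots(stack, "farred", det_params)
        acc = table[table["accepted"]]
        assert len(acc) >= 1
        assert acc["score"].max() == pytest.approx(1.0)
        assert (acc["score"] > 0).all()

    def test_dim_spots_rejected_with_reason(self):
        vol = render_gauss3d((20, 64, 64), (10, 32, 32), 100, 1.4, 0.7, background=5)
        stack = ImageStack(data=vol[None], voxel_size_xy=110, voxel_size_z=1000,
                           channels=("red",))
        table = detect_spots(stack, "red", DetectionParams(min_amplitude=200.0))
        assert (table["reason"] == "dim").any()
        assert not table[table["reason"] == "dim"]["accepted"].any()
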