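import numpy as np
import pytest

from ridgewidth import phantom
from ridgewidth.errors import GeometryError, MeasurementError
from ridgewidth.grid import MeasurementLine, PositionLabel, make_central_line
from ridgewidth.volume_io import VolumeStack
from ridgewidth.width import (
    BOUNDARY_PEAK,
    EXTRA_PEAKS,
    GreyProfile,
    PeakSet,
    UNMEASURABLE,
    extract_profile,
    find_profile_peaks,
    measure_grid,
    ridge_width,
)

from conftest import truth_lookup


# ---------------------------------------------------------------------------
# Independent brute-force peak oracle
# ---------------------------------------------------------------------------

def brute_force_extrema(values, threshold):
    """Exhaustive local-extremum + topographic-prominence scan.

    Plateaus (runs of equal values with strictly lower neighbours on both
    sides) report their centre sample, the lower index for even runs.
    Prominence of a maximum = height minus the higher of the two bases, where
    each base is the minimum between the peak and the nearest strictly higher
    sample (or the profile end) on that side.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)

    def scan(sig):
        peaks = []
        i = 1
        while i < n - 1:
            if sig[i - 1] < sig[i]:
                j = i
                while j < n - 1 and sig[j + 1] == sig[i]:
                    j += 1
                if j < n - 1 and sig[j + 1] < sig[i]:
                    mid = (i + j) // 2
                    # prominence
                    left = sig[:i][::-1]
                    base_l = sig[i]
                    lowest = sig[i]
                    for s in left:
                        if s > sig[i]:
                            break
                        lowest = min(lowest, s)
                    base_l = lowest
                    lowest = sig[i]
                    for s in sig[j + 1 :]:
                        if s > sig[i]:
                            break
                        lowest = min(lowest, s)
                    base_r = lowest
                    if sig[i] - max(base_l, base_r) >= threshold:
                        peaks.append(mid)
                i = j + 1
            else:
                i += 1
        return peaks

    return scan(v), scan(-v)


def profile_from(values, pitch=0.15):
    values = np.asarray(values, dtype=float)
    n = len(values)
    line = MeasurementLine(0, (0.0, 0.0), ((n - 1) * pitch, 0.0), 1)
    return GreyProfile(np.arange(n) * pitch, values, line)


def constant_stack(value, shape=(4, 30, 40)):
    return VolumeStack(np.full(shape, value, dtype=np.uint8), (0.15, 0.15, 0.15))


class TestExtractProfile:
    def test_constant_field(self):
        stack = constant_stack(100)
        line = make_central_line(1, (0.6, 2.1), (5.1, 2.1))
        prof = extract_profile(stack, line)
        np.testing.assert_allclose(prof.value, 100.0)

    def test_sample_count_matches_pitch(self):
        stack = constant_stack(7, shape=(4, 30, 45))
        line = make_central_line(0, (0.0, 2.1), (6.0, 2.1))
        prof = extract_profile(stack, line)
        assert len(prof.distance_mm) == 41
        assert prof.distance_mm[0] == 0.0
        assert prof.distance_mm[-1] == pytest.approx(6.0)

    def test_single_bright_ridge_gives_one_maximum(self):
        stack = constant_stack(10)
        v = stack.voxels.copy()
        v[:, :, 20] = 250  # one-pixel bright column crossing the line
        stack = VolumeStack(v, stack.voxel_size)
        line = MeasurementLine(0, (0.75, 2.25), (5.25, 2.25), sampling_width_px=1)
        prof = extract_profile(stack, line)
        peaks = find_profile_peaks(prof)
        assert len(peaks.maxima) == 1
        assert peaks.maxima[0][0] == pytest.approx(20 * 0.15 - 0.75)

    def test_band_outside_volume_is_geometry_error(self):
        stack = constant_stack(10, shape=(2, 10, 40))
        line = make_central_line(0, (0.0, 0.0), (5.0, 0.0))  # band straddles row edge
        with pytest.raises(GeometryError):
            extract_profile(stack, line)

    def test_wide_line_averages_perpendicular_band(self):
        stack = constant_stack(0, shape=(1, 20, 20))
        v = stack.voxels.copy().astype(np.uint8)
        v[0, 9, :] = 200  # bright row inside the band
        stack = VolumeStack(v, stack.voxel_size)
        line = MeasurementLine(0, (0.3, 9 * 0.15), (2.4, 9 * 0.15), sampling_width_px=5)
        prof = extract_profile(stack, line)
        np.testing.assert_allclose(prof.value, 200 / 5)


class TestFindPeaks:
    def test_matches_brute_force_oracle_on_random_profiles(self, rng):
        """Peak sets equal an independent exhaustive extremum + prominence
        scan on random integer-valued profiles (many plateaus)."""
        for _ in range(300):
            n = int(rng.integers(3, 200))
            values = rng.integers(0, 20, n).astype(float)
            prof = profile_from(values)
            peaks = find_profile_peaks(prof, 0.1)
            rng_range = values.max() - values.min()
            if rng_range == 0:
                assert peaks.flat
                continue
            want_max, want_min = brute_force_extrema(values, 0.1 * rng_range)
            got_max = [round(x / 0.15) for x, _ in peaks.maxima]
            got_min = [round(x / 0.15) for x, _ in peaks.minima]
            assert got_max == want_max
            assert got_min == want_min

    def test_monotone_ramp_has_no_interior_maxima(self):
        prof = profile_from(np.linspace(0, 100, 30))
        peaks = find_profile_peaks(prof)
        assert peaks.maxima == ()
        assert peaks.minima == ()

    def test_symmetric_profile_gives_symmetric_peaks(self):
        x = np.linspace(-1, 1, 81)
        values = np.exp(-((x - 0.5) ** 2) / 0.01) + np.exp(-((x + 0.5) ** 2) / 0.01)
        prof = profile_from(values)
        peaks = find_profile_peaks(prof)
        assert len(peaks.maxima) == 2
        mid = (prof.distance_mm[0] + prof.distance_mm[-1]) / 2
        assert peaks.maxima[0][0] - mid == pytest.approx(mid - peaks.maxima[1][0], abs=1e-9)

    def test_flat_profile_flagged(self):
        peaks = find_profile_peaks(profile_from(np.full(10, 5.0)))
        assert peaks.flat
        assert peaks.maxima == () and peaks.minima == ()

    def test_two_gaussian_bumps_located(self):
        x = np.arange(0, 10.41, 0.05)
        values = 100 * np.exp(-((x - 2.0) ** 2) / 0.5) + 80 * np.exp(-((x - 8.4) ** 2) / 0.5)
        prof = GreyProfile(x, values, MeasurementLine(0, (0, 0), (10.4, 0), 1))
        peaks = find_profile_peaks(prof)
        assert len(peaks.maxima) == 2
        assert peaks.maxima[0][0] == pytest.approx(2.0, abs=0.05)
        assert peaks.maxima[1][0] == pytest.approx(8.4, abs=0.05)


def peakset(maxima, span=(0.0, 12.0), pitch=0.15):
    return PeakSet(tuple(maxima), (), 10.0, span, pitch)


class TestRidgeWidth:
    def test_width_is_outer_maxima_difference(self):
        m = ridge_width(peakset([(2.0, 200.0), (8.4, 190.0)]))
        assert m.width_mm == pytest.approx(6.4)
        assert m.qc_flags == frozenset()

    def test_extra_peaks_flagged_outermost_used(self):
        m = ridge_width(peakset([(2.0, 200.0), (5.0, 150.0), (8.4, 190.0)]))
        assert m.width_mm == pytest.approx(6.4)
        assert EXTRA_PEAKS in m.qc_flags

    def test_single_maximum_is_measurement_error(self):
        with pytest.raises(MeasurementError):
            ridge_width(peakset([(5.0, 200.0)]))

    def test_boundary_peak_flagged(self):
        m = ridge_width(peakset([(0.15, 200.0), (8.4, 190.0)]))
        assert BOUNDARY_PEAK in m.qc_flags


class TestMeasureGrid:
    def test_phantom_recovery_within_half_voxel(self, default_phantom, default_grid, default_spec):
        t0, _, truth = default_phantom
        tt = truth_lookup(truth, "t0")
        half_voxel = default_spec.voxel_size[2] / 2
        ms = measure_grid(t0, default_grid)
        assert len(ms) == 15
        for m in ms:
            assert m.measurable
            assert abs(m.width_mm - tt.loc[(m.label.depth_mm, m.label.offset_mm)]) <= half_voxel + 1e-9

    def test_uniform_stack_yields_unmeasurable_records(self, default_grid):
        stack = constant_stack(80, shape=(45, 60, 90))
        ms = measure_grid(stack, default_grid)
        assert len(ms) == 15
        assert all(not m.measurable and UNMEASURABLE in m.qc_flags for m in ms)

    def test_repeat_invocation_bit_identical(self, default_phantom, default_grid):
        t0, _, _ = default_phantom
        a = measure_grid(t0, default_grid)
        b = measure_grid(t0, default_grid)
        assert a == b

    def test_monotone_grey_map_invariance(self, default_phantom, default_grid):
        """Any strictly increasing grey map leaves every measured width
        unchanged: peak locations are order statistics."""
        t0, t1, _ = default_phantom
        for stack in (t0, t1):
            base = measure_grid(stack, default_grid)
            v = stack.voxels.astype(np.float64)
            for mapped in (
                255.0 * (v / 255.0) ** 2,  # convex
                255.0 * np.sqrt(v / 255.0),  # concave
                3.0 * v + 7.0,  # affine
            ):
                remapped = VolumeStack(mapped, stack.voxel_size)
                ms = measure_grid(remapped, default_grid)
                assert [(m.label, m.width_mm) for m in ms] == [
                    (m.label, m.width_mm) for m in base
                ]

    def test_translation_equivariance(self, default_spec, default_phantom):
        """Shifting volume and grid by the same in-plane whole-voxel vector
        leaves all widths unchanged."""
        import dataclasses

        t0, _, _ = default_phantom
        grid = phantom.default_grid(default_spec)
        shift_vox = (3, -2)  # (rows, cols)
        shifted_voxels = np.roll(t0.voxels, shift_vox, axis=(1, 2))
        shifted_stack = VolumeStack(shifted_voxels, t0.voxel_size)
        d = (shift_vox[1] * 0.15, shift_vox[0] * 0.15)  # (dx, dy) mm
        shifted_lines = tuple(
            dataclasses.replace(
                line,
                p_start=(line.p_start[0] + d[0], line.p_start[1] + d[1]),
                p_end=(line.p_end[0] + d[0], line.p_end[1] + d[1]),
            )
            for line in grid.lines
        )
        shifted_grid = dataclasses.replace(grid, lines=shifted_lines)
        a = measure_grid(t0, grid)
        b = measure_grid(shifted_stack, shifted_grid)
        assert [(m.label, m.width_mm) for m in a] == [(m.label, m.width_mm) for m in b]
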