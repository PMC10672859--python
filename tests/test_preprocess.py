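"""Preprocessing stages: calibration, AsLS baseline, exclusion,
alignment, PQN, and adaptive bucketing."""

import numpy as np
import pytest

from afnmr import (
    SpectraMatrix,
    Spectrum,
    align_spectra,
    baseline_correct,
    calibrate_to_reference,
    exclude_regions,
    intelligent_bucket,
    pqn_normalize,
)
from conftest import lorentzian


def _spectrum(intensity, ppm=None, sid="S1", group="term"):
    if ppm is None:
        ppm = np.linspace(0.0, 10.0, intensity.size)
    return Spectrum(ppm=ppm, intensity=intensity, sample_id=sid, group=group)


@pytest.fixture()
def axis():
    return np.linspace(0.0, 10.0, 4096)


class TestCalibration:
    def test_identity_when_already_calibrated(self, axis):
        y = lorentzian(axis, 0.0, 0.002, 1.0)
        sp = _spectrum(y, axis)
        out = calibrate_to_reference(sp)
        assert np.array_equal(out.intensity, y)

    def test_inverse_shift_recovered(self, axis):
        y = lorentzian(axis, 0.05, 0.002, 1.0)
        out = calibrate_to_reference(_spectrum(y, axis))
        step = axis[1] - axis[0]
        assert abs(axis[np.argmax(out.intensity)]) <= step + 1e-12

    def test_idempotence(self, axis):
        y = lorentzian(axis, 0.07, 0.002, 1.0) + lorentzian(axis, 3.0, 0.003, 2.0)
        once = calibrate_to_reference(_spectrum(y, axis))
        twice = calibrate_to_reference(once)
        assert np.array_equal(once.intensity, twice.intensity)

    def test_missing_reference_peak_raises(self, axis):
        rng = np.random.default_rng(0)
        y = np.abs(rng.normal(1.0, 0.01, axis.size))  # flat: no dominant peak
        with pytest.raises(ValueError, match="reference peak"):
            calibrate_to_reference(_spectrum(y, axis))


class TestBaseline:
    def test_no_baseline_is_a_near_noop(self, axis):
        y = lorentzian(axis, 3.0, 0.004, 5.0) + lorentzian(axis, 7.0, 0.004, 3.0)
        out = baseline_correct(_spectrum(y, axis))
        assert np.max(np.abs(out.intensity - y)) < 0.01 * y.max()

    def test_pure_quadratic_baseline_removed(self, axis):
        base = 5.0 + 0.3 * (axis - 5.0) ** 2
        out = baseline_correct(_spectrum(base, axis))
        assert np.sqrt(np.mean(out.intensity**2)) < 0.01 * np.sqrt(np.mean(base**2))

    def test_peak_integral_recovered_over_linear_ramp(self, axis):
        peak = lorentzian(axis, 5.0, 0.004, 4.0)
        ramp = 2.0 + 0.5 * axis
        out = baseline_correct(_spectrum(peak + ramp, axis))
        window = (axis > 4.8) & (axis < 5.2)
        got = np.trapezoid(out.intensity[window], axis[window])
        want = np.trapezoid(peak[window], axis[window])
        assert abs(got - want) < 0.05 * want

    def test_non_finite_input_rejected(self, axis):
        y = np.ones(axis.size)
        y[10] = np.nan
        with pytest.raises(ValueError, match="finite"):
            baseline_correct(_spectrum(y, axis))

    def test_too_short_input_rejected(self):
        ppm = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="256"):
            baseline_correct(_spectrum(np.ones(100), ppm))


class TestExcludeRegions:
    def _matrix(self, axis):
        y = lorentzian(axis, 3.0, 0.004, 1.0)
        return SpectraMatrix(axis, np.vstack([y, 2 * y]), ["a", "b"],
                             ["term", "preterm"])

    def test_empty_region_list_is_identity(self, axis):
        m = self._matrix(axis)
        out = exclude_regions(m, [])
        assert out.excluded_regions == []
        assert np.array_equal(out.intensities, m.intensities)

    def test_overlapping_regions_merged(self, axis):
        out = exclude_regions(self._matrix(axis), [(4.5, 5.0), (4.8, 5.3)])
        assert out.excluded_regions == [(4.5, 5.3)]

    def test_water_region_excluded_from_buckets(self, axis):
        y = lorentzian(axis, 4.7, 0.004, 5.0) + lorentzian(axis, 3.0, 0.004, 5.0)
        m = SpectraMatrix(axis, np.vstack([y, y * 1.1]), ["a", "b"],
                          ["term", "term"])
        m = exclude_regions(m, [(4.5, 5.0)])
        table = intelligent_bucket(m)
        for lo, hi in table.buckets:
            assert hi <= 4.5 or lo >= 5.0

    def test_region_outside_axis_rejected(self, axis):
        with pytest.raises(ValueError, match="outside"):
            exclude_regions(self._matrix(axis), [(11.0, 12.0)])


class TestAlignment:
    def test_identical_samples_are_untouched(self, axis):
        y = lorentzian(axis, 3.0, 0.004, 1.0) + lorentzian(axis, 6.0, 0.004, 2.0)
        m = SpectraMatrix(axis, np.vstack([y, y, y]), ["a", "b", "c"],
                          ["term"] * 3)
        out = align_spectra(m)
        assert np.allclose(out.intensities, m.intensities)

    def test_shifted_copy_realigned(self, axis):
        y = (lorentzian(axis, 2.0, 0.004, 1.0)
             + lorentzian(axis, 5.5, 0.004, 2.0)
             + lorentzian(axis, 8.0, 0.004, 1.5))
        shifted = np.roll(y, 9)
        m = SpectraMatrix(axis, np.vstack([y, shifted]), ["ref", "moved"],
                          ["term", "term"])
        out = align_spectra(m, max_shift=15)
        r = np.corrcoef(out.intensities[0], out.intensities[1])[0, 1]
        assert r > 0.999

    def test_mean_pairwise_correlation_never_decreases(self, axis):
        rng = np.random.default_rng(5)
        rows = []
        for k in range(4):
            y = sum(
                lorentzian(axis, c + rng.normal(0, 0.01), 0.004, a)
                for c, a in ((2.0, 1.0), (5.0, 2.0), (7.5, 1.0))
            ) + rng.normal(0, 0.02, axis.size)
            rows.append(y)
        m = SpectraMatrix(axis, np.vstack(rows), list("abcd"), ["term"] * 4)

        def mpc(X):
            c = np.corrcoef(X)
            return (c.sum() - len(X)) / (len(X) * (len(X) - 1))

        out = align_spectra(m)
        assert mpc(out.intensities) >= mpc(m.intensities) - 1e-12

    def test_invalid_max_shift_rejected(self, axis):
        m = SpectraMatrix(axis, np.ones((2, axis.size)), ["a", "b"], ["term"] * 2)
        with pytest.raises(ValueError, match="max_shift"):
            align_spectra(m, max_shift=0)


class TestPQN:
    def test_sample_equal_to_reference_gets_factor_one(self, axis):
        y = lorentzian(axis, 3.0, 0.01, 5.0) + 0.1
        m = SpectraMatrix(axis, np.vstack([y, y, y]), list("abc"), ["term"] * 3)
        out, factors = pqn_normalize(m)
        assert np.allclose(factors, 1.0)
        assert np.allclose(out.intensities, m.intensities)

    def test_pure_dilution_recovered(self, axis):
        y = lorentzian(axis, 3.0, 0.01, 5.0) + 0.1
        m = SpectraMatrix(axis, np.vstack([y, 3.0 * y, y]), list("abc"),
                          ["term"] * 3)
        out, factors = pqn_normalize(m, reference=y)
        assert factors[1] == pytest.approx(3.0, rel=1e-9)
        assert np.allclose(out.intensities[1], y, rtol=1e-9)

    def test_factors_match_brute_force_median_quotients(self):
        # 8-point toy, quotients computable by hand/loops
        ppm = np.linspace(1.0, 2.0, 8)
        ref = np.array([1.0, 2.0, 4.0, 8.0, 8.0, 4.0, 2.0, 1.0])
        samples = np.array(
            [
                [2.0, 4.0, 8.0, 16.0, 16.0, 8.0, 4.0, 2.0],
                [1.0, 1.0, 4.0, 12.0, 8.0, 2.0, 2.0, 3.0],
                [0.5, 1.0, 2.0, 4.0, 4.0, 2.0, 1.0, 0.5],
            ]
        )
        m = SpectraMatrix(ppm, samples, list("abc"), ["term"] * 3)
        out, factors = pqn_normalize(m, reference=ref, noise_floor=0.0)

        # independent oracle: explicit integral factors and median quotients
        totals = [np.trapezoid(np.abs(r), ppm) for r in samples]
        mean_total = float(np.mean(totals))
        for i in range(3):
            integral_factor = totals[i] / mean_total
            quots = [
                (samples[i, j] / integral_factor) / ref[j] for j in range(8)
            ]
            expected = integral_factor * float(np.median(quots))
            assert factors[i] == pytest.approx(expected, rel=1e-12)

    def test_all_zero_sample_rejected(self, axis):
        y = lorentzian(axis, 3.0, 0.01, 5.0)
        m = SpectraMatrix(axis, np.vstack([y, np.zeros_like(y)]), ["a", "zz"],
                          ["term"] * 2)
        with pytest.raises(ValueError, match="zz"):
            pqn_normalize(m)


class TestBucketing:
    def test_edge_placed_in_the_valley_between_two_peaks(self, axis):
        y = lorentzian(axis, 2.0, 0.01, 1.0) + lorentzian(axis, 2.3, 0.01, 1.0)
        m = SpectraMatrix(axis, np.vstack([y, y]), ["a", "b"], ["term"] * 2)
        table = intelligent_bucket(m, region=(1.5, 2.8))
        inner = [b for b in table.buckets if b[0] > 1.9 and b[1] < 2.4]
        containing_2 = [b for b in table.buckets if b[0] <= 2.0 < b[1]]
        containing_23 = [b for b in table.buckets if b[0] <= 2.3 < b[1]]
        assert len(containing_2) == 1 and len(containing_23) == 1
        assert containing_2[0] != containing_23[0]
        # the separating edge sits near the mid-valley (2.15)
        edge = containing_2[0][1]
        assert 2.05 < edge < 2.25

    def test_flat_spectrum_yields_zero_buckets(self, axis):
        m = SpectraMatrix(axis, np.zeros((2, axis.size)), ["a", "b"], ["term"] * 2)
        table = intelligent_bucket(m)
        assert len(table.buckets) == 0

    def test_partition_conserves_the_region_integral(self, small_cohort):
        matrix, _ = small_cohort
        table = intelligent_bucket(matrix, region=(0.8, 8.5))
        total = table.values.sum(axis=1)
        if table.dropped_values is not None:
            total = total + table.dropped_values.sum(axis=1)
        ax = matrix.ppm
        i_lo = np.searchsorted(ax, 0.8, side="left")
        i_hi = np.searchsorted(ax, 8.5, side="right") - 1
        direct = np.trapezoid(
            matrix.intensities[:, i_lo : i_hi + 1], ax[i_lo : i_hi + 1], axis=1
        )
        assert np.allclose(total, direct, rtol=1e-9)

    def test_buckets_are_descending_and_disjoint(self, small_cohort):
        matrix, _ = small_cohort
        table = intelligent_bucket(matrix)
        los = [lo for lo, _ in table.buckets]
        assert los == sorted(los, reverse=True)
        asc = sorted(table.buckets)
        for (l1, h1), (l2, _h2) in zip(asc, asc[1:]):
            assert l2 >= h1 - 1e-12

    def test_region_outside_axis_rejected(self, axis):
        m = SpectraMatrix(axis, np.ones((2, axis.size)), ["a", "b"], ["term"] * 2)
        with pytest.raises(ValueError, match="region"):
            intelligent_bucket(m, region=(0.8, 12.0))
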