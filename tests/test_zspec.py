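import numpy as np
import pytest

import aacidcest as ac
from aacidcest.bloch import bm_evolve
from aacidcest.stack import ZSpectrumStack
from aacidcest.zspec import (
    DomainError,
    apply_b0_correction,
    average_repeats,
    estimate_b0,
    fit_spline,
    normalize_by_reference,
)


def _raw_stack(spectra, offsets, refs=(-1000.0, 1000.0), ref_value=1.0, field=400.22):
    """Raw stack helper: sampled frames followed by reference frames."""
    spectra = np.asarray(spectra, dtype=float)
    nx, ny, _ = spectra.shape
    ref = np.full((nx, ny, len(refs)), ref_value)
    data = np.concatenate([spectra, ref], axis=2)
    return ZSpectrumStack(
        data=data,
        offsets_ppm=np.concatenate([offsets, refs]),
        field_mhz=field,
        reference_offsets_ppm=np.asarray(refs),
    )


class TestNormalize:
    def test_spectrum_equal_to_reference_becomes_unity(self):
        offsets = np.arange(1.2, 2.21, 0.1)
        stack = _raw_stack(np.full((2, 2, offsets.size), 7.5), offsets, ref_value=7.5)
        out = normalize_by_reference(stack)
        np.testing.assert_allclose(out.data, 1.0)
        assert out.normalized and not out.is_reference_frame.any()

    def test_reference_mean_division(self):
        # references 100 and 102, saturated frame 51 -> z = 51/101
        offsets = np.array([2.0, 3.0, 4.0, 5.0])
        data = np.concatenate(
            [np.full((1, 1, 4), 51.0), np.array([[[100.0, 102.0]]])], axis=2
        )
        stack = ZSpectrumStack(
            data=data,
            offsets_ppm=np.array([2.0, 3.0, 4.0, 5.0, -1000.0, 1000.0]),
            field_mhz=400.22,
            reference_offsets_ppm=np.array([-1000.0, 1000.0]),
        )
        out = normalize_by_reference(stack)
        assert out.data[0, 0, 0] == pytest.approx(0.50495, abs=1e-5)

    def test_zero_reference_flags_voxel_not_stack(self):
        offsets = np.arange(1.2, 1.61, 0.1)
        spectra = np.full((2, 1, offsets.size), 0.5)
        stack = _raw_stack(spectra, offsets)
        stack.data[0, 0, -2:] = 0.0  # kill this voxel's references
        out = normalize_by_reference(stack)
        assert not out.valid[0, 0] and out.valid[1, 0]
        assert np.isnan(out.data[0, 0]).all()

    def test_effectively_idempotent_with_unit_references(self):
        offsets = np.arange(1.2, 2.21, 0.1)
        z = np.random.default_rng(0).uniform(0.4, 1.0, size=(3, 3, offsets.size))
        once = normalize_by_reference(_raw_stack(z, offsets))
        again = normalize_by_reference(_raw_stack(once.data, offsets, ref_value=1.0))
        np.testing.assert_allclose(again.data, once.data)

    def test_no_reference_frames_raises(self):
        offsets = np.arange(1.2, 2.21, 0.1)
        stack = ZSpectrumStack(
            data=np.full((1, 1, offsets.size), 0.5), offsets_ppm=offsets, field_mhz=400.22
        )
        with pytest.raises(ValueError):
            normalize_by_reference(stack)


class TestAverageRepeats:
    def _normalized(self, data, offsets):
        return ZSpectrumStack(
            data=data, offsets_ppm=offsets, field_mhz=400.22, normalized=True
        )

    def test_identical_stacks_average_to_themselves(self):
        offsets = np.arange(1.2, 2.21, 0.1)
        z = np.random.default_rng(1).uniform(0.4, 1.0, size=(2, 2, offsets.size))
        out = average_repeats([self._normalized(z, offsets)] * 3)
        np.testing.assert_allclose(out.data, z)

    def test_mean_of_scaled_copies(self):
        offsets = np.arange(1.2, 2.21, 0.1)
        z = np.random.default_rng(2).uniform(0.3, 0.7, size=(2, 2, offsets.size))
        out = average_repeats([self._normalized(z, offsets), self._normalized(2 * z, offsets)])
        np.testing.assert_allclose(out.data, 1.5 * z)

    def test_noise_reduction_scales_as_sqrt_n(self, system, wassr_sched):
        # Monte-Carlo: voxel SD after 3-repeat averaging ≈ single-repeat SD/√3
        z = np.array([bm_evolve(system, w, 0.2, 0.1, ph=7.0) for w in wassr_sched.offsets_ppm])
        rng = np.random.default_rng(9)
        sigma, n_mc = 0.02, 300
        single, averaged = [], []
        for _ in range(n_mc):
            reps = [ac.add_rician_noise(z, sigma, rng) for _ in range(3)]
            single.append(reps[0][20])
            averaged.append(np.mean([r[20] for r in reps]))
        ratio = np.std(single, ddof=1) / np.std(averaged, ddof=1)
        assert ratio == pytest.approx(np.sqrt(3), rel=0.2)

    def test_mismatched_offsets_rejected(self):
        o1, o2 = np.arange(1.2, 2.21, 0.1), np.arange(1.3, 2.31, 0.1)
        a = self._normalized(np.full((1, 1, o1.size), 0.5), o1)
        b = self._normalized(np.full((1, 1, o2.size), 0.5), o2)
        with pytest.raises(ValueError):
            average_repeats([a, b])

    def test_invalid_voxels_propagate(self):
        offsets = np.arange(1.2, 2.21, 0.1)
        a = self._normalized(np.full((2, 1, offsets.size), 0.5), offsets)
        b = self._normalized(np.full((2, 1, offsets.size), 0.7), offsets)
        a.valid[0, 0] = False
        a.data[0, 0] = np.nan
        out = average_repeats([a, b])
        assert not out.valid[0, 0] and out.valid[1, 0]


class TestFitSpline:
    def test_zero_smoothing_interpolates_exactly(self):
        x = np.arange(1.2, 6.61, 0.1)
        y = 1 - 0.5 * np.exp(-((x - 3.5) ** 2))
        cs = fit_spline(x, y, 400.22, smoothing=0)
        np.testing.assert_allclose(cs(x), y, atol=1e-10)

    def test_cubic_polynomial_reproduced_everywhere(self):
        x = np.linspace(0, 2, 15)
        y = 0.1 * x**3 - 0.3 * x**2 + 0.05 * x + 0.9
        cs = fit_spline(x, y, 400.22, smoothing=0)
        dense = np.linspace(0, 2, 301)
        np.testing.assert_allclose(cs(dense), 0.1 * dense**3 - 0.3 * dense**2 + 0.05 * dense + 0.9, atol=1e-12)

    def test_grid_resolution_at_most_one_hz(self):
        x = np.arange(1.2, 6.61, 0.1)
        cs = fit_spline(x, np.ones_like(x), 400.22, smoothing=0)
        assert np.diff(cs.grid_ppm()).max() <= 1.0 / 400.22 + 1e-12

    def test_dense_spline_tracks_simulator_oracle(self, system, cest_sched):
        z = np.array([bm_evolve(system, w, 1.5, 4.0, ph=7.0) for w in cest_sched.offsets_ppm])
        cs = fit_spline(cest_sched.offsets_ppm, z, system.field_mhz, smoothing=0)
        dense = np.linspace(1.25, 6.55, 107)
        oracle = np.array([bm_evolve(system, w, 1.5, 4.0, ph=7.0) for w in dense])
        assert np.abs(cs(dense) - oracle).max() < 5e-3

    def test_wassr_spline_tracks_oracle_away_from_water_line(self, system, wassr_sched):
        # the water line at WASSR power is only a few sampling steps wide,
        # so interpolation error concentrates on its flanks; off the line
        # the spline tracks the simulator closely
        z = np.array([bm_evolve(system, w, 0.2, 0.1, ph=7.0) for w in wassr_sched.offsets_ppm])
        cs = fit_spline(wassr_sched.offsets_ppm, z, system.field_mhz, smoothing=0)
        dense = np.linspace(-0.58, 0.58, 117)
        oracle = np.array([bm_evolve(system, w, 0.2, 0.1, ph=7.0) for w in dense])
        off_line = np.abs(dense) > 0.2
        assert np.abs(cs(dense) - oracle)[off_line].max() < 5e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_spline(np.array([1.0, 2.0, 3.0]), np.ones(3), 400.22)

    def test_non_monotone_offsets_rejected(self):
        with pytest.raises(ValueError):
            fit_spline(np.array([1.0, 3.0, 2.0, 4.0]), np.ones(4), 400.22)


class TestEstimateB0:
    def _wassr(self, system, sched, b0=0.0):
        return np.array(
            [bm_evolve(system, w - b0, 0.2, 0.1, ph=7.0) for w in sched.offsets_ppm]
        )

    def test_centered_spectrum_gives_zero_shift(self, system, wassr_sched):
        z = self._wassr(system, wassr_sched)
        shift = estimate_b0(wassr_sched.offsets_ppm, z, system.field_mhz, smoothing=0)
        assert abs(shift) < 1e-3

    def test_round_trip_recovers_known_shift(self, system, wassr_sched):
        z = self._wassr(system, wassr_sched, b0=0.06)
        shift = estimate_b0(wassr_sched.offsets_ppm, z, system.field_mhz, smoothing=0)
        assert shift == pytest.approx(0.06, abs=0.003)

    def test_monotone_spectrum_flagged_unbracketed(self, wassr_sched):
        z = np.linspace(1.0, 0.2, wassr_sched.offsets_ppm.size)  # min at the edge
        with pytest.raises(DomainError):
            estimate_b0(wassr_sched.offsets_ppm, z, 400.22, smoothing=0)

    def test_noisy_estimation_small_bias(self, system, wassr_sched):
        # σ = 0.01, true shifts uniform in ±0.12 ppm
        rng = np.random.default_rng(17)
        z_by_shift = {}
        errors = []
        for _ in range(120):
            true = round(rng.uniform(-0.12, 0.12), 3)
            if true not in z_by_shift:
                z_by_shift[true] = self._wassr(system, wassr_sched, b0=true)
            noisy = ac.add_rician_noise(z_by_shift[true], 0.01, rng)
            est = estimate_b0(wassr_sched.offsets_ppm, noisy, system.field_mhz)
            errors.append(est - true)
        errors = np.asarray(errors)
        assert abs(errors.mean()) < 0.005
        assert errors.std(ddof=1) < 0.01


class TestApplyB0Correction:
    def test_zero_shift_is_identity(self, system, cest_sched):
        z = np.array([bm_evolve(system, w, 1.5, 4.0, ph=7.0) for w in cest_sched.offsets_ppm])
        cs = fit_spline(cest_sched.offsets_ppm, z, system.field_mhz, smoothing=0)
        corrected = apply_b0_correction(cs, 0.0)
        np.testing.assert_allclose(corrected.grid_values(), cs.grid_values())

    def test_large_shift_moves_required_sample_out_of_domain(self, cest_sched):
        x = cest_sched.offsets_ppm
        cs = fit_spline(x, np.ones_like(x), 400.22, smoothing=0)
        with pytest.raises(DomainError):
            apply_b0_correction(cs, 5.0)

    def test_round_trip_restores_aacid_within_2pct(self, system, cest_sched, wassr_sched):
        from aacidcest.mapping import AACIDSamples, compute_aacid

        def aacid_of(cs):
            return compute_aacid(
                AACIDSamples(mz_amine=cs.sample(2.75), mz_amide=cs.sample(3.5), mz_ref=cs.sample(6.0))
            )

        z0 = np.array([bm_evolve(system, w, 1.5, 4.0, ph=7.0) for w in cest_sched.offsets_ppm])
        ref = aacid_of(fit_spline(cest_sched.offsets_ppm, z0, system.field_mhz, smoothing=0))
        for b0 in (-0.1, 0.1):
            z = np.array(
                [bm_evolve(system, w - b0, 1.5, 4.0, ph=7.0) for w in cest_sched.offsets_ppm]
            )
            zw = np.array(
                [bm_evolve(system, w - b0, 0.2, 0.1, ph=7.0) for w in wassr_sched.offsets_ppm]
            )
            est = estimate_b0(wassr_sched.offsets_ppm, zw, system.field_mhz, smoothing=0)
            cs = fit_spline(cest_sched.offsets_ppm, z, system.field_mhz, smoothing=0)
            corrected = apply_b0_correction(cs, est)
            assert aacid_of(corrected) == pytest.approx(ref, rel=0.02)
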