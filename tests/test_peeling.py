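"""The iterative comb-peeling algorithm: detection, tracking, features, removal."""

from dataclasses import replace

import numpy as np
import pytest

import oligopeel as op
from oligopeel.peeling import (
    Comb,
    PeelConfig,
    compute_width_half_height,
    estimate_noise_floor,
    find_apex,
    peel_spectrum,
    track_comb,
)
from oligopeel.preprocess import GridSpectrum


def grid(intensities, start=500.0, step=0.1):
    return GridSpectrum(start, step, np.asarray(intensities, dtype=float))


def comb_from(mz, intensity, spacing=44.0):
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    z = np.zeros(mz.size, dtype=int)
    return Comb(mz, intensity, intensity.copy(), z, z.copy(), z.copy(),
                int(np.argmax(intensity)), int(np.argmax(intensity)), spacing)


class TestNoiseFloor:
    def test_constant_spectrum_floor_equals_constant(self):
        assert estimate_noise_floor(grid(np.full(100, 3.0))) == pytest.approx(3.0)

    def test_sparse_spike_excluded_by_robustness(self):
        x = np.zeros(1000)
        x[500] = 100.0
        assert estimate_noise_floor(grid(x)) == pytest.approx(0.0)

    def test_noise_scale_recovered_within_bounds(self, rng):
        sigma = 0.5
        x = np.abs(rng.normal(0.0, sigma, size=5000))
        floor = estimate_noise_floor(grid(x))
        med = np.median(x)
        assert med <= floor <= med + 4 * sigma


class TestFindApex:
    def test_single_spike(self):
        x = np.zeros(100)
        x[42] = 5.0
        assert find_apex(x) == (42, 5.0)

    def test_tie_breaks_to_lower_mz(self):
        x = np.zeros(100)
        x[[10, 60]] = 7.0
        assert find_apex(x)[0] == 10

    def test_zero_spectrum_has_no_apex(self):
        assert find_apex(np.zeros(10)) is None


class TestTrackComb:
    def test_recovers_all_generated_members_of_single_series(self):
        comp = [op.SimComponent("PEG", 18.0106, abundance=1.0, mean_eo=18.3)]
        pl, truth = op.simulate_spectrum(comp, noise_sd=0.0, seed=7, mz_range=(500.0, 2000.0))
        spec = op.bin_to_grid(pl, 0.1, (500.0, 2000.0))
        result = peel_spectrum(spec)
        assert len(result.records) == 1
        comb = result.records[0].members
        # every truth peak above the member threshold appears as a member
        cfg = PeelConfig()
        apex_bin_val = result.records[0].detection_intensity
        strong = truth.components[0].peaks_intensity >= cfg.member_stop_fraction * apex_bin_val
        expected = truth.components[0].peaks_mz[strong]
        for m in expected:
            assert np.min(np.abs(comb.member_mz - m)) < 0.1 + 0.03
        # and nothing spurious: member count within 2 of expected count
        assert abs(len(comb) - strong.sum()) <= 2

    def test_reanchoring_absorbs_cumulative_spacing_drift(self):
        # peaks spaced 44.05 Da, tracked with nominal 44.0262: cumulative
        # mismatch over 30 members is ~0.7 Da, absorbed by re-anchoring
        start, step = 500.0, 0.1
        n = 20000
        x = np.zeros(n)
        positions = 600.0 + 44.05 * np.arange(30)
        for p in positions:
            x[int(round((p - start) / step))] = 100.0
        spec = GridSpectrum(start, step, x)
        apex_bin = int(round((positions[0] - start) / step))
        comb = track_comb(spec, apex_bin, PeelConfig(track_window=0.3))
        assert len(comb) == 30

    def test_isolated_apex_gives_single_member_comb(self):
        x = np.zeros(2000)
        x[1000] = 50.0
        comb = track_comb(grid(x), 1000, PeelConfig())
        assert len(comb) == 1


class TestWidthHalfHeight:
    def test_hand_interpolated_triangle(self):
        comb = comb_from([800.0, 844.0, 888.0], [40.0, 100.0, 40.0], spacing=44.0)
        # crossings at 807.33 and 880.67 by linear interpolation
        assert compute_width_half_height(comb) == pytest.approx(73.333, abs=0.01)

    def test_gaussian_envelope_matches_fwhm(self):
        comp = [op.SimComponent("g", 18.0106, envelope="gaussian", mean_eo=20.0,
                                sigma_eo=2.0)]
        pl, _ = op.simulate_spectrum(comp, noise_sd=0.0, seed=2, mz_range=(500.0, 2000.0))
        spec = op.bin_to_grid(pl, 0.1, (500.0, 2000.0))
        rec = peel_spectrum(spec).records[0]
        expected = 2.3548 * 2.0 * op.EO_MASS_MONO  # ~207.3 Da
        assert abs(rec.width_half_height - expected) < op.EO_MASS_MONO

    def test_single_member_has_zero_width(self):
        assert compute_width_half_height(comb_from([800.0], [10.0])) == 0.0

    def test_truncated_side_uses_outermost_member(self):
        comb = comb_from([800.0, 844.0], [90.0, 100.0], spacing=44.0)
        # right side never falls below half max: half-width = 0 on that side;
        # left crossing between 800 (90) and nothing -> outermost distance
        assert compute_width_half_height(comb) == pytest.approx(44.0)


class TestPeeling:
    def test_most_abundant_series_peeled_first(self):
        comps = [
            op.SimComponent("major", 18.0106, abundance=1.0, mean_eo=18.3),
            op.SimComponent("minor", 92.0473, abundance=0.4, mean_eo=18.3),
        ]
        pl, truth = op.simulate_spectrum(comps, noise_sd=0.0, seed=5, mz_range=(500.0, 2000.0))
        spec = op.bin_to_grid(pl, 0.1, (500.0, 2000.0))
        result = peel_spectrum(spec)
        assert abs(result.records[0].apex_mz - truth.components[0].apex_mz) < 0.1
        assert abs(result.records[1].apex_mz - truth.components[1].apex_mz) < 0.1

    def test_single_series_residual_below_threshold(self):
        comp = [op.SimComponent("PEG", 18.0106, abundance=1.0, mean_eo=18.3)]
        pl, _ = op.simulate_spectrum(comp, noise_sd=0.0, seed=9, mz_range=(500.0, 2000.0))
        spec = op.bin_to_grid(pl, 0.1, (500.0, 2000.0))
        result = peel_spectrum(spec)
        assert result.residual.intensities.max() < result.stop_threshold

    def test_three_component_ratios_recovered(self, three_component_sim):
        _, truth, _, result = three_component_sim
        assert len(result.records) == 3
        ratios = [r.total_intensity for r in result.records]
        truth_totals = [c.total_intensity for c in truth.components]
        for got, want in zip(ratios, truth_totals):
            assert got / ratios[0] == pytest.approx(want / truth_totals[0], rel=0.10)

    def test_zero_spectrum_yields_nothing(self):
        assert op.peel_all(grid(np.zeros(100))) == []

    def test_component_below_apex_threshold_not_reported(self):
        comps = [
            op.SimComponent("major", 18.0106, abundance=1.0, mean_eo=18.3),
            op.SimComponent("trace", 92.0473, abundance=0.02, mean_eo=18.3),
        ]
        pl, _ = op.simulate_spectrum(comps, noise_sd=0.0, seed=5, mz_range=(500.0, 2000.0))
        spec = op.bin_to_grid(pl, 0.1, (500.0, 2000.0))
        assert len(op.peel_all(spec)) == 1


class TestPeelInvariants:
    def test_conservation_of_total_intensity(self, three_component_sim):
        _, _, spec, result = three_component_sim
        peeled = sum(r.total_intensity for r in result.records)
        assert peeled + result.residual.total == pytest.approx(spec.total, rel=1e-9)

    def test_detection_intensities_non_increasing(self, peg_dataset):
        _, pipeline = peg_dataset
        for records in pipeline.records.values():
            dets = [r.detection_intensity for r in records]
            assert all(a >= b for a, b in zip(dets, dets[1:]))

    def test_ratio_to_main_in_unit_interval(self, peg_dataset):
        _, pipeline = peg_dataset
        for records in pipeline.records.values():
            assert records[0].ratio_to_main == 1.0
            assert all(0 < r.ratio_to_main <= 1.0 for r in records)

    def test_repeeling_residual_under_same_threshold_is_empty(self, three_component_sim):
        _, _, _, result = three_component_sim
        cfg = replace(PeelConfig(), apex_stop_abs=result.stop_threshold)
        assert peel_spectrum(result.residual, cfg).records == []

    def test_noiseless_mixture_members_match_generator_peaks(self, three_component_sim):
        _, truth, _, result = three_component_sim
        # each record's members lie on exactly one truth component's comb
        for rec in result.records:
            phases = [
                np.min(np.abs(rec.apex_mz - c.peaks_mz)) for c in truth.components
            ]
            assert min(phases) < 0.1
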