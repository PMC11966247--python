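"""Synthetic chromatogram generator: linearity axioms, determinism, the
default glycerol-oxidation scenario."""

import io
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromsolve as cs
from chromsolve.exceptions import ConfigurationError
from chromsolve.synth import default_time_grid, load_scenario, save_scenario


PEAKS = (
    cs.PeakSpec("glycerol", 13.6, 0.08),
    cs.PeakSpec("DHA", 13.8, 0.08),
)
MODEL = cs.DetectorResponseModel(
    response_factors={
        "glycerol": {"RID": 0.354, "VWD210": -8e-4},
        "DHA": {"RID": 0.314, "VWD210": 0.30},
    }
)
TIMES = np.arange(10.0, 17.0, 0.00833)
FULL_WINDOW = cs.IntegrationWindow(float(TIMES[0]), float(TIMES[-1]))


class TestSimulateChromatogram:
    def test_empty_mixture_all_zero(self):
        chrom = cs.simulate_chromatogram(
            PEAKS, MODEL, cs.MixtureSpec({}), cs.RID, times=TIMES
        )
        assert np.all(chrom.signals == 0.0)

    def test_unit_area_peak_times_factor(self):
        model = cs.DetectorResponseModel(
            response_factors={"glycerol": {"RID": 2.5}}
        )
        chrom = cs.simulate_chromatogram(
            PEAKS[:1], model, cs.MixtureSpec({"glycerol": 1.0}), cs.RID,
            times=TIMES,
        )
        area = cs.integrate_window(chrom, FULL_WINDOW)
        assert area == pytest.approx(2.5, rel=1e-6)

    def test_negative_response_factor_gives_negative_peak(self):
        chrom = cs.simulate_chromatogram(
            PEAKS, MODEL, cs.MixtureSpec({"glycerol": 500.0}), cs.vwd(210),
            times=TIMES,
        )
        assert chrom.signals.min() < 0
        area = cs.integrate_window(chrom, FULL_WINDOW)
        assert area == pytest.approx(500.0 * -8e-4, rel=1e-6)

    def test_mixture_is_pointwise_sum_of_components(self):
        mix = cs.MixtureSpec({"glycerol": 500.0, "DHA": 5.0})
        combined = cs.simulate_chromatogram(PEAKS, MODEL, mix, cs.RID,
                                            times=TIMES)
        parts = sum(
            cs.simulate_chromatogram(
                PEAKS, MODEL, cs.MixtureSpec({a: c}), cs.RID, times=TIMES
            ).signals
            for a, c in mix.concentrations.items()
        )
        np.testing.assert_array_equal(combined.signals, parts)

    def test_missing_response_factor_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            cs.simulate_chromatogram(
                PEAKS, MODEL, cs.MixtureSpec({"glycerol": 1.0}), cs.vwd(270),
                times=TIMES,
            )

    def test_emg_peak_keeps_unit_area(self):
        peak = cs.PeakSpec("glycerol", 13.6, 0.05, shape="emg", tail_tau=0.1)
        model = cs.DetectorResponseModel(
            response_factors={"glycerol": {"RID": 1.0}}
        )
        chrom = cs.simulate_chromatogram(
            (peak,), model, cs.MixtureSpec({"glycerol": 3.0}), cs.RID,
            times=np.arange(10.0, 20.0, 0.00833),
        )
        area = cs.integrate_window(chrom, cs.IntegrationWindow(10.0, 19.9))
        assert area == pytest.approx(3.0, rel=1e-5)

    @given(alpha=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_homogeneity_in_concentration(self, alpha):
        base = cs.simulate_chromatogram(
            PEAKS, MODEL, cs.MixtureSpec({"glycerol": 100.0, "DHA": 2.0}),
            cs.RID, times=TIMES,
        )
        scaled = cs.simulate_chromatogram(
            PEAKS, MODEL,
            cs.MixtureSpec({"glycerol": alpha * 100.0, "DHA": alpha * 2.0}),
            cs.RID, times=TIMES,
        )
        a0 = cs.integrate_window(base, FULL_WINDOW)
        a1 = cs.integrate_window(scaled, FULL_WINDOW)
        assert a1 == pytest.approx(alpha * a0, rel=1e-9)

    def test_seeded_noise_is_byte_reproducible(self):
        noisy = replace(MODEL, noise_sd=0.05, seed=123)
        bufs = []
        for _ in range(2):
            chrom = cs.simulate_chromatogram(
                PEAKS, noisy, cs.MixtureSpec({"DHA": 5.0}), cs.RID,
                times=TIMES,
            )
            buf = io.StringIO()
            cs.write_chromatogram(chrom, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seeds_differ(self):
        traces = [
            cs.simulate_chromatogram(
                PEAKS, replace(MODEL, noise_sd=0.05, seed=s),
                cs.MixtureSpec({"DHA": 5.0}), cs.RID, times=TIMES,
            ).signals
            for s in (1, 2)
        ]
        assert not np.array_equal(traces[0], traces[1])


class TestCalibrationSeries:
    def test_noise_free_series_proportional(self):
        standards = cs.generate_calibration_series(
            "glycerol", [1.0, 2.0, 4.0], MODEL, PEAKS, cs.RID,
            window=FULL_WINDOW, times=TIMES,
        )
        areas = [s.area for s in standards]
        assert areas[1] == pytest.approx(2 * areas[0], rel=1e-9)
        assert areas[2] == pytest.approx(4 * areas[0], rel=1e-9)

    def test_round_trip_recovers_response_factor(self):
        standards = cs.generate_calibration_series(
            "glycerol", [1.0, 2.0, 5.0], MODEL, PEAKS, cs.RID,
            window=FULL_WINDOW, times=TIMES,
        )
        curve = cs.fit_zero_intercept(standards, "glycerol", cs.RID)
        assert curve.slope == pytest.approx(0.354, rel=1e-6)

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(ConfigurationError):
            cs.generate_calibration_series(
                "glycerol", [], MODEL, PEAKS, cs.RID
            )


class TestGorScenario:
    def test_noise_free_recovery_of_validation_mixtures(self, gor_scenario,
                                                        gor_matrix):
        for name, mix in gor_scenario.mixtures.items():
            areas = cs.scenario_area_vector(gor_scenario, name)
            est = cs.solve_concentrations(gor_matrix, areas)
            for analyte, conc in est.as_dict().items():
                true = mix.concentrations[analyte]
                assert conc == pytest.approx(true, rel=1e-3), (name, analyte)

    def test_rid_calibration_matches_benchmark_areas(self, gor_scenario):
        # 500 mM glycerol -> 177, 5 mM DHA -> 1.57, 5 mM FA -> 0.319
        curves = {
            c.analyte: c
            for c in cs.scenario_calibration_curves(gor_scenario, [cs.RID])
        }
        assert 500 * curves["glycerol"].slope == pytest.approx(177.0, rel=1e-5)
        assert 5 * curves["DHA"].slope == pytest.approx(1.57, rel=1e-5)
        assert 5 * curves["FA"].slope == pytest.approx(0.319, rel=1e-5)

    def test_collinear_detector_subset_is_unsolvable(self, gor_scenario):
        # VWD205's response factors are exactly proportional to VWD210's,
        # so swapping it in for VWD270 drops the rank to 2
        detectors = (cs.RID, cs.vwd(210), cs.vwd(205))
        matrix = cs.scenario_response_matrix(gor_scenario, detectors)
        report = cs.assess_solvability(matrix)
        assert matrix.rank == 2
        assert not report.solvable

    def test_glycerol_uv_response_is_negative(self, gor_matrix):
        j = gor_matrix.analytes.index("glycerol")
        for i, det in enumerate(gor_matrix.detectors):
            if det.kind == "variable-wavelength":
                assert gor_matrix.entries[i, j] < 0

    def test_scenario_round_trip_through_yaml(self, gor_scenario):
        buf = io.StringIO()
        save_scenario(gor_scenario, buf)
        back = load_scenario(io.StringIO(buf.getvalue()))
        assert back.analytes == gor_scenario.analytes
        assert back.detectors == gor_scenario.detectors
        assert back.window == gor_scenario.window
        m0 = cs.scenario_response_matrix(gor_scenario)
        m1 = cs.scenario_response_matrix(back)
        np.testing.assert_array_equal(m0.entries, m1.entries)


def test_default_grid_matches_instrument_cadence():
    grid = default_time_grid(1.0)
    assert grid[0] == pytest.approx(0.00667)
    assert np.allclose(np.diff(grid), 0.00833)
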