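"""Double-exponential calibration: fitting, inversion and dose mapping.

Oracles: a brute-force grid over the two decay rates with a linear solve
for the amplitudes (checks the nonlinear fit found the global basin), a
dense-grid lookup inverse (checks the bisection), and direct evaluation of
the model formula.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import filmdose3d as fd
from filmdose3d.calibration import (
    FLAG_OK,
    FLAG_SATURATED,
    CalibrationCurve,
    CalibrationTable,
    _double_exp,
)
from filmdose3d.film_io import NetImage

TABLE_DOSES = np.array([0, 2, 4, 6, 8, 10, 15, 20, 25, 50, 75, 100, 150, 200], float)

#: Coefficients of the reference film response as printed with the fitted
#: reference dataset (net pixel value scale, mGy^-1 rates).
PRINTED = {"y0": 29525.0, "A1": -15404.0, "B1": 0.01617, "A2": -14172.0, "B2": 0.085367}
PRINTED_SE = {"y0": 323.0, "A1": 1170.0, "B1": 0.0019, "A2": 1350.0, "B2": 0.00771}

CLEAN = {"y0": 30000.0, "A1": -16000.0, "B1": 0.016, "A2": -14000.0, "B2": 0.09}


def printed_curve() -> CalibrationCurve:
    return CalibrationCurve(**PRINTED)


class TestFit:
    def test_reference_table_has_14_rows(self, ref_table):
        assert ref_table.n == 14
        assert np.array_equal(ref_table.doses, TABLE_DOSES)

    def test_reference_fit_matches_printed_coefficients(self, fitted_curve):
        for name, value in PRINTED.items():
            got = fitted_curve.coefficients()[name]
            assert got == pytest.approx(value, abs=PRINTED_SE[name]), name

    def test_reference_fit_rms_below_2pct_of_asymptote(self, fitted_curve):
        assert fitted_curve.rms_residual < 0.02 * fitted_curve.y0

    def test_noiseless_recovery_to_4_significant_figures(self):
        y = _double_exp(TABLE_DOSES, CLEAN["y0"], CLEAN["A1"], CLEAN["B1"],
                        CLEAN["A2"], CLEAN["B2"])
        curve = fd.fit_calibration(CalibrationTable(TABLE_DOSES, y))
        for name, value in CLEAN.items():
            assert curve.coefficients()[name] == pytest.approx(value, rel=5e-4), name

    def test_grid_oracle_agrees_with_nonlinear_fit(self, ref_table, fitted_curve):
        """Brute-force (B1, B2) grid + linear amplitude solve finds the same
        minimum basin as the Levenberg-Marquardt fit."""
        x, y = ref_table.doses, ref_table.net_values
        rates = np.geomspace(1e-3, 0.3, 60)
        best_sse, best = np.inf, None
        for i, b1 in enumerate(rates):
            for b2 in rates[i + 1:]:
                M = np.column_stack([np.ones_like(x), np.exp(-b1 * x), np.exp(-b2 * x)])
                coef, *_ = np.linalg.lstsq(M, y, rcond=None)
                sse = float(np.sum((y - M @ coef) ** 2))
                if sse < best_sse:
                    best_sse, best = sse, (b1, b2)
        fit_sse = fitted_curve.rms_residual**2 * ref_table.n
        assert fit_sse <= best_sse * 1.0001
        assert fitted_curve.B1 == pytest.approx(best[0], rel=0.15)
        assert fitted_curve.B2 == pytest.approx(best[1], rel=0.15)

    def test_canonical_ordering_slow_rate_first(self, fitted_curve):
        assert 0 < fitted_curve.B1 < fitted_curve.B2

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fd.fit_calibration(
                CalibrationTable(TABLE_DOSES, np.full(14, 100.0))
            )

    def test_coefficient_coverage_under_noise(self):
        """Under sigma=100 scanner noise, recovered coefficients fall within
        3 estimated standard errors of truth in >= 95% of replicates."""
        truth = np.array([CLEAN[k] for k in ("y0", "A1", "B1", "A2", "B2")])
        clean = _double_exp(TABLE_DOSES, *truth)
        rng = np.random.default_rng(42)
        n_rep, covered = 200, 0
        for _ in range(n_rep):
            y = np.maximum(clean + rng.normal(0, 100, clean.shape), 0.0)
            y[0] = 0.0  # keep the zero-dose anchor non-negative and sorted
            try:
                curve = fd.fit_calibration(CalibrationTable(TABLE_DOSES, y))
            except (ValueError, RuntimeError):
                continue
            got = np.array([curve.coefficients()[k] for k in ("y0", "A1", "B1", "A2", "B2")])
            se = np.array([curve.stderr[k] for k in ("y0", "A1", "B1", "A2", "B2")])
            if np.all(np.abs(got - truth) <= 3 * se):
                covered += 1
        assert covered >= 0.95 * n_rep


class TestForwardModel:
    def test_zero_dose_with_printed_coefficients(self):
        assert 29525 - 15404 - 14172 == -51
        assert fd.dose_to_pixel(printed_curve(), 0.0) == pytest.approx(-51.0)

    def test_monotone_increasing(self, fitted_curve):
        assert fd.dose_to_pixel(fitted_curve, 200) > fd.dose_to_pixel(fitted_curve, 2)
        assert fitted_curve.is_monotone()

    def test_dose_10_near_observed_response(self):
        """The printed coefficients put f(10) near 1.04e4, within fit
        residuals of the observed 10328."""
        val = fd.dose_to_pixel(printed_curve(), 10.0)
        assert val == pytest.approx(1.04e4, rel=0.005)
        assert abs(val - 10328) < 300

    def test_negative_dose_rejected(self, fitted_curve):
        with pytest.raises(ValueError):
            fd.dose_to_pixel(fitted_curve, -1.0)


class TestInverse:
    def test_round_trip_at_50_mGy(self, fitted_curve):
        net = fd.dose_to_pixel(fitted_curve, 50.0)
        assert fd.pixel_to_dose(fitted_curve, net) == pytest.approx(50.0, abs=0.01)

    def test_bisection_matches_dense_grid_oracle(self, fitted_curve):
        grid = np.linspace(0, 200, 100_000)
        f = fd.dose_to_pixel(fitted_curve, grid)
        targets = np.linspace(f[0], f[-1], 257)
        oracle = grid[np.searchsorted(f, targets).clip(0, len(grid) - 1)]
        got = fd.pixel_to_dose(fitted_curve, targets)
        assert np.max(np.abs(got - oracle)) < 0.01

    def test_observed_25mGy_row_inverts_near_25(self, fitted_curve):
        """The measured net value 17911 maps back to ~25 mGy within the
        dose tolerance implied by the fit residual at that point."""
        dose = fd.pixel_to_dose(fitted_curve, 17911.0)
        c = fitted_curve
        slope_25 = -c.A1 * c.B1 * np.exp(-c.B1 * 25) - c.A2 * c.B2 * np.exp(-c.B2 * 25)
        # first-order tolerance, with 10% slack for the curve's curvature
        tol = 1.1 * abs(c(25.0) - 17911.0) / slope_25 + 0.01
        assert dose == pytest.approx(25.0, abs=tol)

    def test_saturation_and_floor_flags(self, fitted_curve):
        dose, flags = fd.pixel_to_dose(
            fitted_curve,
            np.array([fitted_curve(0.0) - 100, fitted_curve(100.0), 1e6]),
            return_flags=True,
        )
        assert dose[0] == 0.0 and flags[0] != FLAG_OK
        assert flags[1] == FLAG_OK
        assert dose[2] == 200.0 and flags[2] == FLAG_SATURATED

    @given(
        y0=st.floats(20000, 40000),
        b1=st.floats(0.005, 0.03),
        ratio=st.floats(2.0, 10.0),
        split=st.floats(0.2, 0.8),
        dose=st.floats(0.0, 200.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_property_over_curve_family(self, y0, b1, ratio, split, dose):
        """pixel_to_dose inverts dose_to_pixel within 0.05 mGy for any
        physically shaped curve (amplitudes splitting -y0, B1 < B2)."""
        curve = CalibrationCurve(
            y0=y0, A1=-y0 * split, B1=b1, A2=-y0 * (1 - split), B2=b1 * ratio
        )
        net = fd.dose_to_pixel(curve, dose)
        assert fd.pixel_to_dose(curve, net) == pytest.approx(dose, abs=0.05)


class TestApplyCalibration:
    def test_zero_net_image_maps_to_zero_dose(self):
        from filmdose3d.synthetic import default_forward_curve

        net = NetImage(np.zeros((5, 5)), dpi=150)
        dm = fd.apply_calibration(net, default_forward_curve())
        assert np.all(dm.values == 0.0)
        assert dm.spacing_mm == pytest.approx(25.4 / 150)

    def test_noiseless_synthetic_round_trip(self, infant_pipeline, infant_cfg):
        """Render -> read -> net -> dose recovers the field within 0.01 mGy."""
        err = np.abs(infant_pipeline["dose_map"].values - infant_pipeline["field"])
        assert err.max() < 0.01

    def test_saturated_pixel_masked_and_clamped(self, fitted_curve):
        net = NetImage(np.array([[100.0, fitted_curve(200.0) + 500]]), dpi=150)
        dm = fd.apply_calibration(net, fitted_curve)
        assert dm.mask[0, 1] == FLAG_SATURATED
        assert dm.values[0, 1] == 200.0


class TestExtractSegments:
    def _strip(self, values, seg=20):
        arr = np.concatenate([np.full((seg, 30), v) for v in values])
        return NetImage(arr.astype(float), dpi=150)

    def test_uniform_strip_gives_equal_values(self):
        strip = self._strip([500.0] * 6)
        layout = [
            (d, (i * 20, 0, (i + 1) * 20, 30))
            for i, d in enumerate([0, 2, 4, 6, 8, 10])
        ]
        table = fd.extract_segments(strip, layout)
        assert np.allclose(table.net_values, 500.0)

    def test_14_segment_layout_gives_14_rows(self):
        values = np.linspace(0, 28000, 14)
        strip = self._strip(values)
        layout = [(d, (i * 20, 0, (i + 1) * 20, 30)) for i, d in enumerate(TABLE_DOSES)]
        table = fd.extract_segments(strip, layout)
        assert table.n == 14
        assert np.array_equal(table.doses, TABLE_DOSES)

    def test_noisy_segment_means_near_truth(self):
        rng = np.random.default_rng(11)
        truth = np.linspace(100, 20000, 8)
        sigma = 50.0
        arr = np.concatenate(
            [np.full((40, 60), v) + rng.normal(0, sigma, (40, 60)) for v in truth]
        )
        strip = NetImage(np.maximum(arr, 0), dpi=150)
        layout = [(d, (i * 40, 0, (i + 1) * 40, 60)) for i, d in enumerate(range(8))]
        table = fd.extract_segments(strip, layout)
        # central 50% of a 40x60 ROI is ~1200 pixels
        tol = 3 * sigma / np.sqrt(1200)
        assert np.all(np.abs(table.net_values - truth) < 3 * tol)

    def test_overlapping_rois_rejected(self):
        strip = self._strip([1.0, 2.0])
        with pytest.raises(ValueError, match="overlap"):
            fd.extract_segments(strip, [(0, (0, 0, 25, 30)), (2, (20, 0, 40, 30))])

    def test_roi_outside_strip_rejected(self):
        strip = self._strip([1.0])
        with pytest.raises(ValueError, match="outside"):
            fd.extract_segments(strip, [(0, (0, 0, 100, 30))])
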