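"""Calibration fitting and peak-area quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nadflux import (
    AmbiguityError,
    CalibrationCurve,
    CalibrationStandard,
    CalibrationError,
    CellContext,
    DegenerateDesignError,
    InputError,
    SchemaError,
    build_labeling_table,
    fit_calibration,
    quantify_peak,
    quantify_table,
)
from nadflux.srm_quant import identity_curves


class TestFitCalibration:
    def test_exact_line(self, exact_standards):
        curve = fit_calibration(exact_standards, "d3-NAD+")
        assert curve.slope == pytest.approx(100.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.valid_range == (0.0, 5.0)
        assert curve.loq_pmol == 0.4

    def test_matches_normal_equation_oracle(self):
        # closed-form OLS on (1,95),(2,205),(4,400),(8,810):
        # slope = (n*Sxy - Sx*Sy) / (n*Sxx - Sx^2) = 11690/115
        stds = [
            CalibrationStandard("d0-Nam", x, y)
            for x, y in [(1, 95), (2, 205), (4, 400), (8, 810)]
        ]
        curve = fit_calibration(stds, "d0-Nam")
        assert curve.slope == pytest.approx(11690 / 115)
        assert curve.intercept == pytest.approx((1510 - 15 * 11690 / 115) / 4)

    def test_no_amount_spread_is_degenerate(self):
        stds = [CalibrationStandard("d4-Nam", 1.0, 100.0)] * 3
        with pytest.raises(DegenerateDesignError):
            fit_calibration(stds, "d4-Nam")

    def test_too_few_standards(self, exact_standards):
        with pytest.raises(DegenerateDesignError):
            fit_calibration(exact_standards[:2], "d3-NAD+")

    def test_fit_quality_gate(self):
        noisy = [
            CalibrationStandard("d0-NAD+", x, y)
            for x, y in [(1, 150), (2, 140), (4, 400), (8, 500)]
        ]
        with pytest.raises(CalibrationError):
            fit_calibration(noisy, "d0-NAD+")
        curve = fit_calibration(noisy, "d0-NAD+", enforce_fit_quality=False)
        assert curve.r_squared < 0.99

    def test_inverse_amount_weighting_excludes_blank(self, exact_standards):
        curve = fit_calibration(exact_standards, "d3-NAD+", weighting="1/x")
        assert curve.slope == pytest.approx(100.0)
        # the blank is excluded, so the calibrated range starts at 1 pmol
        assert curve.valid_range[0] == 1.0

    def test_negative_slope_rejected(self):
        stds = [
            CalibrationStandard("d3-Nam", x, y)
            for x, y in [(1, 500), (2, 400), (4, 200), (8, 1)]
        ]
        with pytest.raises(CalibrationError):
            fit_calibration(stds, "d3-Nam", enforce_fit_quality=False)


class TestQuantifyPeak:
    @pytest.fixture
    def curve(self):
        return CalibrationCurve(
            analyte="d3-NAD+",
            slope=100.0,
            intercept=0.0,
            r_squared=1.0,
            loq_pmol=0.4,
            valid_range=(0.0, 5.0),
        )

    def test_inverse_of_line(self, curve):
        q = quantify_peak(curve, 250.0)
        assert q.amount_pmol == pytest.approx(2.5)
        assert not q.below_loq and not q.out_of_range

    def test_below_loq_flagged(self, curve):
        q = quantify_peak(curve, 20.0)
        assert q.amount_pmol == pytest.approx(0.2)
        assert q.below_loq

    def test_area_at_intercept_is_zero(self, curve):
        q = quantify_peak(curve, 0.0)
        assert q.amount_pmol == 0.0
        assert q.below_loq

    def test_above_range_flagged(self, curve):
        assert quantify_peak(curve, 600.0).out_of_range

    def test_negative_area_rejected(self, curve):
        with pytest.raises(InputError):
            quantify_peak(curve, -1.0)

    @given(
        slope=st.floats(1e-3, 1e4),
        intercept=st.floats(0, 100),
        amount=st.floats(0.5, 4.9),
    )
    def test_round_trip_on_exact_line(self, slope, intercept, amount):
        """Inverting the fitted line recovers any in-range amount exactly."""
        stds = [
            CalibrationStandard("d0-NAD+", x, slope * x + intercept)
            for x in (0.0, 1.0, 2.0, 5.0)
        ]
        curve = fit_calibration(stds, "d0-NAD+")
        q = quantify_peak(curve, slope * amount + intercept)
        assert q.amount_pmol == pytest.approx(amount, rel=1e-9)

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=10))
    def test_monotone_in_peak_area(self, areas):
        curve = CalibrationCurve(
            analyte="d3-NAD+",
            slope=100.0,
            intercept=0.0,
            r_squared=1.0,
            loq_pmol=0.4,
            valid_range=(0.0, 5.0),
        )
        amounts = [quantify_peak(curve, a).amount_pmol for a in sorted(areas)]
        assert all(a1 <= a2 for a1, a2 in zip(amounts, amounts[1:]))


class TestBuildLabelingTable:
    def _peaks(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "time_h", "compartment", "analyte", "peak_area"]
        )

    def test_per_cell_normalization(self, hepg2_context):
        # 111.5 pmol of cellular d3-NAD+ at 4.04e5 cells -> 276 pmol/1e6 cells
        peaks = self._peaks([("s1", 3.0, "cells", "d3-NAD+", 111.5)])
        tables = build_labeling_table(peaks, identity_curves(), hepg2_context)
        tp = tables["s1"][0]
        assert tp.cell_d3_nad == pytest.approx(111.5 / 0.404, rel=1e-12)
        assert tp.cell_d3_nad == pytest.approx(276, rel=5e-4)
        assert tp.cell_d0_nad is None  # absent, not zero

    def test_identity_at_one_million_cells(self):
        context = CellContext(
            cell_count=1e6, cell_volume_pl=2.5, medium_volume_ml=1.0
        )
        peaks = self._peaks([("s1", 3.0, "cells", "d3-NAD+", 276.0)])
        tables = build_labeling_table(peaks, identity_curves(), context)
        assert tables["s1"][0].cell_d3_nad == pytest.approx(276.0)

    def test_unknown_analyte_rejected(self, hepg2_context):
        peaks = self._peaks([("s1", 3.0, "cells", "d2-NAD+", 10.0)])
        with pytest.raises(SchemaError):
            build_labeling_table(peaks, identity_curves(), hepg2_context)

    def test_duplicate_rows_rejected(self, hepg2_context):
        peaks = self._peaks(
            [
                ("s1", 3.0, "cells", "d3-NAD+", 10.0),
                ("s1", 3.0, "cells", "d3-NAD+", 11.0),
            ]
        )
        with pytest.raises(AmbiguityError):
            build_labeling_table(peaks, identity_curves(), hepg2_context)

    def test_compartment_analyte_mismatch_rejected(self, hepg2_context):
        peaks = self._peaks([("s1", 3.0, "medium", "d3-NAD+", 10.0)])
        with pytest.raises(SchemaError):
            build_labeling_table(peaks, identity_curves(), hepg2_context)

    def test_missing_curve_rejected(self, hepg2_context):
        peaks = self._peaks([("s1", 3.0, "cells", "d3-NAD+", 10.0)])
        curves = {k: v for k, v in identity_curves().items() if k != "d3-NAD+"}
        with pytest.raises(InputError):
            quantify_table(peaks, curves, hepg2_context)

    def test_flags_propagate_to_tidy_table(self, hepg2_context):
        curves = identity_curves(loq_pmol=0.4, valid_range=(0.0, 5.0))
        peaks = self._peaks(
            [
                ("s1", 3.0, "cells", "d3-NAD+", 0.2),
                ("s1", 3.0, "cells", "d0-NAD+", 50.0),
            ]
        )
        tidy = quantify_table(peaks, curves, hepg2_context).set_index("analyte")
        assert bool(tidy.loc["d3-NAD+", "below_loq"])
        assert bool(tidy.loc["d0-NAD+", "out_of_range"])
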