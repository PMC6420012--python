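"""SRM peak-area quantification through per-analyte calibration curves.

Selected reaction monitoring (SRM) on a triple-quadrupole instrument reports
one peak area per analyte transition.  Each of the five analytes tracked by
the assay (d0-NAD+, d3-NAD+, d0-Nam, d3-Nam, d4-Nam) gets its own calibration
line fitted to external standards; unknowns are inverted through the line and
flagged against the limit of quantification (LOQ) and the calibrated range.

The default LOQ is 0.4 pmol, the conservative end of the instrument's
0.1-0.4 pmol range; per-analyte overrides come from configuration.  SRM
transition settings (m/z pairs, collision energies) are provenance metadata
only and never enter the arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    AmbiguityError,
    CalibrationError,
    DegenerateDesignError,
    InputError,
    SchemaError,
)
from .flux_core import CellContext, LabelingTimepoint

__all__ = [
    "ANALYTES",
    "NAD_ANALYTES",
    "NAM_ANALYTES",
    "DEFAULT_LOQ_PMOL",
    "CalibrationStandard",
    "CalibrationCurve",
    "QuantifiedAmount",
    "fit_calibration",
    "quantify_peak",
    "quantify_table",
    "build_labeling_table",
    "identity_curves",
]

#: Analytes quantified by the assay and their compartment of measurement.
NAD_ANALYTES = ("d0-NAD+", "d3-NAD+")
NAM_ANALYTES = ("d0-Nam", "d3-Nam", "d4-Nam")
ANALYTES = NAD_ANALYTES + NAM_ANALYTES

#: Worst-case lower limit of quantification across the panel, pmol.
DEFAULT_LOQ_PMOL = 0.4

#: Timepoint field populated by each analyte (cells -> NAD+, medium -> Nam).
_ANALYTE_FIELD = {
    "d0-NAD+": ("cells", "cell_d0_nad"),
    "d3-NAD+": ("cells", "cell_d3_nad"),
    "d0-Nam": ("medium", "medium_d0_nam"),
    "d3-Nam": ("medium", "medium_d3_nam"),
    "d4-Nam": ("medium", "medium_d4_nam"),
}


@dataclass(frozen=True)
class CalibrationStandard:
    """One external standard: a known amount and its measured peak area."""

    analyte: str
    amount_pmol: float
    peak_area: float

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise SchemaError(f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}")
        if self.amount_pmol < 0:
            raise InputError(f"standard amount must be >= 0 pmol, got {self.amount_pmol}")
        if self.peak_area < 0:
            raise InputError(f"peak area must be >= 0, got {self.peak_area}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear detector response ``area = slope * amount + intercept``."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    loq_pmol: float
    valid_range: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"{self.analyte}: non-positive slope {self.slope}")
        if self.loq_pmol <= 0:
            raise InputError(f"{self.analyte}: LOQ must be > 0 pmol, got {self.loq_pmol}")
        if self.r_squared > 1 + 1e-12:
            raise InputError(f"{self.analyte}: r_squared {self.r_squared} > 1")


@dataclass(frozen=True)
class QuantifiedAmount:
    """A back-calculated amount with its quality flags.

    ``below_loq`` marks amounts under the limit of quantification (including
    areas at or below the fitted intercept, floored at 0); ``out_of_range``
    marks extrapolation beyond the calibrated amount range.  Flags are always
    carried, never used to drop or clip the value silently.
    """

    analyte: str
    amount_pmol: float
    below_loq: bool = False
    out_of_range: bool = False


def fit_calibration(
    standards: Iterable[CalibrationStandard],
    analyte: str,
    *,
    loq_pmol: Optional[float] = None,
    min_r_squared: float = 0.99,
    weighting: Optional[str] = None,
    enforce_fit_quality: bool = True,
) -> CalibrationCurve:
    """Fit a per-analyte calibration line by ordinary least squares.

    Parameters
    ----------
    standards
        Calibration standards; only those matching ``analyte`` are used.
        At least 3 standards spanning >= 2 distinct amounts are required.
    loq_pmol
        Limit of quantification for this analyte; defaults to the
        conservative panel-wide 0.4 pmol.
    min_r_squared
        Fit-quality gate.  Calibration lines in this assay are expected to
        be essentially exact; a poor fit raises ``CalibrationError`` unless
        ``enforce_fit_quality`` is switched off.
    weighting
        ``None`` (unweighted, default) or ``"1/x"`` for inverse-amount
        weighted least squares; zero-amount standards are excluded from a
        weighted fit.
    """
    pts = [s for s in standards if s.analyte == analyte]
    if len(pts) < 3:
        raise DegenerateDesignError(
            f"{analyte}: need >= 3 calibration standards, got {len(pts)}"
        )
    x = np.array([s.amount_pmol for s in pts], dtype=float)
    y = np.array([s.peak_area for s in pts], dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateDesignError(f"{analyte}: all standard amounts identical ({x[0]} pmol)")

    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "1/x":
        keep = x > 0
        if keep.sum() < 3:
            raise DegenerateDesignError(
                f"{analyte}: 1/x weighting needs >= 3 non-zero standards"
            )
        x, y = x[keep], y[keep]
        if np.unique(x).size < 2:
            raise DegenerateDesignError(f"{analyte}: no amount spread after excluding blanks")
        w = 1.0 / x
    else:
        raise InputError(f"unknown weighting {weighting!r}; use None or '1/x'")

    # Weighted normal equations for area = slope*amount + intercept.
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    if slope <= 0:
        raise CalibrationError(f"{analyte}: fitted slope {slope:.4g} is not positive")
    if enforce_fit_quality and r_squared < min_r_squared:
        raise CalibrationError(
            f"{analyte}: r_squared {r_squared:.4f} below the {min_r_squared} gate; "
            "pass enforce_fit_quality=False to override"
        )

    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(r_squared, 1.0)),
        loq_pmol=DEFAULT_LOQ_PMOL if loq_pmol is None else loq_pmol,
        valid_range=(float(np.min(x)), float(np.max(x))),
    )


def quantify_peak(curve: CalibrationCurve, peak_area: float) -> QuantifiedAmount:
    """Invert a peak area through a calibration curve.

    ``amount = (area - intercept) / slope`` floored at 0.  Amounts under the
    LOQ are flagged ``below_loq``; amounts outside the calibrated range are
    flagged ``out_of_range``.
    """
    if peak_area < 0:
        raise InputError(f"peak area must be >= 0, got {peak_area}")
    raw = (peak_area - curve.intercept) / curve.slope
    amount = max(raw, 0.0)
    lo, hi = curve.valid_range
    return QuantifiedAmount(
        analyte=curve.analyte,
        amount_pmol=amount,
        below_loq=amount < curve.loq_pmol,
        out_of_range=not (lo <= amount <= hi),
    )


def identity_curves(
    loq_pmol: float = DEFAULT_LOQ_PMOL,
    valid_range: Tuple[float, float] = (0.0, float("inf")),
) -> dict:
    """Unit-slope, zero-intercept curves: peak areas read directly as pmol.

    Convenient when a table already carries amounts, or for simulator output
    emitted without a detector-response model.
    """
    return {
        analyte: CalibrationCurve(
            analyte=analyte,
            slope=1.0,
            intercept=0.0,
            r_squared=1.0,
            loq_pmol=loq_pmol,
            valid_range=valid_range,
        )
        for analyte in ANALYTES
    }


_PEAK_COLUMNS = ["sample_id", "time_h", "compartment", "analyte", "peak_area"]


def _check_peak_table(peak_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _PEAK_COLUMNS if c not in peak_table.columns]
    if missing:
        raise SchemaError(f"peak table lacks columns {missing}; expected {_PEAK_COLUMNS}")
    unknown = set(peak_table["analyte"]) - set(ANALYTES)
    if unknown:
        raise SchemaError(f"unknown analyte label(s) {sorted(unknown)}; expected {ANALYTES}")
    bad_comp = set(peak_table["compartment"]) - {"cells", "medium"}
    if bad_comp:
        raise SchemaError(f"unknown compartment(s) {sorted(bad_comp)}; expected cells|medium")
    dup = peak_table.duplicated(subset=["sample_id", "time_h", "analyte"])
    if dup.any():
        rows = peak_table.loc[dup, ["sample_id", "time_h", "analyte"]].drop_duplicates()
        raise AmbiguityError(
            "duplicate (sample, time, analyte) rows: "
            + "; ".join(f"{r.sample_id}/{r.time_h}/{r.analyte}" for r in rows.itertuples())
        )
    for row in peak_table.itertuples():
        expected_comp = _ANALYTE_FIELD[row.analyte][0]
        if row.compartment != expected_comp:
            raise SchemaError(
                f"{row.analyte} measured in {row.compartment!r}; the assay measures it in "
                f"{expected_comp!r}"
            )
    return peak_table


def quantify_table(
    peak_table: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    context: CellContext,
) -> pd.DataFrame:
    """Quantify a tidy peak-area table into pmol per 10^6 cells.

    Input columns: ``sample_id,time_h,compartment,analyte,peak_area``.
    Output adds ``amount_pmol_per_1e6cells,below_loq,out_of_range``.
    """
    peak_table = _check_peak_table(peak_table)
    missing = set(peak_table["analyte"]) - set(curves)
    if missing:
        raise InputError(f"no calibration curve for analyte(s) {sorted(missing)}")

    records = []
    for row in peak_table.itertuples():
        q = quantify_peak(curves[row.analyte], row.peak_area)
        records.append(
            {
                "sample_id": row.sample_id,
                "time_h": float(row.time_h),
                "compartment": row.compartment,
                "analyte": row.analyte,
                "amount_pmol_per_1e6cells": q.amount_pmol / context.cell_count * 1e6,
                "below_loq": q.below_loq,
                "out_of_range": q.out_of_range,
            }
        )
    return pd.DataFrame.from_records(records)


def build_labeling_table(
    peak_table: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    context: CellContext,
) -> dict:
    """Convert a peak-area table into labeling timepoints per sample.

    Returns ``{sample_id: [LabelingTimepoint, ...]}`` with each sample's
    timepoints sorted by time.  Cell-compartment rows populate the NAD+
    isotopologues and medium rows the Nam isotopomers; analytes missing from
    a (sample, time) group stay absent (``None``), never zero.
    """
    quantified = quantify_table(peak_table, curves, context)
    out: dict = {}
    for (sample_id, time_h), group in quantified.groupby(["sample_id", "time_h"], sort=True):
        fields = {}
        for row in group.itertuples():
            fields[_ANALYTE_FIELD[row.analyte][1]] = row.amount_pmol_per_1e6cells
        out.setdefault(sample_id, []).append(LabelingTimepoint(time_h=time_h, **fields))
    for tps in out.values():
        tps.sort(key=lambda tp: tp.time_h)
    return out


def read_standards_csv(path) -> list:
    """Read a standards CSV with header ``analyte,amount_pmol,peak_area``."""
    df = pd.read_csv(path)
    required = ["analyte", "amount_pmol", "peak_area"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"standards table lacks columns {missing}")
    return [
        CalibrationStandard(row.analyte, float(row.amount_pmol), float(row.peak_area))
        for row in df.itertuples()
    ]
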