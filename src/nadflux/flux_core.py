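"""Core flux estimators for the d4-nicotinamide NAD+ labeling assay.

The assay replaces the unlabeled nicotinamide (d0-Nam) in the culture medium
with ring-deuterated d4-Nam at the same concentration.  Salvage synthesis
through Nampt then produces M+3-labeled NAD+ (d3-NAD+; one ring deuterium is
lost during redox cycling), while the pre-existing d0-NAD+ pool is consumed
by NAD+-degrading enzymes.  Over a labeling window of length ``t`` hours:

* ``a`` = d3-NAD+ appeared (pmol per 10^6 cells)  ->  synthesis rate
  ``R_S = a / t``
* ``b`` = d0-NAD+ decreased (pmol per 10^6 cells) ->  breakdown rate
  ``R_B = b / t``

Per-cell amounts convert to absolute intracellular concentrations through
the mean single-cell volume: pmol per 10^6 cells divided by pL per cell is
exactly uM (10^6 cells x 1 pL = 1 uL, and pmol/uL = uM).  Under first-order
breakdown the NAD+ half-life is ``t_1/2 = ln(2) * C / R_B``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InputError, InsufficientDataError

__all__ = [
    "LabelingTimepoint",
    "CellContext",
    "FluxResult",
    "compute_rs",
    "compute_rb",
    "total_nad",
    "amount_to_concentration",
    "half_life",
    "fold_change",
    "estimate_fluxes",
    "fit_labeling_slope",
    "estimate_fluxes_series",
]


def _check_nonneg(name: str, value: Optional[float]) -> None:
    if value is not None and value < 0:
        raise InputError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class LabelingTimepoint:
    """Measured isotopologue amounts at one time, in pmol per 10^6 cells.

    Cellular NAD+ isotopologues come from the cell extract; Nam isotopomers
    from the culture medium.  A missing measurement is ``None`` (absent),
    never silently zero.
    """

    time_h: float
    cell_d3_nad: Optional[float] = None
    cell_d0_nad: Optional[float] = None
    medium_d3_nam: Optional[float] = None
    medium_d0_nam: Optional[float] = None
    medium_d4_nam: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise InputError(f"time_h must be >= 0, got {self.time_h}")
        for name in (
            "cell_d3_nad",
            "cell_d0_nad",
            "medium_d3_nam",
            "medium_d0_nam",
            "medium_d4_nam",
        ):
            _check_nonneg(name, getattr(self, name))

    @property
    def has_medium_nam(self) -> bool:
        return (
            self.medium_d3_nam is not None
            and self.medium_d0_nam is not None
            and self.medium_d4_nam is not None
        )


@dataclass(frozen=True)
class CellContext:
    """Normalization basis for one sample.

    cell_count
        Number of cells in the labeled well (Coulter-type counter).
    cell_volume_pl
        Mean single-cell volume in pL from the same counter; the divisor
        that turns per-cell amounts into uM.
    medium_volume_ml
        Culture medium volume in mL.
    d4_nam_conc_um
        d4-Nam concentration in the medium at the switch, uM.
    """

    cell_count: float
    cell_volume_pl: float
    medium_volume_ml: float
    d4_nam_conc_um: float = 2.0

    def __post_init__(self) -> None:
        for name in ("cell_count", "cell_volume_pl", "medium_volume_ml", "d4_nam_conc_um"):
            value = getattr(self, name)
            if value <= 0:
                raise InputError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class FluxResult:
    """Output record of the flux assay for one sample.

    Rates are stored on the per-cell basis (pmol per 10^6 cells per h) and on
    the absolute cell-volume basis (uM/h).  ``half_life_h`` is ``None`` when
    breakdown was not observed.  ``valid`` is ``None`` when no medium Nam
    measurements were available to run the recycling check.
    """

    r_s: float
    r_b: float
    r_s_um_h: float
    r_b_um_h: float
    total_nad: float
    nad_conc_um: float
    half_life_h: Optional[float]
    valid: Optional[bool] = None
    b_clamped: bool = False
    recycling_report: Optional[object] = field(default=None, repr=False)


def compute_rs(d3_nad_appeared: float, time_h: float) -> float:
    """Synthesis rate R_S = a / t, pmol per 10^6 cells per h."""
    if time_h <= 0:
        raise InputError(f"labeling time must be > 0 h, got {time_h}")
    if d3_nad_appeared < 0:
        raise InputError(
            f"d3-NAD+ appeared must be >= 0 (labels cannot vanish), got {d3_nad_appeared}"
        )
    return d3_nad_appeared / time_h


def compute_rb(d0_nad_decreased: float, time_h: float) -> float:
    """Breakdown rate R_B = b / t, pmol per 10^6 cells per h.

    A negative observed decrease (d0-NAD+ apparently rising, possible under
    measurement noise) is clamped to zero with a warning rather than raising,
    so a noisy replicate does not halt a batch.
    """
    if time_h <= 0:
        raise InputError(f"labeling time must be > 0 h, got {time_h}")
    if d0_nad_decreased < 0:
        warnings.warn(
            f"negative d0-NAD+ decrease ({d0_nad_decreased:.3g}) clamped to 0",
            stacklevel=2,
        )
        d0_nad_decreased = 0.0
    return d0_nad_decreased / time_h


def total_nad(d3: float, d0: float) -> float:
    """Total NAD+ content as the sum of the d3 and d0 isotopologues."""
    if d3 < 0 or d0 < 0:
        raise InputError("NAD+ isotopologue amounts must be >= 0")
    return d3 + d0


def amount_to_concentration(amount: float, cell_volume_pl: float) -> float:
    """Convert pmol per 10^6 cells into uM using the mean cell volume in pL.

    The conversion is an exact unit identity: 10^6 cells x 1 pL = 1 uL, and
    pmol/uL = uM.
    """
    if cell_volume_pl <= 0:
        raise InputError(f"cell volume must be > 0 pL, got {cell_volume_pl}")
    return amount / cell_volume_pl


def half_life(nad_conc_um: float, r_b_um_h: float) -> Optional[float]:
    """NAD+ half-life t_1/2 = ln(2) * C / R_B under first-order breakdown.

    Returns ``None`` (undefined) when ``r_b_um_h`` is zero — with no
    observed breakdown the pool never halves.
    """
    if nad_conc_um < 0 or r_b_um_h < 0:
        raise InputError("concentration and breakdown rate must be >= 0")
    if r_b_um_h == 0:
        return None
    return math.log(2.0) * nad_conc_um / r_b_um_h


def fold_change(value: float, baseline: float) -> float:
    """Ratio of a quantity to its baseline (same units)."""
    if baseline <= 0:
        raise InputError(f"baseline must be > 0, got {baseline}")
    return value / baseline


def estimate_fluxes(
    t0: LabelingTimepoint,
    tN: LabelingTimepoint,
    context: CellContext,
    *,
    recycling_threshold: float = 0.10,
) -> FluxResult:
    """Two-point flux estimate between the medium switch (t0) and tN.

    ``a`` is the d3-NAD+ appeared and ``b`` the d0-NAD+ decreased over the
    window; total NAD+ and its concentration are taken at tN.  When tN
    carries medium Nam isotopomer amounts, the Nam-recycling validity check
    is run and its verdict stored in ``valid``.
    """
    dt = tN.time_h - t0.time_h
    if dt <= 0:
        raise InputError(f"tN must be later than t0 (got dt = {dt} h)")
    for name, tp in (("t0", t0), ("tN", tN)):
        if tp.cell_d3_nad is None or tp.cell_d0_nad is None:
            raise InputError(f"{name} lacks cellular NAD+ isotopologue measurements")

    a = tN.cell_d3_nad - t0.cell_d3_nad
    if a < 0:
        raise InputError(f"d3-NAD+ decreased over the window (a = {a:.3g}); labels cannot vanish")
    b = t0.cell_d0_nad - tN.cell_d0_nad
    b_clamped = b < 0

    r_s = compute_rs(a, dt)
    r_b = compute_rb(b, dt)
    tot = total_nad(tN.cell_d3_nad, tN.cell_d0_nad)
    conc = amount_to_concentration(tot, context.cell_volume_pl)
    r_s_um = amount_to_concentration(r_s, context.cell_volume_pl)
    r_b_um = amount_to_concentration(r_b, context.cell_volume_pl)
    t12 = half_life(conc, r_b_um)

    valid: Optional[bool] = None
    report = None
    if tN.has_medium_nam:
        from .validation import recycling_check

        report = recycling_check(
            tN.medium_d3_nam,
            tN.medium_d0_nam,
            tN.medium_d4_nam,
            threshold=recycling_threshold,
        )
        valid = bool(report.passed) and not b_clamped

    return FluxResult(
        r_s=r_s,
        r_b=r_b,
        r_s_um_h=r_s_um,
        r_b_um_h=r_b_um,
        total_nad=tot,
        nad_conc_um=conc,
        half_life_h=t12,
        valid=valid,
        b_clamped=b_clamped,
        recycling_report=report,
    )


def fit_labeling_slope(
    times_h: Sequence[float],
    amounts: Sequence[float],
    *,
    through_origin: bool = True,
) -> float:
    """OLS slope of amount vs time, by default constrained through the origin.

    The through-origin form matches the labeling protocol: d3-NAD+ is exactly
    zero at the medium switch.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(amounts, dtype=float)
    if t.size != y.size or t.size < 2:
        raise InsufficientDataError("need >= 2 matched (time, amount) points")
    if through_origin:
        denom = float(np.dot(t, t))
        if denom == 0:
            raise InputError("all times are zero; slope is unidentified")
        return float(np.dot(t, y) / denom)
    if np.ptp(t) == 0:
        raise InputError("times have no spread; slope is unidentified")
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def estimate_fluxes_series(
    timepoints: Sequence[LabelingTimepoint],
    context: CellContext,
    *,
    recycling_threshold: float = 0.10,
) -> FluxResult:
    """Multi-timepoint flux estimate for a labeling time course.

    R_S is the through-origin OLS slope of d3-NAD+ vs time; R_B the negated
    free-intercept OLS slope of d0-NAD+ vs time.  Total NAD+, concentration,
    half-life, and the validity check are taken at the last timepoint.
    """
    tps = sorted(timepoints, key=lambda tp: tp.time_h)
    if len(tps) < 3:
        raise InsufficientDataError("series estimator needs >= 3 timepoints")
    for tp in tps:
        if tp.cell_d3_nad is None or tp.cell_d0_nad is None:
            raise InputError(f"timepoint at {tp.time_h} h lacks NAD+ measurements")
    times = [tp.time_h for tp in tps]
    r_s = fit_labeling_slope(times, [tp.cell_d3_nad for tp in tps], through_origin=True)
    d0_slope = fit_labeling_slope(
        times, [tp.cell_d0_nad for tp in tps], through_origin=False
    )
    b_clamped = d0_slope > 0
    if b_clamped:
        warnings.warn("d0-NAD+ slope is positive; breakdown rate clamped to 0", stacklevel=2)
    r_b = max(-d0_slope, 0.0)
    if r_s < 0:
        raise InputError(f"negative d3-NAD+ slope ({r_s:.3g}); labels cannot vanish")

    last = tps[-1]
    tot = total_nad(last.cell_d3_nad, last.cell_d0_nad)
    conc = amount_to_concentration(tot, context.cell_volume_pl)
    r_s_um = amount_to_concentration(r_s, context.cell_volume_pl)
    r_b_um = amount_to_concentration(r_b, context.cell_volume_pl)

    valid: Optional[bool] = None
    report = None
    if last.has_medium_nam:
        from .validation import recycling_check

        report = recycling_check(
            last.medium_d3_nam,
            last.medium_d0_nam,
            last.medium_d4_nam,
            threshold=recycling_threshold,
        )
        valid = bool(report.passed) and not b_clamped

    return FluxResult(
        r_s=r_s,
        r_b=r_b,
        r_s_um_h=r_s_um,
        r_b_um_h=r_b_um,
        total_nad=tot,
        nad_conc_um=conc,
        half_life_h=half_life(conc, r_b_um),
        valid=valid,
        b_clamped=b_clamped,
        recycling_report=report,
    )
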