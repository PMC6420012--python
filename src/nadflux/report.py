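"""Cross-sample analysis: regressions, dose-response, induction tables.

These are the summary analyses run across samples or conditions once the
per-sample fluxes exist: ordinary least-squares relationships (e.g. R_S vs
total Nampt activity, R_S vs R_B), the Nam dose-response saturation summary,
and fold-change tables against an uninduced baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .flux_core import fold_change

__all__ = [
    "RegressionSummary",
    "regress",
    "DoseResponseSummary",
    "dose_response_summary",
    "induction_table",
    "flux_table",
]


@dataclass(frozen=True)
class RegressionSummary:
    """OLS line y = slope * x + intercept with its determination coefficient."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def regress(x: Sequence[float], y: Sequence[float]) -> RegressionSummary:
    """Ordinary least squares of y on x with a free intercept.

    ``r_squared`` is the squared Pearson correlation.  A degenerate design
    (constant x) raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InputError("regress needs two equal-length arrays with >= 2 points")
    if np.ptp(x) == 0:
        raise InputError("x has no spread; the slope is unidentified")
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(x.size),
    )


@dataclass(frozen=True)
class DoseResponseSummary:
    """Saturation summary of synthesis rate vs precursor concentration.

    ``saturating_conc`` is the smallest concentration whose rate reaches at
    least ``threshold_frac`` of the maximum observed rate.  When only the
    highest tested concentration qualifies the response never plateaued
    within the tested range and ``saturated`` is False.
    """

    table: pd.DataFrame
    saturating_conc: float
    saturated: bool
    threshold_frac: float


def dose_response_summary(
    conc_um: Sequence[float],
    r_s: Sequence[float],
    *,
    threshold_frac: float = 0.95,
) -> DoseResponseSummary:
    """Tabulate R_S vs medium Nam concentration and locate saturation."""
    conc = np.asarray(conc_um, dtype=float)
    rates = np.asarray(r_s, dtype=float)
    if conc.size != rates.size or conc.size < 3:
        raise InputError("dose-response needs >= 3 matched (conc, rate) points")
    order = np.argsort(conc)
    conc, rates = conc[order], rates[order]
    table = pd.DataFrame({"nam_conc_uM": conc, "r_s": rates})

    cutoff = threshold_frac * rates.max()
    qualifying = conc[rates >= cutoff]
    saturating = float(qualifying.min())
    saturated = saturating < conc.max()
    if not saturated:
        warnings.warn(
            "only the highest tested concentration reaches the saturation "
            "threshold; the response is not saturated within the tested range",
            stacklevel=2,
        )
    return DoseResponseSummary(
        table=table,
        saturating_conc=saturating,
        saturated=saturated,
        threshold_frac=threshold_frac,
    )


def induction_table(
    conditions: Sequence[Tuple[str, float, float, float, float]],
    baseline_label: str,
) -> pd.DataFrame:
    """Fold changes of activity, R_S, R_B and NAD+ against a baseline row.

    ``conditions`` rows are ``(label, total_activity, r_s, r_b, nad_conc)``
    in any consistent units; exactly one label must match
    ``baseline_label``.
    """
    df = pd.DataFrame(
        conditions, columns=["label", "total_activity", "r_s", "r_b", "nad_conc"]
    )
    base = df[df["label"] == baseline_label]
    if len(base) != 1:
        raise InputError(
            f"exactly one baseline row labelled {baseline_label!r} required, found {len(base)}"
        )
    base = base.iloc[0]
    for col in ("total_activity", "r_s", "r_b", "nad_conc"):
        df[f"{col}_fold"] = [fold_change(v, base[col]) for v in df[col]]
    return df


def flux_table(
    quantified: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    recycling_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-sample two-point flux estimates from a quantified-amounts table.

    The quantified table (columns ``sample_id,time_h,compartment,analyte,
    amount_pmol_per_1e6cells,...``) is treated as one labeling series: the
    time-0 samples (averaged if replicated) form the baseline and every
    later sample gets its own flux estimate against it.  Metadata supplies
    each sample's cell context.
    """
    from .flux_core import CellContext, LabelingTimepoint, estimate_fluxes

    field_of = {
        "d0-NAD+": "cell_d0_nad",
        "d3-NAD+": "cell_d3_nad",
        "d0-Nam": "medium_d0_nam",
        "d3-Nam": "medium_d3_nam",
        "d4-Nam": "medium_d4_nam",
    }

    meta = metadata.set_index("sample_id")

    def timepoint(group: pd.DataFrame, time_h: float) -> LabelingTimepoint:
        fields: Dict[str, float] = {}
        for analyte, sub in group.groupby("analyte"):
            fields[field_of[analyte]] = float(sub["amount_pmol_per_1e6cells"].mean())
        return LabelingTimepoint(time_h=time_h, **fields)

    t0_rows = quantified[quantified["time_h"] == 0.0]
    if t0_rows.empty:
        raise InputError("no time-0 baseline sample in the quantified table")
    t0 = timepoint(t0_rows, 0.0)

    records = []
    for sample_id, group in quantified[quantified["time_h"] > 0].groupby("sample_id"):
        time_h = float(group["time_h"].iloc[0])
        if sample_id not in meta.index:
            raise InputError(f"sample {sample_id!r} missing from metadata")
        m = meta.loc[sample_id]
        context = CellContext(
            cell_count=float(m["cell_count"]),
            cell_volume_pl=float(m["cell_volume_pL"]),
            medium_volume_ml=float(m["medium_volume_mL"]),
            d4_nam_conc_um=float(m["d4_nam_conc_uM"]),
        )
        res = estimate_fluxes(
            t0, timepoint(group, time_h), context, recycling_threshold=recycling_threshold
        )
        records.append(
            {
                "sample_id": sample_id,
                "r_s_pmol_per_1e6cells_h": res.r_s,
                "r_b_pmol_per_1e6cells_h": res.r_b,
                "r_s_uM_h": res.r_s_um_h,
                "r_b_uM_h": res.r_b_um_h,
                "total_nad_pmol_per_1e6cells": res.total_nad,
                "nad_conc_uM": res.nad_conc_um,
                "half_life_h": res.half_life_h if res.half_life_h is not None else np.nan,
                "valid": res.valid,
            }
        )
    return pd.DataFrame(records)
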