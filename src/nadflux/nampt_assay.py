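"""Total Nampt activity from the cell-lysate assay.

Lysates are incubated with saturating substrate (50 uM Nam, 0.3 mM PRPP) so
the product formation rate reads out the maximal enzyme activity, free of
the NAD+ feedback present in intact cells.  Normalizing to the same per-cell
and cell-volume bases as the in-cell synthesis rate R_S makes the two
directly comparable: the ratio R_S / total activity quantifies how strongly
Nampt is suppressed in situ (well below 1 in resting cells).

Radioactivity-to-pmol conversion happens upstream; records carry product
amounts in pmol, keeping the module instrument-agnostic.  No
substrate-depletion correction is applied to the 1-h assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError, SchemaError
from .flux_core import amount_to_concentration

__all__ = [
    "LysateAssayRecord",
    "specific_activity",
    "activity_concentration",
    "suppression_ratio",
    "read_lysate_csv",
]


@dataclass(frozen=True)
class LysateAssayRecord:
    """One lysate-assay measurement.

    ``cells_equivalent`` is the number of cells whose lysate went into the
    reaction — the normalization basis.  Substrate concentrations are
    context metadata recording the assay conditions.
    """

    product_amount_pmol: float
    incubation_time_h: float
    cells_equivalent: float
    substrate_conc_um: float = 50.0
    prpp_conc_um: float = 300.0

    def __post_init__(self) -> None:
        if self.product_amount_pmol < 0:
            raise InputError(f"product amount must be >= 0, got {self.product_amount_pmol}")
        if self.incubation_time_h <= 0:
            raise InputError(f"incubation time must be > 0 h, got {self.incubation_time_h}")
        if self.cells_equivalent <= 0:
            raise InputError(f"cells_equivalent must be > 0, got {self.cells_equivalent}")


def specific_activity(rec: LysateAssayRecord) -> float:
    """Nampt specific activity, pmol NMN per 10^6 cells per h."""
    return rec.product_amount_pmol / rec.incubation_time_h / rec.cells_equivalent * 1e6


def activity_concentration(spec_act: float, cell_volume_pl: float) -> float:
    """Convert a per-cell activity into uM/h via the mean cell volume."""
    if spec_act < 0:
        raise InputError(f"specific activity must be >= 0, got {spec_act}")
    return amount_to_concentration(spec_act, cell_volume_pl)


def suppression_ratio(r_s_um_h: float, total_activity_um_h: float) -> float:
    """In-cell synthesis rate over maximal lysate activity (same units).

    Values far below 1 indicate that Nampt runs well under its capacity in
    intact cells.
    """
    if total_activity_um_h <= 0:
        raise InputError(f"total activity must be > 0, got {total_activity_um_h}")
    if r_s_um_h < 0:
        raise InputError(f"R_S must be >= 0, got {r_s_um_h}")
    return r_s_um_h / total_activity_um_h


def read_lysate_csv(path) -> pd.DataFrame:
    """Read a lysate CSV (``sample_id,product_pmol,time_h,cells_equivalent``)
    and append the per-cell specific activity column."""
    df = pd.read_csv(path)
    required = ["sample_id", "product_pmol", "time_h", "cells_equivalent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"lysate table lacks columns {missing}")
    df = df.copy()
    df["specific_activity_pmol_per_1e6cells_h"] = [
        specific_activity(
            LysateAssayRecord(
                product_amount_pmol=float(r.product_pmol),
                incubation_time_h=float(r.time_h),
                cells_equivalent=float(r.cells_equivalent),
            )
        )
        for r in df.itertuples()
    ]
    return df
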