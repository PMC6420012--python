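"""Assay-validity checks for the labeling experiment.

Accurate two-point flux estimation requires that (1) nicotinamide released by
NAD+ breakdown (d3-Nam, d0-Nam) has not accumulated enough in the medium to
be re-incorporated at a meaningful rate — otherwise both rates are
underestimated; (2) labeled NAD+ accumulates linearly over the labeling
window; and (3) the labeled and unlabeled precursors are bioequivalent.
These checks are descriptive tolerance gates, not hypothesis tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .errors import InputError, InsufficientDataError

__all__ = [
    "RecyclingReport",
    "LinearityReport",
    "EquivalenceReport",
    "recycling_check",
    "linearity_check",
    "equivalence_check",
]

#: Combined d3+d0 medium Nam fraction accepted as "no significant recycling".
#: The assay's reference 3-h run shows 6.4%; 10% is a round configurable bound.
DEFAULT_RECYCLING_THRESHOLD = 0.10
DEFAULT_LINEARITY_MIN_R2 = 0.98
DEFAULT_EQUIVALENCE_TOLERANCE = 0.15


@dataclass(frozen=True)
class RecyclingReport:
    """Isotopomer composition of the medium Nam pool and its verdict."""

    frac_d3_nam: float
    frac_d0_nam: float
    frac_d4_nam: float
    combined_nonprecursor_frac: float
    threshold: float
    passed: bool

    def as_dict(self) -> Dict[str, float]:
        return {
            "frac_d3_nam": self.frac_d3_nam,
            "frac_d0_nam": self.frac_d0_nam,
            "frac_d4_nam": self.frac_d4_nam,
            "combined_nonprecursor_frac": self.combined_nonprecursor_frac,
            "threshold": self.threshold,
            "passed": self.passed,
        }


@dataclass(frozen=True)
class LinearityReport:
    slope: float
    r_squared: float
    min_r_squared: float
    passed: bool

    def as_dict(self) -> Dict[str, float]:
        return {
            "slope": self.slope,
            "r_squared": self.r_squared,
            "min_r_squared": self.min_r_squared,
            "passed": self.passed,
        }


@dataclass(frozen=True)
class EquivalenceReport:
    group_means: Dict[str, float]
    max_relative_difference: float
    tolerance: float
    passed: bool

    def as_dict(self) -> Dict[str, object]:
        return {
            "group_means": dict(self.group_means),
            "max_relative_difference": self.max_relative_difference,
            "tolerance": self.tolerance,
            "passed": self.passed,
        }


def recycling_check(
    medium_d3_nam: float,
    medium_d0_nam: float,
    medium_d4_nam: float,
    *,
    threshold: float = DEFAULT_RECYCLING_THRESHOLD,
) -> RecyclingReport:
    """Check that breakdown-derived Nam stays negligible next to the tracer.

    Fractions are of the total medium Nam pool; the check passes when the
    combined non-precursor (d3 + d0) fraction is at or below ``threshold``.
    """
    amounts = (medium_d3_nam, medium_d0_nam, medium_d4_nam)
    if any(a < 0 for a in amounts):
        raise InputError(f"medium Nam amounts must be >= 0, got {amounts}")
    total = sum(amounts)
    if total <= 0:
        raise InputError("total medium Nam is zero; recycling fractions undefined")
    f3, f0, f4 = (a / total for a in amounts)
    combined = f3 + f0
    return RecyclingReport(
        frac_d3_nam=f3,
        frac_d0_nam=f0,
        frac_d4_nam=f4,
        combined_nonprecursor_frac=combined,
        threshold=threshold,
        passed=combined <= threshold,
    )


def linearity_check(
    series: Sequence[Tuple[float, float]],
    *,
    min_r_squared: float = DEFAULT_LINEARITY_MIN_R2,
) -> LinearityReport:
    """Check that d3-NAD+ rises linearly with labeling time.

    Fits amount = slope * time through the origin (d3-NAD+ is structurally
    zero at the switch) and scores it with the conventional coefficient of
    determination around the mean, so saturating curves are penalized.
    """
    if len(series) < 3:
        raise InsufficientDataError(f"linearity check needs >= 3 timepoints, got {len(series)}")
    t = np.array([p[0] for p in series], dtype=float)
    y = np.array([p[1] for p in series], dtype=float)
    denom = float(np.dot(t, t))
    if denom == 0:
        raise InputError("all times are zero; slope is unidentified")
    slope = float(np.dot(t, y) / denom)
    resid = y - slope * t
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearityReport(
        slope=slope,
        r_squared=r_squared,
        min_r_squared=min_r_squared,
        passed=r_squared >= min_r_squared,
    )


def equivalence_check(
    groups: Mapping[str, Sequence[float]],
    *,
    tolerance: float = DEFAULT_EQUIVALENCE_TOLERANCE,
) -> EquivalenceReport:
    """Check that precursor isotopomers yield equivalent NAD+ readouts.

    Each group holds readouts for one precursor condition (e.g. d0-, d3-,
    d4-Nam).  The statistic is the largest relative deviation of any group
    mean from the grand mean of the group means.
    """
    if len(groups) < 2:
        raise InputError(f"equivalence check needs >= 2 groups, got {len(groups)}")
    means = {}
    for name, values in groups.items():
        values = list(values)
        if not values:
            raise InputError(f"group {name!r} is empty")
        means[name] = float(np.mean(values))
    grand = float(np.mean(list(means.values())))
    if grand <= 0:
        raise InputError("grand mean must be > 0 for a relative comparison")
    max_rel = max(abs(m - grand) / grand for m in means.values())
    return EquivalenceReport(
        group_means=means,
        max_relative_difference=max_rel,
        tolerance=tolerance,
        passed=max_rel <= tolerance,
    )
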