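"""YAML configuration and run-provenance helpers.

One YAML file governs all pipeline stages, with sections ``calibration``,
``flux``, ``validation``, ``simulation`` and ``report``.  Example::

    calibration:
      min_r_squared: 0.99
      weighting: null          # or "1/x"
      loq_pmol:
        d0-NAD+: 0.4
        d3-Nam: 0.1
    validation:
      recycling_threshold: 0.10
      linearity_min_r_squared: 0.98
      equivalence_tolerance: 0.15
    simulation:
      vmax: 637.9
      seed: 1

Unknown keys are rejected early so typos do not silently fall back to
defaults.  Every CLI run writes a provenance header (config hash, seed,
input digests) so results are replayable.
"""

from __future__ import annotations

import hashlib
from dataclasses import fields as dataclass_fields
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .errors import InputError
from .salvage_sim import KineticParams

__all__ = [
    "load_config",
    "calibration_options",
    "validation_options",
    "kinetic_params_from_config",
    "sha256_file",
]

_SECTIONS = {"calibration", "flux", "validation", "simulation", "report"}
_CALIBRATION_KEYS = {"min_r_squared", "weighting", "loq_pmol"}
_VALIDATION_KEYS = {
    "recycling_threshold",
    "linearity_min_r_squared",
    "equivalence_tolerance",
}


def load_config(path: Optional[str]) -> Dict[str, Any]:
    """Load and structurally check a YAML config; ``None`` means defaults."""
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InputError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise InputError(f"unknown config section(s) {sorted(unknown)}; expected {_SECTIONS}")
    cal = raw.get("calibration") or {}
    bad = set(cal) - _CALIBRATION_KEYS
    if bad:
        raise InputError(f"unknown calibration key(s) {sorted(bad)}")
    val = raw.get("validation") or {}
    bad = set(val) - _VALIDATION_KEYS
    if bad:
        raise InputError(f"unknown validation key(s) {sorted(bad)}")
    sim = raw.get("simulation") or {}
    allowed = {f.name for f in dataclass_fields(KineticParams)} | {"times", "replicates"}
    bad = set(sim) - allowed
    if bad:
        raise InputError(f"unknown simulation key(s) {sorted(bad)}")
    return raw


def calibration_options(config: Dict[str, Any]) -> Dict[str, Any]:
    cal = config.get("calibration") or {}
    return {
        "min_r_squared": float(cal.get("min_r_squared", 0.99)),
        "weighting": cal.get("weighting"),
        "loq_pmol": dict(cal.get("loq_pmol") or {}),
    }


def validation_options(config: Dict[str, Any]) -> Dict[str, float]:
    val = config.get("validation") or {}
    return {
        "recycling_threshold": float(val.get("recycling_threshold", 0.10)),
        "linearity_min_r_squared": float(val.get("linearity_min_r_squared", 0.98)),
        "equivalence_tolerance": float(val.get("equivalence_tolerance", 0.15)),
    }


def kinetic_params_from_config(
    config: Dict[str, Any], seed: Optional[int] = None
) -> KineticParams:
    """Build ``KineticParams`` from the ``simulation`` section.

    An explicit ``seed`` argument (e.g. from the command line) overrides the
    config value.
    """
    sim = dict(config.get("simulation") or {})
    sim.pop("times", None)
    sim.pop("replicates", None)
    if seed is not None:
        sim["seed"] = int(seed)
    return KineticParams(**sim)


def sha256_file(path) -> str:
    """Hex digest of a file's bytes, for run provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
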