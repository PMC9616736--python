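"""Behavioral index formulas: two-choice preference index and
evaporation-corrected CAFE (capillary feeder) consumption."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError

__all__ = ["ChoiceCounts", "CafeRecord", "preference_index", "cafe_consumption"]


@dataclass
class ChoiceCounts:
    n_wet: int
    n_dry: int


@dataclass
class CafeRecord:
    volumes: Sequence[float]  # uL consumed per capillary
    evaporation: Sequence[float]  # uL lost in empty control vials
    flies_start: int
    flies_end: int


def preference_index(n_wet: int, n_dry: int) -> float:
    """(n_wet - n_dry) / (n_wet + n_dry), in [-1, 1].

    Serves the humidity preference index and, with the arms reinterpreted,
    any two-option choice index.  Undefined (error) for zero total.
    """
    if n_wet < 0 or n_dry < 0:
        raise DataError("counts must be non-negative")
    total = n_wet + n_dry
    if total == 0:
        raise DataError("preference index undefined for zero total flies")
    return (n_wet - n_dry) / total


def cafe_consumption(record: CafeRecord, per_fly: str = "end") -> tuple:
    """Evaporation-corrected consumption and per-fly volume (uL).

    corrected = max(0, sum(volumes) - mean(evaporation controls)).
    ``per_fly="end"`` normalizes by survivors at the end of the assay;
    ``"mean"`` by the mean of start and end counts.
    """
    vols = np.asarray(record.volumes, float)
    evap = np.asarray(record.evaporation, float)
    if evap.size == 0:
        raise DataError("at least one evaporation control is required")
    if np.any(vols < 0) or np.any(evap < 0):
        raise DataError("volumes must be non-negative")
    if record.flies_end > record.flies_start or record.flies_end < 0:
        raise DataError("flies_end must be in [0, flies_start]")
    corrected = max(0.0, float(vols.sum() - evap.mean()))
    if per_fly == "end":
        denom = record.flies_end
    elif per_fly == "mean":
        denom = 0.5 * (record.flies_start + record.flies_end)
    else:
        raise DataError(f"unknown per_fly mode: {per_fly}")
    if denom <= 0:
        raise DataError("no surviving flies: per-fly volume undefined")
    return corrected, corrected / denom
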