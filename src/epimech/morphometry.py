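"""Mosaic-clone morphometry: clone-versus-control ratios.

In genetically mosaic tissue, a patch of labelled (clone) cells is compared
against unlabelled control cells of the same anatomical unit (one follicle
or one embryonic segment). Each unit contributes a single observation: the
ratio of the clone-cell group mean to the control-cell group mean, for
apical domain width (um) or apical fluorescence intensity (a.u.). Using
the ratio of group means keeps the statistic well-defined for unequal
group sizes and cancels any calibration common to both groups; per-unit
ratios (not a pooled ratio across units) are the observations fed to the
group statistics, matching how follicles are counted as n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CloneMeasurementSet",
    "RatioResult",
    "widths_from_boundaries",
    "clone_ratio",
    "cohort_ratios",
    "ratios_to_frame",
]


@dataclass
class CloneMeasurementSet:
    """Paired clone and control per-cell measurements within one unit."""

    unit_id: str
    clone_values: np.ndarray
    control_values: np.ndarray
    measure_kind: Literal["width", "intensity"] = "width"

    def __post_init__(self) -> None:
        self.clone_values = np.asarray(self.clone_values, dtype=float)
        self.control_values = np.asarray(self.control_values, dtype=float)
        for name, arr in (("clone_values", self.clone_values),
                          ("control_values", self.control_values)):
            if arr.size == 0:
                raise ValueError(f"{name}: must be non-empty")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name}: values must be finite and > 0")
        if self.measure_kind not in ("width", "intensity"):
            raise ValueError(f"measure_kind: unknown kind {self.measure_kind!r}")


@dataclass
class RatioResult:
    unit_id: str
    clone_mean: float
    control_mean: float
    ratio: float
    measure_kind: str = "width"
    n_clone: int = 0
    n_control: int = 0


def widths_from_boundaries(boundary_positions: Sequence[float]) -> np.ndarray:
    """Per-cell apical widths from ordered boundary positions along a surface.

    Boundaries are strictly increasing coordinates (um) of successive cell
    edges along the apical surface; widths are the consecutive differences.
    """
    pos = np.asarray(boundary_positions, dtype=float)
    if pos.ndim != 1 or pos.size < 2:
        raise ValueError("boundary_positions: need at least 2 positions")
    widths = np.diff(pos)
    if np.any(widths <= 0):
        raise ValueError("boundary_positions: must be strictly increasing")
    return widths


def clone_ratio(mset: CloneMeasurementSet) -> RatioResult:
    """Ratio of the clone group mean to the control group mean for one unit."""
    clone_mean = float(mset.clone_values.mean())
    control_mean = float(mset.control_values.mean())
    return RatioResult(unit_id=mset.unit_id, clone_mean=clone_mean,
                       control_mean=control_mean,
                       ratio=clone_mean / control_mean,
                       measure_kind=mset.measure_kind,
                       n_clone=int(mset.clone_values.size),
                       n_control=int(mset.control_values.size))


def cohort_ratios(sets: Sequence[CloneMeasurementSet]) -> list[RatioResult]:
    """One RatioResult per unit, order preserved."""
    if len(sets) == 0:
        raise ValueError("sets: need at least one measurement set")
    return [clone_ratio(s) for s in sets]


def ratios_to_frame(results: Sequence[RatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in results],
            "measure_kind": [r.measure_kind for r in results],
            "clone_mean": [r.clone_mean for r in results],
            "control_mean": [r.control_mean for r in results],
            "ratio": [r.ratio for r in results],
            "n_clone": [r.n_clone for r in results],
            "n_control": [r.n_control for r in results],
        }
    )
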