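"""Well-exclusion rules.

Two main criteria remove wells from screening statistics, mirroring how
the assay is quality-controlled in practice:

1. spheroid count — wells with zero, two or more segmented spheroids are
   omitted;
2. shape — wells whose spheroid roundness statistic (weighted moment of
   inertia of the contiguous object) exceeds the *upper adjacent value*
   (the boxplot upper-whisker datum, largest observation within
   Q3 + 1.5·IQR) of the plate's single-spheroid wells are flagged
   misshapen (fibers, fused debris).

A third, auxiliary rule catches gross brightfield-segmentation failures:
a core area below a quarter of the plate's median core area.  The fence is
computed once per plate across its single-spheroid wells, so re-running
the exclusions on the survivors flags nothing new.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError
from .quantify import WellMetrics

FLAG_KINDS = (
    "no_spheroid",
    "multiple_spheroids",
    "misshapen",
    "segmentation_failure",
    "empty_well",
)


@dataclass
class QCFlags:
    flags: set[str] = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return bool(self.flags)


def spheroid_count_flag(n_spheroids: int) -> str | None:
    """``None`` iff exactly one spheroid; otherwise the exclusion flag."""
    if n_spheroids < 0:
        raise ContractError("spheroid count cannot be negative")
    if n_spheroids == 1:
        return None
    return "no_spheroid" if n_spheroids == 0 else "multiple_spheroids"


def upper_adjacent_value(values: Sequence[float]) -> float:
    """Largest observation ≤ Q3 + 1.5·IQR (linear-interpolation quartiles)."""
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ContractError("need at least 4 values for the upper adjacent value")
    q1, q3 = np.percentile(v, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return float(v[v <= fence].max())


def apply_exclusions(
    metrics: Sequence[WellMetrics],
    core_area_floor_fraction: float = 0.25,
) -> dict[str, QCFlags]:
    """Flag every well of a plate; a well is excluded iff it has any flag.

    The misshapen fence is the upper adjacent value of the roundness of
    the plate's single-spheroid wells (skipped when fewer than four are
    available); the segmentation-failure floor is relative to the plate's
    median single-spheroid core area.
    """
    metrics = list(metrics)
    if not metrics:
        raise ContractError("empty plate")
    result = {m.well_id: QCFlags(set()) for m in metrics}

    single = [m for m in metrics if m.n_spheroids == 1]
    roundness = np.array([m.roundness for m in single], dtype=float)
    roundness = roundness[np.isfinite(roundness)]
    fence = upper_adjacent_value(roundness) if roundness.size >= 4 else None
    core_areas = np.array(
        [m.core_area for m in single if m.core_area > 0], dtype=float
    )
    floor = (
        core_area_floor_fraction * float(np.median(core_areas))
        if core_areas.size
        else None
    )

    for m in metrics:
        flags = result[m.well_id].flags
        count_flag = spheroid_count_flag(m.n_spheroids)
        if count_flag:
            flags.add(count_flag)
        if "empty_well" in m.qc_flags:
            flags.add("empty_well")
        if "segmentation_failure" in m.qc_flags:
            flags.add("segmentation_failure")
        if m.n_spheroids == 1:
            if fence is not None and np.isfinite(m.roundness) and m.roundness > fence:
                flags.add("misshapen")
            if floor is not None and m.core_area < floor:
                flags.add("segmentation_failure")
    return result


def qc_report(
    metrics: Sequence[WellMetrics], flags: dict[str, QCFlags]
) -> pd.DataFrame:
    """Per-well QC table: flags, exclusion status, roundness, fence value."""
    single = [m for m in metrics if m.n_spheroids == 1]
    roundness = np.array([m.roundness for m in single], dtype=float)
    roundness = roundness[np.isfinite(roundness)]
    fence = upper_adjacent_value(roundness) if roundness.size >= 4 else np.nan
    rows = [
        {
            "well": m.well_id,
            "flags": ";".join(sorted(flags[m.well_id].flags)),
            "excluded": flags[m.well_id].excluded,
            "roundness": m.roundness,
            "fence": fence,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows)
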