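"""Flocculation scoring from multi-point plate-reader OD600 scans.

A flocculating culture settles into clumps, so optical density measured at
many points across one well is spatially heterogeneous. The flocculation
score of a well is the coefficient of variation (sd/mean) of its
background-corrected multi-point OD600 readings. A filter-based assay
variant scores the fraction of biomass retained on a filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WellScan",
    "PlateScan",
    "FlocScore",
    "parse_scan_csv",
    "background_subtract",
    "flocculation_cv",
    "score_plate",
    "filtering_fraction",
]


@dataclass(frozen=True)
class WellScan:
    """An n x n grid of OD600 readings measured across one well."""

    well_id: str
    readings: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.readings, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] < 2:
            raise ValueError(
                f"well {self.well_id}: readings must form an n x n grid, n >= 2"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"well {self.well_id}: non-finite readings")
        object.__setattr__(self, "readings", arr)

    @property
    def n(self) -> int:
        return self.readings.shape[0]


@dataclass(frozen=True)
class PlateScan:
    """Up to 96 well scans plus the identity of the negative-control well."""

    wells: dict[str, WellScan]
    control_well: str
    background_corrected: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.control_well not in self.wells:
            raise ValueError(f"control well {self.control_well!r} not in plate")


@dataclass(frozen=True)
class FlocScore:
    well_id: str
    mean_od: float
    cv: float  # NaN when the corrected mean is <= 0
    flagged: bool


def parse_scan_csv(path: str | Path, n: int) -> pd.DataFrame:
    """Parse a multi-point plate-reader scan CSV.

    Dialect: one row per well, the well id (e.g. ``A1``) followed by n*n
    comma-separated OD600 readings in row-major grid order. ``n`` is the
    square root of the measurements per well (e.g. 15 for 15 x 15 scans) and
    is required to validate row lengths.

    Returns a DataFrame indexed by well id with one column per grid point;
    combine with :func:`make_plate` / :class:`PlateScan` for scoring.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    path = Path(path)
    rows: dict[str, np.ndarray] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            well = parts[0].strip()
            if not well:
                raise ValueError(f"{path.name}:{lineno}: missing well id")
            values = parts[1:]
            if len(values) != n * n:
                raise ValueError(
                    f"{path.name}: well {well} has {len(values)} readings, "
                    f"expected {n * n} (n={n})"
                )
            if well in rows:
                raise ValueError(f"{path.name}: duplicate well id {well}")
            rows[well] = np.asarray(values, dtype=float)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "well"
    return frame


def make_plate(scan: pd.DataFrame, control_well: str) -> PlateScan:
    """Assemble a :class:`PlateScan` from a parsed scan table."""
    n = math.isqrt(scan.shape[1])
    if n * n != scan.shape[1]:
        raise ValueError(f"{scan.shape[1]} readings per well is not a square")
    wells = {
        str(w): WellScan(str(w), scan.loc[w].to_numpy(dtype=float).reshape(n, n))
        for w in scan.index
    }
    return PlateScan(wells=wells, control_well=control_well)


def background_subtract(plate: PlateScan) -> PlateScan:
    """Subtract the control well's mean OD from every reading on the plate.

    Controls for background light absorption of medium and plastic; the
    control well's corrected mean is exactly 0.
    """
    background = float(plate.wells[plate.control_well].readings.mean())
    corrected = {
        wid: WellScan(wid, well.readings - background)
        for wid, well in plate.wells.items()
    }
    return replace(plate, wells=corrected, background_corrected=True)


def flocculation_cv(well: WellScan, ddof: int = 0) -> FlocScore:
    """Coefficient of variation of a well's (background-corrected) readings.

    cv = sd / mean, with the population standard deviation by default
    (``ddof=0``): the grid is the full set of measurements, not a sample.
    When the corrected mean is <= 0 there is no biomass signal to normalize
    by; the score is returned missing (NaN) and flagged.
    """
    readings = well.readings.ravel()
    mean = float(readings.mean())
    if mean <= 0:
        warnings.warn(
            f"well {well.well_id}: non-positive corrected mean ({mean:.4g}); "
            "CV undefined",
            stacklevel=2,
        )
        return FlocScore(well.well_id, mean_od=mean, cv=float("nan"), flagged=True)
    sd = float(readings.std(ddof=ddof))
    return FlocScore(well.well_id, mean_od=mean, cv=sd / mean, flagged=False)


def score_plate(plate: PlateScan, ddof: int = 0) -> pd.DataFrame:
    """Background-subtract a plate and score every well.

    Returns a DataFrame with columns well, mean_od, cv, flagged.
    """
    corrected = plate if plate.background_corrected else background_subtract(plate)
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-well flags carry the diagnostics
        for wid in corrected.wells:
            s = flocculation_cv(corrected.wells[wid], ddof=ddof)
            scores.append((s.well_id, s.mean_od, s.cv, s.flagged))
    return pd.DataFrame(scores, columns=["well", "mean_od", "cv", "flagged"])


def filtering_fraction(od_a: float, od_b: float) -> float:
    """Fraction of flocculating cells in the filter assay.

    ``od_a`` is the OD600 of the culture fraction passing the filter
    (non-flocculating), ``od_b`` the fraction retained (flocculating);
    the flocculating fraction is OD(B) / (OD(A) + OD(B)).
    """
    if od_a < 0 or od_b < 0:
        raise ValueError("optical densities must be >= 0")
    if od_a == 0 and od_b == 0:
        raise ValueError("no biomass: both optical densities are 0")
    return od_b / (od_a + od_b)
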