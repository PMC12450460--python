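"""Per-well intensity statistics over circular regions of interest.

For each well the median, mean, population standard deviation, mode,
minimum, maximum and pixel count are computed over exactly the ROI
pixel multiset. The mode of a real-valued (background-corrected) image
is taken after rounding pixel values to the nearest integer of the
original intensity scale, with ties broken toward the smallest value;
the median of an even pixel count is the midpoint of the two central
values.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridGeometry, WellROI, well_rois
from .plate_io import RasterImage

MEASUREMENT_COLUMNS = ["well", "median", "mean", "sd", "mode", "min", "max", "n_pixels"]


@dataclass(frozen=True)
class WellMeasurement:
    well_label: str
    median: float
    mean: float
    sd: float
    mode: float
    min: float
    max: float
    n_pixels: int


def _mode_rounded(values: np.ndarray) -> float:
    """Most frequent value after rounding to the integer intensity scale.

    Ties are broken by the smallest value. np.unique returns sorted
    values, so the first argmax hit is the smallest tied value.
    """
    rounded = np.rint(values)
    uniq, counts = np.unique(rounded, return_counts=True)
    return float(uniq[np.argmax(counts)])


def measure_well(image: RasterImage, roi: WellROI) -> WellMeasurement:
    """Intensity statistics over one ROI; sd is the population sd."""
    values = roi.pixel_values(image)
    if values.size == 0:
        raise ValueError(f"empty ROI for well {roi.well_label}")
    return WellMeasurement(
        well_label=roi.well_label,
        median=float(np.median(values)),
        mean=float(np.mean(values)),
        sd=float(np.std(values)),  # population (ddof=0)
        mode=_mode_rounded(values),
        min=float(np.min(values)),
        max=float(np.max(values)),
        n_pixels=int(values.size),
    )


def measure_plate(image: RasterImage, g: GridGeometry) -> pd.DataFrame:
    """Measure every well; one row per well in row-major A1..H12 order."""
    rows = []
    for roi in well_rois(g, image):
        m = measure_well(image, roi)
        d = asdict(m)
        d["well"] = d.pop("well_label")
        rows.append(d)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def export_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write the measurement table as CSV (header + one row per well)."""
    table.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return df[MEASUREMENT_COLUMNS]
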