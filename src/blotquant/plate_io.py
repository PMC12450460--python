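"""Image and plate-map input/output.

Grayscale dot-blot scans are exchanged as single-channel 8- or 16-bit
TIFF files; plate maps arrive as CSV. Internally every image operation
works on a :class:`RasterImage`, a float64 pixel array with its source
bit depth remembered so integer images round-trip losslessly.

Coordinate convention: 0-based ``(row, column)`` = ``(y, x)``; continuous
coordinates place integer values at pixel centers.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

ROLE_SAMPLE = "sample"
ROLE_BUFFER = "buffer_only"
ROLE_UNTAGGED = "untagged"
VALID_ROLES = frozenset({ROLE_SAMPLE, ROLE_BUFFER, ROLE_UNTAGGED})
CONTROL_ROLES = frozenset({ROLE_BUFFER, ROLE_UNTAGGED})

_WELL_RE = re.compile(r"^([A-Z])([0-9]{1,2})$")


class PlateMapError(ValueError):
    """A plate-map CSV row violates the documented dialect."""


@dataclass
class RasterImage:
    """A 2-D grid of non-negative pixel intensities.

    Parameters
    ----------
    pixels
        2-D float64 array, all values >= 0.
    source_bit_depth
        8 or 16 for integer scanner exports, or ``None`` when unknown
        (e.g. after background correction).
    """

    pixels: np.ndarray
    source_bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.source_bit_depth not in (None, 8, 16):
            raise ValueError(f"unsupported bit depth: {self.source_bit_depth}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PlateMapEntry:
    well: str
    sample_id: str
    replicate_group: str
    role: str
    bca_concentration: float | None


@dataclass
class PlateMap:
    """Assignment of each well to a sample, replicate group and role."""

    entries: list[PlateMapEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            parse_well_label(e.well)
            if e.well in seen:
                raise PlateMapError(f"duplicate well label {e.well!r}")
            seen.add(e.well)
            if e.role not in VALID_ROLES:
                raise PlateMapError(
                    f"unknown role {e.role!r} for well {e.well} "
                    f"(expected one of {sorted(VALID_ROLES)})"
                )
            if e.role == ROLE_SAMPLE:
                if e.bca_concentration is None:
                    raise PlateMapError(f"sample well {e.well} lacks a BCA concentration")
                if e.bca_concentration <= 0:
                    raise PlateMapError(f"non-positive BCA concentration for well {e.well}")

    def __len__(self) -> int:
        return len(self.entries)

    def by_role(self, role: str) -> list[PlateMapEntry]:
        return [e for e in self.entries if e.role == role]


def parse_well_label(label: str, n_rows: int = 8, n_cols: int = 12) -> tuple[int, int]:
    """Parse ``"A1"``..``"H12"`` into 0-based (row, column) indices."""
    m = _WELL_RE.match(label)
    if not m:
        raise PlateMapError(f"malformed well label {label!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if row >= n_rows or not (0 <= col < n_cols):
        raise PlateMapError(
            f"well label {label!r} outside the {n_rows}x{n_cols} plate"
        )
    return row, col


def well_label(row: int, col: int) -> str:
    """0-based (row, col) -> ``"A1"`` style label."""
    return f"{chr(ord('A') + row)}{col + 1}"


def read_image(path: str | Path) -> RasterImage:
    """Read a grayscale TIFF scanner export.

    Multi-channel input uses channel 0 with a logged warning. Integer
    pixel values are converted to float64 on their original scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        # channel-last (H, W, C) or channel-first planar stack
        axis = 2 if arr.shape[2] <= 4 else 0
        logger.warning(
            "multi-channel TIFF %s: using channel 0 of %d", path, arr.shape[axis]
        )
        arr = arr[:, :, 0] if axis == 2 else arr[0]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.dtype == np.uint8:
        depth: int | None = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        depth = None
    return RasterImage(arr.astype(np.float64), source_bit_depth=depth)


def write_image(image: RasterImage, path: str | Path) -> None:
    """Write a :class:`RasterImage` as TIFF.

    Integer-valued images are stored losslessly at their declared bit
    depth; real-valued images (or unknown depth) as 32-bit float.
    """
    path = Path(path)
    px = image.pixels
    depth = image.source_bit_depth
    if depth is not None:
        ceiling = 2**depth - 1
        if px.max(initial=0) > ceiling:
            raise ValueError(
                f"pixel value {px.max():g} exceeds the declared {depth}-bit ceiling {ceiling}"
            )
        if np.array_equal(px, np.round(px)):
            dtype = np.uint8 if depth == 8 else np.uint16
            tifffile.imwrite(path, px.astype(dtype))
            return
    tifffile.imwrite(path, px.astype(np.float32))


def read_plate_map(path: str | Path) -> PlateMap:
    """Parse a plate-map CSV with header ``well,sample,replicate_group,role,bca``.

    The ``bca`` field may be blank only for control roles. Every
    malformed row raises :class:`PlateMapError` naming its line number.
    """
    path = Path(path)
    required = ["well", "sample", "replicate_group", "role", "bca"]
    entries: list[PlateMapEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != required:
            raise PlateMapError(
                f"{path}: expected header {','.join(required)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                bca_raw = (row["bca"] or "").strip()
                bca = float(bca_raw) if bca_raw else None
                entry = PlateMapEntry(
                    well=row["well"].strip(),
                    sample_id=row["sample"].strip(),
                    replicate_group=row["replicate_group"].strip(),
                    role=row["role"].strip(),
                    bca_concentration=bca,
                )
                parse_well_label(entry.well)
                if entry.role not in VALID_ROLES:
                    raise PlateMapError(f"unknown role {entry.role!r}")
                if entry.role == ROLE_SAMPLE and (bca is None or bca <= 0):
                    raise PlateMapError("sample row requires a positive bca value")
            except (PlateMapError, ValueError, KeyError) as exc:
                raise PlateMapError(f"{path}:{lineno}: {exc}") from exc
            entries.append(entry)
    return PlateMap(entries)


def write_plate_map(pm: PlateMap, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "sample", "replicate_group", "role", "bca"])
        for e in pm.entries:
            bca = "" if e.bca_concentration is None else repr(e.bca_concentration)
            writer.writerow([e.well, e.sample_id, e.replicate_group, e.role, bca])
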