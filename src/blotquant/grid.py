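"""Virtual 96-well grid from three corner-well anchors.

Grid registration follows the three-point scheme used for microplate
scans: the user supplies the pixel centers of wells A1, A12 and H1 and
every other well center is the bilinear span

    center(r, c) = A1 + ((c-1)/(n_cols-1)) * (A12 - A1)
                      + ((r-1)/(n_rows-1)) * (H1 - A1)

(1-based row r, column c), which handles translated, rotated and
sheared plates by construction. Circular regions of interest collect
every pixel whose center lies within the well radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .plate_io import RasterImage, well_label


@dataclass(frozen=True)
class PlateLayout:
    """Row/column structure of the plate (default 8x12 = 96 wells)."""

    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("layout needs at least 2 rows and 2 columns")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def labels(self) -> list[str]:
        """Row-major well labels A1..H12."""
        return [
            well_label(r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]


@dataclass(frozen=True)
class GridGeometry:
    """Three corner anchors plus well radius.

    Anchors are (x, y) pixel coordinates of the centers of the first-row
    first-column well (A1), the first-row last-column well (A12 on a
    standard plate) and the last-row first-column well (H1).
    """

    p_a1: tuple[float, float]
    p_a1n: tuple[float, float]
    p_h1: tuple[float, float]
    well_radius: float
    layout: PlateLayout = field(default_factory=PlateLayout)

    def __post_init__(self) -> None:
        a1 = np.asarray(self.p_a1, float)
        u = np.asarray(self.p_a1n, float) - a1
        v = np.asarray(self.p_h1, float) - a1
        cross = u[0] * v[1] - u[1] * v[0]
        if abs(cross) < 1e-9:
            raise ValueError("the three anchors are collinear")
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        col_spacing = float(np.linalg.norm(u)) / (self.layout.n_cols - 1)
        row_spacing = float(np.linalg.norm(v)) / (self.layout.n_rows - 1)
        if self.well_radius >= min(col_spacing, row_spacing) / 2:
            raise ValueError(
                f"well_radius {self.well_radius:g} must be below half the "
                f"smaller inter-well spacing ({min(col_spacing, row_spacing) / 2:g})"
            )

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        """Continuous (x, y) center of the 0-based (row, col) well."""
        fc = col / (self.layout.n_cols - 1)
        fr = row / (self.layout.n_rows - 1)
        # barycentric form of A1 + fc*(A12-A1) + fr*(H1-A1): recovers the
        # anchors bit-for-bit at the corner wells
        a1 = np.asarray(self.p_a1, float)
        a1n = np.asarray(self.p_a1n, float)
        h1 = np.asarray(self.p_h1, float)
        center = (1.0 - fc - fr) * a1 + fc * a1n + fr * h1
        return float(center[0]), float(center[1])

    def centers(self) -> list[tuple[str, float, float]]:
        """All well centers, row-major: (label, x, y)."""
        return [
            (well_label(r, c), *self.well_center(r, c))
            for r in range(self.layout.n_rows)
            for c in range(self.layout.n_cols)
        ]


@dataclass(frozen=True)
class WellROI:
    """Circular region of interest of one well.

    ``pixel_set`` holds the 0-based (row, col) indices of every pixel
    whose center lies within ``radius`` (inclusive) of ``center``.
    """

    well_label: str
    center: tuple[float, float]
    radius: float
    pixel_set: frozenset[tuple[int, int]]

    def pixel_values(self, image: RasterImage) -> np.ndarray:
        idx = np.array(sorted(self.pixel_set))
        return image.pixels[idx[:, 0], idx[:, 1]]


def fit_grid(
    p_a1: tuple[float, float],
    p_a1n: tuple[float, float],
    p_h1: tuple[float, float],
    well_radius: float,
    layout: PlateLayout | None = None,
) -> GridGeometry:
    """Construct the grid from the three corner-well centers."""
    return GridGeometry(
        p_a1=tuple(map(float, p_a1)),
        p_a1n=tuple(map(float, p_a1n)),
        p_h1=tuple(map(float, p_h1)),
        well_radius=float(well_radius),
        layout=layout or PlateLayout(),
    )


def adjust_grid(
    g: GridGeometry,
    dx: float = 0.0,
    dy: float = 0.0,
    radius_new: float | None = None,
    col_scale: float = 1.0,
    row_scale: float = 1.0,
) -> GridGeometry:
    """Fine-tune the grid: translate, rescale spacings about A1, set radius.

    The A1->A12 vector is scaled by ``col_scale`` and the A1->H1 vector
    by ``row_scale``; all anchors are then shifted by ``(dx, dy)``.
    """
    a1 = np.asarray(g.p_a1, float)
    u = np.asarray(g.p_a1n, float) - a1
    v = np.asarray(g.p_h1, float) - a1
    shift = np.array([dx, dy], float)
    new_a1 = a1 + shift
    new_a1n = a1 + col_scale * u + shift
    new_h1 = a1 + row_scale * v + shift
    return replace(
        g,
        p_a1=(float(new_a1[0]), float(new_a1[1])),
        p_a1n=(float(new_a1n[0]), float(new_a1n[1])),
        p_h1=(float(new_h1[0]), float(new_h1[1])),
        well_radius=g.well_radius if radius_new is None else float(radius_new),
    )


def roi_pixels(
    center: tuple[float, float], radius: float
) -> frozenset[tuple[int, int]]:
    """Pixels whose center lies within ``radius`` of ``center`` (inclusive)."""
    cx, cy = center
    r = radius
    rows = range(int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1)
    cols = range(int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1)
    out = {
        (row, col)
        for row in rows
        for col in cols
        if (col - cx) ** 2 + (row - cy) ** 2 <= r * r
    }
    return frozenset(out)


def well_rois(g: GridGeometry, image: RasterImage) -> list[WellROI]:
    """One circular ROI per well, row-major A1..H12.

    Raises ``ValueError`` naming the first well whose disc extends
    (even partially) outside the image bounds.
    """
    rois: list[WellROI] = []
    for label, cx, cy in g.centers():
        r = g.well_radius
        if cx - r < -0.5 or cy - r < -0.5 or cx + r > image.width - 0.5 or cy + r > image.height - 0.5:
            raise ValueError(
                f"ROI for well {label} extends outside the "
                f"{image.height}x{image.width} image"
            )
        pixels = roi_pixels((cx, cy), r)
        if not pixels:
            raise ValueError(f"ROI for well {label} contains no pixels")
        rois.append(WellROI(label, (cx, cy), r, pixels))
    return rois


def write_geometry(g: GridGeometry, path) -> None:
    """Plain-text key=value geometry file consumed by the quantify CLI."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"a1={g.p_a1[0]!r},{g.p_a1[1]!r}\n")
        fh.write(f"a1n={g.p_a1n[0]!r},{g.p_a1n[1]!r}\n")
        fh.write(f"h1={g.p_h1[0]!r},{g.p_h1[1]!r}\n")
        fh.write(f"radius={g.well_radius!r}\n")
        fh.write(f"rows={g.layout.n_rows}\n")
        fh.write(f"cols={g.layout.n_cols}\n")


def read_geometry(path) -> GridGeometry:
    kv: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    def pt(key: str) -> tuple[float, float]:
        x, y = kv[key].split(",")
        return float(x), float(y)
    return GridGeometry(
        p_a1=pt("a1"),
        p_a1n=pt("a1n"),
        p_h1=pt("h1"),
        well_radius=float(kv["radius"]),
        layout=PlateLayout(int(kv.get("rows", 8)), int(kv.get("cols", 12))),
    )
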