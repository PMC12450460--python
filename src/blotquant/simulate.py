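"""Synthetic dot-blot plate images with known ground truth.

The simulator emulates a near-infrared flatbed scan of a 96-well dot
blot: an 8x12 near-affine grid of roughly Gaussian spots of varying
amplitude sitting on a smooth uneven-illumination field (offset plus
linear gradient), with additive Gaussian read noise, quantized to the
16-bit scanner scale. Every parameter of the scene — grid geometry,
per-well amplitude, illumination, noise — is recorded as ground truth
so the correction, gridding, quantification and normalization steps can
be validated end to end without external data.

The default fixture mirrors a typical abundance-screening plate: 30
strains in 3 replicates each plus 6 control wells (3 buffer-only at
amplitude zero, 3 untagged-strain wells at a small constant), replicate
wells scattered over the plate, spot amplitudes spanning two orders of
magnitude, and per-well protein loading variation recorded as the BCA
concentration. Flat-top spots (constant plateau within two spot sigmas
of the center) make the per-well median recover the amplitude exactly
in the noise-free case, separating geometry errors from PSF effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridGeometry, PlateLayout
from .plate_io import (
    ROLE_BUFFER,
    ROLE_SAMPLE,
    ROLE_UNTAGGED,
    PlateMap,
    PlateMapEntry,
    RasterImage,
)

SPOT_GAUSSIAN = "gaussian"
SPOT_FLAT_TOP = "flat_top"

DEFAULT_SEED = 20260101

# default fixture scene parameters (16-bit scanner scale)
_N_SAMPLES = 30
_N_REPLICATES = 3
_N_BUFFER = 3
_N_UNTAGGED = 3
_AMP_MIN, _AMP_MAX = 10.0, 1000.0  # two orders of magnitude
_UNTAGGED_AMPLITUDE = 2.0  # residual anti-tag cross-reactivity
_LOADING_RANGE = (0.8, 1.25)  # per-well protein loading spread (BCA)


@dataclass
class SimulationConfig:
    """Full description of one synthetic plate scene."""

    layout: PlateLayout
    geometry: GridGeometry
    amplitudes: np.ndarray  # per-well, row-major A1..H12
    spot_sigma: float
    spot_shape: str = SPOT_FLAT_TOP
    illum_gradient: tuple[float, float] = (0.0, 0.0)  # (gx, gy) intensity/px
    illum_offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = DEFAULT_SEED
    image_shape: tuple[int, int] = (320, 440)  # (height, width)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.size != self.layout.n_wells:
            raise ValueError(
                f"expected {self.layout.n_wells} amplitudes, got {self.amplitudes.size}"
            )
        if np.any(self.amplitudes < 0):
            raise ValueError("spot amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spot_shape not in (SPOT_GAUSSIAN, SPOT_FLAT_TOP):
            raise ValueError(f"unknown spot shape {self.spot_shape!r}")
        h, w = self.image_shape
        margin = 2 * self.spot_sigma
        for label, cx, cy in self.geometry.centers():
            if not (margin <= cx <= w - 1 - margin and margin <= cy <= h - 1 - margin):
                raise ValueError(
                    f"well {label} (center {cx:g},{cy:g}) does not fit the "
                    f"{h}x{w} canvas"
                )


def simulate_plate(cfg: SimulationConfig) -> tuple[RasterImage, pd.DataFrame]:
    """Render the scene and return the image plus the ground-truth table.

    image = offset + gx*x + gy*y + sum of per-well spots + N(0, noise_sd),
    rounded to the integer scanner scale and clipped to [0, 2^depth - 1].
    Identical seeds give bitwise-identical images. The truth table lists
    each well's center and amplitude, row-major.
    """
    h, w = cfg.image_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    gx, gy = cfg.illum_gradient
    field_img = cfg.illum_offset + gx * xx + gy * yy

    truth_rows = []
    for (label, cx, cy), amp in zip(cfg.geometry.centers(), cfg.amplitudes):
        truth_rows.append({"well": label, "x": cx, "y": cy, "amplitude": amp})
        if amp == 0:
            continue
        # render inside a local window; the spot is negligible beyond it
        reach = int(np.ceil(5 * cfg.spot_sigma))
        r0, r1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
        c0, c1 = max(0, int(cx) - reach), min(w, int(cx) + reach + 1)
        wy, wx = np.mgrid[r0:r1, c0:c1].astype(float)
        d2 = (wx - cx) ** 2 + (wy - cy) ** 2
        if cfg.spot_shape == SPOT_FLAT_TOP:
            spot = np.where(d2 <= (2 * cfg.spot_sigma) ** 2, amp, 0.0)
        else:
            spot = amp * np.exp(-d2 / (2 * cfg.spot_sigma**2))
        field_img[r0:r1, c0:c1] += spot

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        field_img = field_img + rng.normal(0.0, cfg.noise_sd, size=field_img.shape)

    ceiling = 2**cfg.bit_depth - 1
    pixels = np.clip(np.rint(field_img), 0, ceiling)
    image = RasterImage(pixels, source_bit_depth=cfg.bit_depth)
    truth = pd.DataFrame(truth_rows, columns=["well", "x", "y", "amplitude"])
    return image, truth


# ---------------------------------------------------------------------------
# Default fixture: a realistic abundance-screening plate


def _fixture_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _fixture_design(seed: int) -> pd.DataFrame:
    """Well-by-well design: sample identity, role, expression, loading.

    30 samples x 3 replicates + 3 buffer-only + 3 untagged wells are
    scattered over the 96 positions with a seed-derived permutation.
    True expression amplitudes are log-spaced over two orders of
    magnitude; per-well loading factors multiply the rendered spot and
    are reported as the BCA concentration.
    """
    layout = PlateLayout()
    labels = layout.labels()
    rng = _fixture_rng(seed)

    expression = np.logspace(
        np.log10(_AMP_MIN), np.log10(_AMP_MAX), _N_SAMPLES
    )
    slots: list[tuple[str, str, float]] = []  # (sample_id, role, expression)
    for i, amp in enumerate(expression):
        sid = f"S{i + 1:02d}"
        slots.extend((sid, ROLE_SAMPLE, float(amp)) for _ in range(_N_REPLICATES))
    slots.extend(("buffer", ROLE_BUFFER, 0.0) for _ in range(_N_BUFFER))
    slots.extend(("untagged", ROLE_UNTAGGED, _UNTAGGED_AMPLITUDE) for _ in range(_N_UNTAGGED))
    assert len(slots) == layout.n_wells

    order = rng.permutation(len(slots))
    loading = rng.uniform(*_LOADING_RANGE, size=layout.n_wells)
    rows = []
    for pos, slot_idx in enumerate(order):
        sid, role, expr = slots[slot_idx]
        load = float(loading[pos])
        rows.append(
            {
                "well": labels[pos],
                "sample": sid,
                "role": role,
                "expression": expr,
                # buffer-only wells hold no cells: nothing to load
                "loading": load if role != ROLE_BUFFER else 0.0,
                "spot_amplitude": expr * load if role != ROLE_BUFFER else 0.0,
            }
        )
    return pd.DataFrame(rows)


def default_fixture_geometry() -> GridGeometry:
    """True grid of the fixture: 30 px pitch, 60 px margins, radius 5."""
    return GridGeometry(
        p_a1=(50.0, 50.0),
        p_a1n=(380.0, 50.0),
        p_h1=(50.0, 260.0),
        well_radius=5.0,
        layout=PlateLayout(),
    )


def default_fixture(seed: int = DEFAULT_SEED) -> SimulationConfig:
    """The standard verification scene (see module docstring)."""
    design = _fixture_design(seed)
    return SimulationConfig(
        layout=PlateLayout(),
        geometry=default_fixture_geometry(),
        amplitudes=design["spot_amplitude"].to_numpy(),
        spot_sigma=3.5,
        spot_shape=SPOT_FLAT_TOP,
        illum_gradient=(0.02, 0.03),
        illum_offset=20.0,
        noise_sd=0.01 * _AMP_MAX,  # 1% of the maximum spot amplitude
        seed=seed,
        image_shape=(320, 440),
        bit_depth=16,
    )


def default_fixture_plate_map(seed: int = DEFAULT_SEED) -> PlateMap:
    """Plate map matching :func:`default_fixture`.

    Sample wells report their loading factor as the BCA concentration;
    control wells (no cells / no tagged protein) leave it blank, as a
    real BCA table would.
    """
    design = _fixture_design(seed)
    entries = []
    rep_counter: dict[str, int] = {}
    for row in design.itertuples():
        rep_counter[row.sample] = rep_counter.get(row.sample, 0) + 1
        entries.append(
            PlateMapEntry(
                well=row.well,
                sample_id=row.sample,
                replicate_group=f"{row.sample}_r{rep_counter[row.sample]}",
                role=row.role,
                bca_concentration=row.loading if row.role == ROLE_SAMPLE else None,
            )
        )
    return PlateMap(entries)


def default_fixture_truth(seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """True per-sample expression amplitudes of the fixture."""
    design = _fixture_design(seed)
    samples = design[design["role"] == ROLE_SAMPLE]
    return (
        samples.groupby("sample", as_index=False)
        .agg(expression=("expression", "first"))
        .sort_values("sample")
        .reset_index(drop=True)
    )
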